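"""End-to-end orchestration: simulate/load -> tabulate -> partition -> contrasts -> trends.

``run_pipeline`` runs every analysis stage on one Lexis grid and returns a
JSON-serialisable report: the eligibility partition counts, the eligible and
too-old mortality rate ratios, the double-difference net mortality effect,
band-wise stage 2-4 annual changes, the 14 year-specific matched rate
ratios, and the conditional-Poisson net-deficit model, together with a
provenance block (config hash, seed, library versions).  Given a fixed seed
the report is idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contrasts import double_difference, grid_strata, mh_rate_ratio
from .grid import GridSpec, LexisGrid, partition_cells
from .registry import build_grid, read_registry, read_women_years
from .simulate import SimulationConfig, simulate
from .trends import band_annual_change, fit_conditional_poisson, table1_bands, yearly_mh_ratios

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyse_grid"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for a full reproduce-all run.

    Either ``records_path``/``women_years_path`` point at existing registry
    files, or (when both are None) a synthetic registry is simulated from
    ``simulation`` with ``seed``.
    """

    seed: int = 17
    records_path: str | None = None
    women_years_path: str | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    cutoff_age: int = 64
    reference_year: int = 2000
    participation: float = 0.70
    time_basis: str = "quadratic"
    trend_years: tuple[int, int] = (2000, 2007)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not 0 < self.participation <= 1:
            raise ValueError("participation must lie in (0, 1]")
        if self.time_basis not in ("constant", "linear", "quadratic"):
            raise ValueError(f"unknown time basis {self.time_basis!r}")
        for path in (self.records_path, self.women_years_path):
            if path is not None and not Path(path).exists():
                raise ValueError(f"input file not found: {path}")
        if (self.records_path is None) != (self.women_years_path is None):
            raise ValueError("records and women-years paths must be given together")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "grid" in kwargs:
            kwargs["grid"] = GridSpec(**kwargs["grid"])
        if "simulation" in kwargs:
            sim = dict(kwargs["simulation"])
            if "spec" in sim:
                sim["spec"] = GridSpec(**sim["spec"])
            elif "grid" in kwargs:
                sim["spec"] = kwargs["grid"]
            kwargs["simulation"] = SimulationConfig(**sim)
        elif "grid" in kwargs:
            kwargs["simulation"] = SimulationConfig(spec=kwargs["grid"])
        if "trend_years" in kwargs:
            kwargs["trend_years"] = tuple(kwargs["trend_years"])
        return cls(**kwargs)

    def digest(self) -> str:
        canon = json.dumps(_jsonable(self.__dict__), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return _jsonable(vars(obj))
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(vars(obj))
    return obj


def _rr_dict(rr) -> dict:
    return {
        "estimate": rr.estimate,
        "rounded": rr.rounded,
        "log_variance": rr.log_variance,
        "log_variance_approx": rr.log_variance_approx,
        "ci95": list(rr.ci95),
        "D1": rr.D1,
        "D0": rr.D0,
        "n_strata": rr.n_strata,
    }


def analyse_grid(
    grid: LexisGrid,
    cutoff_age: int = 64,
    reference_year: int = 2000,
    participation: float = 0.70,
    time_basis: str = "quadratic",
    trend_years: tuple[int, int] = (2000, 2007),
) -> dict:
    """All analysis stages on one tabulated Lexis grid; returns the report body."""
    partition = partition_cells(grid.spec, cutoff_age, reference_year)
    report: dict = {
        "partition": {
            "eligible_cells": partition.n_eligible,
            "too_old_cells": partition.n_too_old,
            "total_cells": grid.spec.n_cells,
        }
    }

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    rr_eligible = stage(
        "mortality_contrast_eligible",
        lambda: mh_rate_ratio(grid_strata(grid, partition.eligible, "deaths")),
    )
    rr_background = stage(
        "mortality_contrast_background",
        lambda: mh_rate_ratio(grid_strata(grid, partition.too_old, "deaths")),
    )
    net = stage(
        "double_difference",
        lambda: double_difference(rr_eligible, rr_background, participation),
    )
    report["mortality"] = {
        "eligible": _rr_dict(rr_eligible),
        "background": _rr_dict(rr_background),
        "net": {
            "net_ratio": net.net_ratio,
            "log_variance": net.log_variance,
            "ci95": list(net.ci95),
            "percent_reduction": net.percent_reduction,
            "percent_reduction_ci95": list(net.percent_reduction_ci95),
            "deaths_averted": net.deaths_averted,
            "participation": net.participation,
            "efficacy_estimate": net.efficacy_estimate,
        },
    }

    rr24_eligible = stage(
        "stage24_contrast_eligible",
        lambda: mh_rate_ratio(grid_strata(grid, partition.eligible, "stage24_cases")),
    )
    rr24_background = stage(
        "stage24_contrast_background",
        lambda: mh_rate_ratio(grid_strata(grid, partition.too_old, "stage24_cases")),
    )
    report["stage24"] = {
        "eligible": _rr_dict(rr24_eligible),
        "background": _rr_dict(rr24_background),
        "net_ratio": rr24_eligible.estimate / rr24_background.estimate,
    }

    def bands():
        out = {}
        for band in table1_bands(grid.spec, *trend_years):
            row = {}
            for region in (1, 2):
                try:
                    row[f"region{region}_percent_per_year"] = band_annual_change(
                        grid, region, band
                    )
                except (ValueError, RuntimeError) as exc:
                    row[f"region{region}_percent_per_year"] = None
                    logger.warning("band %s region %d: %s", band.name, region, exc)
            out[f"{band.kind}:{band.name}"] = row
        return out

    report["band_trends"] = stage("band_trends", bands)

    yearly = stage("yearly_ratios", lambda: yearly_mh_ratios(grid, partition))
    report["yearly_stage24_ratios"] = {
        int(year): (None if rr is None else _rr_dict(rr))
        for year, rr in zip(grid.spec.years, yearly)
    }

    model = stage(
        "net_effect_model",
        lambda: fit_conditional_poisson(grid, partition, time_basis),
    )
    report["net_effect_model"] = {
        "background_log_rr": model.background_log_rr,
        "coefficients": list(model.coefficients),
        "coefficient_se": list(model.coefficient_se),
        "year_center": model.year_center,
        "time_basis": model.time_basis,
        "net_rr_by_year": dict(
            zip(map(int, model.years), map(float, model.net_rr_by_year))
        ),
        "deficit_by_year": dict(
            zip(map(int, model.years), map(float, model.deficit))
        ),
        "loglik": model.loglik,
        "null_loglik": model.null_loglik,
        "converged": model.converged,
        "n_cells": model.n_cells,
    }
    return report


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full pipeline and (optionally) write report + grid to out_dir."""
    config.validate()
    if config.records_path is not None:
        read = read_registry(config.records_path)
        records = read.records
        wy = read_women_years(config.women_years_path, config.grid)
        source = "files"
    else:
        records, wy = simulate(config.simulation, config.seed)
        source = "simulation"
    try:
        grid = build_grid(records, wy, config.grid)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("tabulate", exc) from exc

    report = analyse_grid(
        grid,
        cutoff_age=config.cutoff_age,
        reference_year=config.reference_year,
        participation=config.participation,
        time_basis=config.time_basis,
        trend_years=config.trend_years,
    )
    report["provenance"] = {
        "package": f"lexiscreen {__version__}",
        "numpy": np.__version__,
        "seed": config.seed,
        "input_source": source,
        "config_sha256_16": config.digest(),
        "n_records": len(records),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        grid.write_csv(out_dir / "grid.csv")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
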
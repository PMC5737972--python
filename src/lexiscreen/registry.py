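"""Registry-style incidence files: parsing, validation and Lexis tabulation.

An incidence file has one row per diagnosed woman: region of residence at
diagnosis, age and year of diagnosis, stage class, and (when she died during
follow-up) the death year and cause.  Tabulation implements incidence-based
mortality counting: a breast-cancer death enters the grid only if the
underlying cancer was diagnosed inside the study window, so that deaths from
pre-programme diagnoses — which no screening invitation could have
prevented — are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import REGIONS, GridSpec, LexisGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RegistryRecord",
    "RegistryReadResult",
    "read_registry",
    "write_registry",
    "tabulate_mortality",
    "tabulate_stage24",
    "read_women_years",
    "build_grid",
]

STAGE_CLASSES = ("stage1", "stage2_4", "unknown")

DEFAULT_COLUMNS = {
    "region": "region",
    "year_dx": "year_dx",
    "age_dx": "age_dx",
    "stage_class": "stage_class",
    "death_year": "death_year",
    "death_cause": "death_cause",
}


@dataclass(frozen=True)
class RegistryRecord:
    """One diagnosed woman, as recorded by a cancer registry."""

    region: int
    year_dx: int
    age_dx: int
    stage_class: str
    death_year: int | None = None
    death_cause: str | None = None

    def check(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.age_dx < 0:
            raise ValueError("age at diagnosis must be non-negative")
        if self.stage_class not in STAGE_CLASSES:
            raise ValueError(f"unknown stage class {self.stage_class!r}")
        if self.death_cause is not None and self.death_year is None:
            raise ValueError("death cause recorded without a death year")
        if self.death_year is not None and self.death_year < self.year_dx:
            raise ValueError("death year precedes diagnosis year")

    @property
    def age_at_death(self) -> int | None:
        """Age in the death year, assuming the cohort diagonal (year - age constant)."""
        if self.death_year is None:
            return None
        return self.age_dx + (self.death_year - self.year_dx)


@dataclass
class RegistryReadResult:
    records: list[RegistryRecord]
    rejected: list[tuple[int, str]]  # (1-based data row number, reason)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def _load_schema(schema_config) -> dict[str, str]:
    """Column mapping: canonical field -> file column name."""
    if schema_config is None:
        return dict(DEFAULT_COLUMNS)
    if isinstance(schema_config, (str, Path)):
        with open(schema_config) as fh:
            schema_config = yaml.safe_load(fh) or {}
    mapping = dict(DEFAULT_COLUMNS)
    columns = schema_config.get("columns", schema_config)
    unknown = set(columns) - set(DEFAULT_COLUMNS)
    if unknown:
        raise ValueError(f"schema maps unknown fields: {sorted(unknown)}")
    mapping.update(columns)
    return mapping


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_registry(path, schema_config=None) -> RegistryReadResult:
    """Parse an incidence file into records, rejecting invalid rows.

    Rows violating record invariants (negative age, death before diagnosis,
    unknown stage/region) are collected with their row number rather than
    aborting the parse; a missing mandatory column is a hard error.
    """
    mapping = _load_schema(schema_config)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=object)
    mandatory = ["region", "year_dx", "age_dx", "stage_class"]
    missing = [mapping[f] for f in mandatory if mapping[f] not in frame.columns]
    if missing:
        raise ValueError(f"mandatory columns missing from {path}: {missing}")

    records: list[RegistryRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        try:
            death_year = row.get(mapping["death_year"])
            death_cause = row.get(mapping["death_cause"])
            if isinstance(death_cause, float) and np.isnan(death_cause):
                death_cause = None
            record = RegistryRecord(
                region=int(row[mapping["region"]]),
                year_dx=int(row[mapping["year_dx"]]),
                age_dx=int(row[mapping["age_dx"]]),
                stage_class=str(row[mapping["stage_class"]]),
                death_year=None if death_year in (None, "") or pd.isna(death_year)
                else int(float(death_year)),
                death_cause=None if death_cause in (None, "") or pd.isna(death_cause)
                else str(death_cause),
            )
            record.check()
        except (ValueError, TypeError, KeyError) as exc:
            rejected.append((i, str(exc)))
            continue
        records.append(record)
    if rejected:
        logger.warning("rejected %d of %d rows in %s", len(rejected), len(frame), path)
    return RegistryReadResult(records, rejected)


def write_registry(records, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "region": r.region,
                "year_dx": r.year_dx,
                "age_dx": r.age_dx,
                "stage_class": r.stage_class,
                "death_year": r.death_year,
                "death_cause": r.death_cause,
            }
            for r in records
        ],
        columns=list(DEFAULT_COLUMNS),
    )
    frame.to_csv(path, sep=_sep_for(path), index=False)


def tabulate_mortality(
    records,
    spec: GridSpec | None = None,
    dx_year_min: int = 2000,
    dx_age_min: int = 50,
    death_age_range: tuple[int, int] = (50, 84),
    followup_end: int | None = None,
):
    """Incidence-based breast-cancer death counts on the Lexis grid.

    A death contributes +1 to cell (age at death, death year) of its region
    iff the cause is breast cancer, the cancer was diagnosed in
    ``dx_year_min`` or later at age ``dx_age_min`` or older, the death year
    lies within the grid/follow-up window, and the age at death lies in
    ``death_age_range``.  Returns ``(deaths array, exclusion log)`` where the
    log counts excluded deaths by reason.
    """
    spec = spec if spec is not None else GridSpec()
    followup_end = spec.year_max if followup_end is None else followup_end
    deaths = np.zeros((spec.n_ages, spec.n_years, len(REGIONS)))
    excluded = {
        "not_breast_cancer_death": 0,
        "pre_programme_diagnosis": 0,
        "diagnosis_below_age_window": 0,
        "death_outside_followup": 0,
        "death_age_outside_window": 0,
    }
    for r in records:
        if r.death_year is None or r.death_cause != "breast_cancer":
            if r.death_year is not None:
                excluded["not_breast_cancer_death"] += 1
            continue
        if r.year_dx < dx_year_min:
            excluded["pre_programme_diagnosis"] += 1
            continue
        if r.age_dx < dx_age_min:
            excluded["diagnosis_below_age_window"] += 1
            continue
        if not (spec.year_min <= r.death_year <= followup_end):
            excluded["death_outside_followup"] += 1
            continue
        age = r.age_at_death
        if not (death_age_range[0] <= age <= death_age_range[1]) or not spec.contains(
            age, r.death_year
        ):
            excluded["death_age_outside_window"] += 1
            continue
        i, j = spec.index(age, r.death_year)
        deaths[i, j, REGIONS.index(r.region)] += 1
    return deaths, excluded


def tabulate_stage24(records, spec: GridSpec | None = None):
    """Stage 2-4 diagnosis counts per Lexis cell.

    Records with unknown stage are excluded (not imputed) and counted in the
    returned log, as are diagnoses falling outside the grid.
    """
    spec = spec if spec is not None else GridSpec()
    cases = np.zeros((spec.n_ages, spec.n_years, len(REGIONS)))
    excluded = {"stage_unknown": 0, "outside_grid": 0, "stage1": 0}
    for r in records:
        if r.stage_class == "unknown":
            excluded["stage_unknown"] += 1
            continue
        if r.stage_class == "stage1":
            excluded["stage1"] += 1
            continue
        if not spec.contains(r.age_dx, r.year_dx):
            excluded["outside_grid"] += 1
            continue
        i, j = spec.index(r.age_dx, r.year_dx)
        cases[i, j, REGIONS.index(r.region)] += 1
    return cases, excluded


def read_women_years(path, spec: GridSpec | None = None) -> np.ndarray:
    """Read a long-format person-time table (age, year, region, women_years)."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    return women_years_array(frame, spec)


def women_years_array(frame: pd.DataFrame, spec: GridSpec | None = None) -> np.ndarray:
    spec = spec if spec is not None else GridSpec()
    needed = {"age", "year", "region", "women_years"}
    if not needed <= set(frame.columns):
        raise ValueError(f"person-time table must have columns {sorted(needed)}")
    if frame["women_years"].isna().any():
        raise ValueError("missing person-time is not allowed")
    wy = np.zeros((spec.n_ages, spec.n_years, len(REGIONS)))
    for row in frame.itertuples(index=False):
        if spec.contains(int(row.age), int(row.year)):
            i, j = spec.index(int(row.age), int(row.year))
            wy[i, j, REGIONS.index(int(row.region))] = row.women_years
    return wy


def build_grid(records, women_years, spec: GridSpec | None = None) -> LexisGrid:
    """Tabulate records and combine with a person-time table into a LexisGrid."""
    spec = spec if spec is not None else GridSpec()
    deaths, death_log = tabulate_mortality(records, spec)
    cases, case_log = tabulate_stage24(records, spec)
    if isinstance(women_years, pd.DataFrame):
        women_years = women_years_array(women_years, spec)
    grid = LexisGrid(spec, deaths=deaths, stage24_cases=cases, women_years=women_years)
    logger.info("tabulation exclusions: deaths=%s, stage=%s", death_log, case_log)
    return grid
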
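"""Stage 2-4 incidence trend models.

Three views of the stage-shift signal left by screening:

* within-region annual percent changes from log-linear Poisson fits over
  5-year-wide bands of Lexis cells, grouped either by attained age
  (horizontal bands) or by birth cohort (diagonal bands — following women
  into subsequent age bands, where the delayed effects of screening at the
  upper invitation ages actually appear);
* between-region year-specific Mantel-Haenszel rate ratios matched on
  attained age;
* a smooth-in-time conditional Poisson model.  Conditioning on the total
  number of stage 2-4 cases in a cell makes the region-1 share binomial,
  ``n1_ay ~ Binomial(n_ay, p_ay)`` with
  ``logit p_ay = log(T1/T0) + background_log_rr + log netRR(y)``,
  where the background log rate ratio is estimated from the too-old cells
  and ``log netRR(y)`` is a polynomial in (centred) calendar year.  One
  minus ``netRR(y)`` is the fraction of the stage 2-4 cases expected in
  year y that screening had already removed to an earlier year and stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .contrasts import RateRatioResult, mh_rate_ratio
from .grid import EligibilityPartition, GridSpec, LexisGrid

__all__ = [
    "TrendBand",
    "NetEffectModel",
    "annual_change",
    "band_annual_change",
    "table1_bands",
    "yearly_mh_ratios",
    "fit_conditional_poisson",
]

TIME_BASES = ("constant", "linear", "quadratic")


@dataclass(frozen=True)
class TrendBand:
    """A band of Lexis cells over which a within-region trend is fitted."""

    kind: str  # "attained_age" | "birth_cohort"
    name: str
    spec: GridSpec
    mask: np.ndarray = field(repr=False)  # bool, (n_ages, n_years)

    @classmethod
    def attained_age(cls, spec: GridSpec, age_lo: int, age_hi: int,
                     year_lo: int, year_hi: int) -> "TrendBand":
        """Horizontal band: ages in [age_lo, age_hi] across the given years."""
        a = spec.ages[:, None]
        y = spec.years[None, :]
        mask = (a >= age_lo) & (a <= age_hi) & (y >= year_lo) & (y <= year_hi)
        return cls("attained_age", f"ages {age_lo}-{age_hi}", spec, mask)

    @classmethod
    def birth_cohort(cls, spec: GridSpec, ref_age_lo: int, ref_age_hi: int,
                     year_lo: int, year_hi: int,
                     reference_year: int = 2000) -> "TrendBand":
        """Diagonal band: cohorts aged [ref_age_lo, ref_age_hi] at the
        reference year, followed along their diagonals across the years."""
        a = spec.ages[:, None]
        y = spec.years[None, :]
        ref_age = a - (y - reference_year)
        mask = ((ref_age >= ref_age_lo) & (ref_age <= ref_age_hi)
                & (y >= year_lo) & (y <= year_hi))
        return cls("birth_cohort",
                   f"aged {ref_age_lo}-{ref_age_hi} in {reference_year}", spec, mask)


def table1_bands(spec: GridSpec | None = None,
                 year_lo: int = 2000, year_hi: int = 2007) -> list[TrendBand]:
    """The seven default pre-rollout bands: three 5-year attained-age bands
    within the invitation window, three 5-cohort diagonal bands, and the
    diagonal band of cohorts reaching age 50 in 2001-2005 (cohorts reaching
    50 in 2006-2007 are omitted as too briefly observed)."""
    spec = spec if spec is not None else GridSpec()
    bands = [
        TrendBand.attained_age(spec, 50, 54, year_lo, year_hi),
        TrendBand.attained_age(spec, 55, 59, year_lo, year_hi),
        TrendBand.attained_age(spec, 60, 64, year_lo, year_hi),
        TrendBand.birth_cohort(spec, 50, 54, year_lo, year_hi),
        TrendBand.birth_cohort(spec, 55, 59, year_lo, year_hi),
        TrendBand.birth_cohort(spec, 60, 64, year_lo, year_hi),
        TrendBand.birth_cohort(spec, 45, 49, year_lo, year_hi),
    ]
    return bands


def annual_change(counts, years, exposure) -> float:
    """Annual percent change from a log-linear Poisson fit.

    Maximises the Poisson likelihood of ``log E[count] = a + b*year +
    log(exposure)`` and returns ``100 * (exp(b) - 1)``.  Invariant to
    rescaling all exposures by a positive constant.
    """
    counts = np.asarray(counts, dtype=float)
    years = np.asarray(years, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    keep = exposure > 0
    counts, years, exposure = counts[keep], years[keep], exposure[keep]
    if np.unique(years).size < 2:
        raise ValueError("trend needs at least 2 distinct years with person-time")
    if counts.sum() == 0:
        raise ValueError("trend undefined: all counts zero")
    X = np.column_stack([np.ones_like(years), years - years.mean()])
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=np.log(exposure))
    result = model.fit()
    if not result.converged:
        raise RuntimeError(f"Poisson trend did not converge: {result.mle_retvals}")
    return float(100.0 * np.expm1(result.params[1]))


def band_annual_change(grid: LexisGrid, region: int, band: TrendBand) -> float:
    """Annual percent change in stage 2-4 incidence within one band and region."""
    if not band.mask.any():
        raise ValueError("band contains no cells")
    k = region - 1
    years = np.broadcast_to(grid.spec.years[None, :], band.mask.shape)[band.mask]
    counts = grid.stage24_cases[..., k][band.mask]
    wy = grid.women_years[..., k][band.mask]
    return annual_change(counts, years, wy)


def yearly_mh_ratios(
    grid: LexisGrid, partition: EligibilityPartition, event: str = "stage24_cases"
) -> list[RateRatioResult | None]:
    """Year-specific between-region rate ratios matched on attained age.

    For each study year, a Mantel-Haenszel summary over that year's eligible
    cells, each age being one stratum.  A year with no events (or an
    otherwise undefined ratio) yields ``None`` rather than an error.
    """
    counts = getattr(grid, event)
    results: list[RateRatioResult | None] = []
    for j in range(grid.spec.n_years):
        rows = partition.eligible[:, j]
        strata = np.column_stack(
            [
                counts[rows, j, 0],
                grid.women_years[rows, j, 0],
                counts[rows, j, 1],
                grid.women_years[rows, j, 1],
            ]
        )
        try:
            results.append(mh_rate_ratio(strata))
        except ValueError:
            results.append(None)
    return results


@dataclass(frozen=True)
class NetEffectModel:
    """Fitted conditional-Poisson net stage 2-4 rate-ratio model.

    ``log netRR(y) = b0 + b1*(y - year_center) + b2*(y - year_center)^2``,
    on top of a fixed background log rate ratio estimated from the too-old
    cells.  ``deficit`` is ``1 - netRR(y)`` per study year: the fraction of
    the initial stage 2-4 "target" already detected earlier, at stage 1.
    """

    background_log_rr: float
    coefficients: tuple[float, float, float]  # (b0, b1, b2); zeros if unused
    coefficient_se: tuple[float, float, float]
    year_center: float
    years: np.ndarray
    net_rr_by_year: np.ndarray
    loglik: float
    null_loglik: float
    converged: bool
    time_basis: str
    n_cells: int

    def net_rr(self, year) -> np.ndarray:
        yc = np.asarray(year, dtype=float) - self.year_center
        b0, b1, b2 = self.coefficients
        return np.exp(b0 + b1 * yc + b2 * yc**2)

    @property
    def deficit(self) -> np.ndarray:
        return 1.0 - self.net_rr_by_year


def _binomial_cells(grid: LexisGrid, mask: np.ndarray):
    """(n1, n0, log T1/T0, year) for masked cells with at least one event."""
    n1 = grid.stage24_cases[..., 0][mask]
    n0 = grid.stage24_cases[..., 1][mask]
    T1 = grid.women_years[..., 0][mask]
    T0 = grid.women_years[..., 1][mask]
    years = np.broadcast_to(grid.spec.years[None, :], mask.shape)[mask]
    has_events = (n1 + n0) > 0
    if np.any(has_events & ((T1 <= 0) | (T0 <= 0))):
        raise ValueError("cells with events must have positive person-time in both regions")
    n1, n0, T1, T0, years = (a[has_events] for a in (n1, n0, T1, T0, years))
    return n1, n0, np.log(T1 / T0), years


def _fit_binomial(n1, n0, offset, X):
    model = sm.GLM(np.column_stack([n1, n0]), X,
                   family=sm.families.Binomial(), offset=offset)
    result = model.fit(tol=1e-10, maxiter=200)
    if not result.converged:
        raise RuntimeError("conditional Poisson fit did not converge")
    return model, result


def fit_conditional_poisson(
    grid: LexisGrid,
    partition: EligibilityPartition,
    time_basis: str = "quadratic",
    year_center: float | None = None,
    background_log_rr: float | None = None,
) -> NetEffectModel:
    """Two-step conditional-Poisson fit of the net stage 2-4 rate ratio.

    Step 1 estimates the background log rate ratio from the too-old cells
    (constant model, no net term); a known value can be supplied instead via
    ``background_log_rr``.  Step 2 plugs it in as a fixed offset and
    maximises the binomial likelihood of the region-1 case share over the
    eligible cells, with ``log netRR(y)`` constant, linear or quadratic in
    centred calendar year.
    """
    if time_basis not in TIME_BASES:
        raise ValueError(f"time_basis must be one of {TIME_BASES}")
    spec = grid.spec
    if year_center is None:
        year_center = (spec.year_min + spec.year_max) / 2.0

    if background_log_rr is not None:
        background = float(background_log_rr)
    else:
        # step 1: background regional difference from cells screening cannot touch
        n1b, n0b, off_b, _ = _binomial_cells(grid, partition.too_old)
        if n1b.size == 0:
            raise ValueError("no events in too-old cells: background ratio inestimable")
        if n1b.sum() == 0 or n0b.sum() == 0:
            raise ValueError("separation in too-old cells: all events in one region")
        _, res_b = _fit_binomial(n1b, n0b, off_b, np.ones((n1b.size, 1)))
        background = float(res_b.params[0])

    # step 2: net effect over the eligible cells
    n1, n0, off, years = _binomial_cells(grid, partition.eligible)
    if n1.size == 0:
        raise ValueError("no events in eligible cells")
    if n1.sum() == 0 or n0.sum() == 0:
        raise ValueError("separation: all eligible-cell events in one region")
    yc = years - year_center
    ncoef = TIME_BASES.index(time_basis) + 1
    X = np.column_stack([np.ones_like(yc), yc, yc**2])[:, :ncoef]
    model, result = _fit_binomial(n1, n0, off + background, X)

    params = np.zeros(3)
    params[:ncoef] = result.params
    se = np.zeros(3)
    se[:ncoef] = result.bse
    yc_all = spec.years - year_center
    net_rr = np.exp(params[0] + params[1] * yc_all + params[2] * yc_all**2)
    return NetEffectModel(
        background_log_rr=background,
        coefficients=tuple(params),
        coefficient_se=tuple(se),
        year_center=float(year_center),
        years=spec.years.copy(),
        net_rr_by_year=net_rr,
        loglik=float(model.loglike(result.params)),
        null_loglik=float(model.loglike(np.zeros(ncoef))),
        converged=bool(result.converged),
        time_basis=time_basis,
        n_cells=int(n1.size),
    )
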
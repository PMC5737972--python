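"""Stratified rate-ratio contrasts between two regions on a Lexis grid.

The estimator chain is the classical one for person-time data:

* a Mantel-Haenszel summary rate ratio over age-year cell strata,
  ``RR_MH = [sum_i d1_i T0_i / T_i] / [sum_i d0_i T1_i / T_i]``;
* the Breslow-Day variance of its log,
  ``var(log RR_MH) = [sum_i d_i T1_i T0_i / T_i^2] / (R * S)``
  with ``R`` and ``S`` the MH numerator and denominator sums, which for
  near-balanced person-time is well approximated by ``1/D1 + 1/D0``;
* a double difference — the ratio of the eligible-cohort rate ratio to the
  too-old ("background") rate ratio — whose log-variance is the sum of the
  two component log-variances, approximated by the Woolf-like sum of
  reciprocal death counts.

The double difference isolates the effect attributable to one region's
earlier access to screening, net of background regional differences in
incidence and treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateRatioResult",
    "DoubleDifferenceResult",
    "mh_rate_ratio",
    "woolf_variance",
    "ratio_ci",
    "double_difference",
    "grid_strata",
]

Z95 = 1.96  # fixed normal quantile for 95% intervals


def ratio_ci(estimate: float, log_variance: float, z: float = Z95) -> tuple[float, float]:
    """95% CI for a ratio from the variance of its log."""
    half = z * np.sqrt(log_variance)
    return float(estimate * np.exp(-half)), float(estimate * np.exp(half))


@dataclass(frozen=True)
class RateRatioResult:
    """A summary rate ratio with its log-scale variance and 95% CI.

    ``D1`` and ``D0`` are the total event counts in regions 1 and 2 over the
    contributing strata; ``log_variance_approx`` is the reciprocal-counts
    approximation ``1/D1 + 1/D0``.
    """

    estimate: float
    log_variance: float
    ci95: tuple[float, float]
    D1: float
    D0: float
    n_strata: int
    log_variance_approx: float
    n_dropped: int = 0

    @property
    def rounded(self) -> float:
        """Estimate rounded to two decimals, the display convention."""
        return round(self.estimate, 2)


@dataclass(frozen=True)
class DoubleDifferenceResult:
    """Net effect of earlier screening: a ratio of rate ratios.

    ``percent_reduction`` is ``100 * (1 - net_ratio)`` — the
    invitation-to-screen (intention-to-treat) reduction.
    ``efficacy_estimate`` rescales it by the participation fraction to the
    reduction expected among full participants.  ``deaths_averted`` converts
    the proportional reduction into an absolute count using the later
    region's eligible-cohort deaths as the reference.
    """

    net_ratio: float
    log_variance: float
    ci95: tuple[float, float]
    percent_reduction: float
    percent_reduction_ci95: tuple[float, float]
    deaths_averted: float
    participation: float
    efficacy_estimate: float


def _strata_arrays(strata):
    arr = np.atleast_2d(np.asarray(strata, dtype=float))
    if arr.shape[1] != 4:
        raise ValueError("each stratum must be (d1, T1, d0, T0)")
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


def mh_rate_ratio(strata) -> RateRatioResult:
    """Mantel-Haenszel summary rate ratio over person-time strata.

    ``strata`` is an iterable of ``(d1, T1, d0, T0)`` tuples (or an
    equivalent (n, 4) array): events and person-time in region 1 and
    region 2 for each stratum.  Strata with zero total person-time are
    dropped (their number is reported in ``n_dropped``).
    """
    d1, T1, d0, T0 = _strata_arrays(strata)
    if np.any(d1 < 0) or np.any(d0 < 0) or np.any(T1 < 0) or np.any(T0 < 0):
        raise ValueError("negative events or person-time")
    T = T1 + T0
    keep = T > 0
    n_dropped = int((~keep).sum())
    d1, T1, d0, T0, T = d1[keep], T1[keep], d0[keep], T0[keep], T[keep]
    if d1.size == 0 or (d1.sum() + d0.sum()) == 0:
        raise ValueError("rate ratio undefined: no events in any stratum")

    numer = float(np.sum(d1 * T0 / T))  # R
    denom = float(np.sum(d0 * T1 / T))  # S
    if denom == 0:
        raise ValueError("rate ratio undefined: Mantel-Haenszel denominator is zero")
    if numer == 0:
        raise ValueError("rate ratio undefined: Mantel-Haenszel numerator is zero")
    estimate = numer / denom
    log_variance = float(np.sum((d1 + d0) * T1 * T0 / T**2)) / (numer * denom)
    D1, D0 = float(d1.sum()), float(d0.sum())
    approx = (1.0 / D1 if D1 > 0 else np.inf) + (1.0 / D0 if D0 > 0 else np.inf)
    return RateRatioResult(
        estimate=estimate,
        log_variance=log_variance,
        ci95=ratio_ci(estimate, log_variance),
        D1=D1,
        D0=D0,
        n_strata=int(d1.size),
        log_variance_approx=approx,
        n_dropped=n_dropped,
    )


def woolf_variance(D1: float, D0: float, D1p: float, D0p: float) -> float:
    """Woolf-like variance of the log ratio of rate ratios.

    The sum of reciprocal event counts over the four cells of the double
    difference: ``1/D1 + 1/D0 + 1/D1' + 1/D0'``.  Its magnitude — hence the
    CI width — is dominated by the smallest count.
    """
    counts = (D1, D0, D1p, D0p)
    if any(c <= 0 for c in counts):
        raise ValueError("Woolf-like variance undefined with a zero event count")
    return float(sum(1.0 / c for c in counts))


def double_difference(
    rr_eligible: RateRatioResult,
    rr_background: RateRatioResult,
    participation: float = 0.70,
) -> DoubleDifferenceResult:
    """Net screening effect: eligible-cohort rate ratio over background ratio.

    The log-variance of the net ratio is the sum of the two component
    Breslow-Day log-variances.  ``participation`` (fraction of invitees who
    attend) de-attenuates the invitation-to-screen reduction into an
    efficacy estimate for full participants.
    """
    if not 0 < participation <= 1:
        raise ValueError("participation must lie in (0, 1]")
    if rr_background.estimate <= 0:
        raise ValueError("background rate ratio must be positive")
    net = rr_eligible.estimate / rr_background.estimate
    log_variance = rr_eligible.log_variance + rr_background.log_variance
    ci = ratio_ci(net, log_variance)
    reduction = 100.0 * (1.0 - net)
    reduction_ci = (100.0 * (1.0 - ci[1]), 100.0 * (1.0 - ci[0]))
    return DoubleDifferenceResult(
        net_ratio=net,
        log_variance=log_variance,
        ci95=ci,
        percent_reduction=reduction,
        percent_reduction_ci95=reduction_ci,
        deaths_averted=(1.0 - net) * rr_eligible.D0,
        participation=participation,
        efficacy_estimate=reduction / participation,
    )


def grid_strata(grid, mask: np.ndarray, event: str = "deaths") -> np.ndarray:
    """Extract (d1, T1, d0, T0) strata from a LexisGrid for the masked cells.

    Each True cell of ``mask`` (shape (n_ages, n_years)) becomes one stratum.
    ``event`` selects the count surface: "deaths" or "stage24_cases".
    """
    counts = getattr(grid, event)
    wy = grid.women_years
    return np.column_stack(
        [counts[mask, 0], wy[mask, 0], counts[mask, 1], wy[mask, 1]]
    )
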
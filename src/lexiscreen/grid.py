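"""Lexis-grid geometry: cells, cohorts, eligibility polygons and invitation schedules.

A Lexis diagram is an (age x calendar-year) grid on which a birth cohort
travels along a diagonal: the cohort index ``c = year - age`` is constant
along that diagonal.  All analyses in this package are carried out on
1-year x 1-year cells, half-open ``[a, a+1) x [y, y+1)``, with age measured
in completed years at the start of the calendar year.

The central geometric object for a staggered screening rollout is the split
of the grid into an *eligible* polygon (cohorts young enough at the reference
year to ever be invited) and a *too-old* polygon (cohorts already past the
upper invitation age at the reference year).  The too-old cells carry no
screening signal and serve as a contemporaneous control for background
regional differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import convolve2d

__all__ = [
    "GridSpec",
    "LexisCell",
    "LexisGrid",
    "EligibilityPartition",
    "InvitationSchedule",
    "partition_cells",
    "invitation_ages",
    "smooth_3x3",
]

REGIONS = (1, 2)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular Lexis grid: inclusive age and calendar-year ranges.

    Defaults cover attained ages 50-85 (36 rows) over the study years
    2000-2013 (14 columns), i.e. 504 cells.
    """

    age_min: int = 50
    age_max: int = 85
    year_min: int = 2000
    year_max: int = 2013

    def __post_init__(self) -> None:
        if self.age_max < self.age_min or self.year_max < self.year_min:
            raise ValueError("empty grid: max bound below min bound")

    @property
    def n_ages(self) -> int:
        return self.age_max - self.age_min + 1

    @property
    def n_years(self) -> int:
        return self.year_max - self.year_min + 1

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_min, self.year_max + 1)

    @property
    def n_cells(self) -> int:
        return self.n_ages * self.n_years

    def contains(self, age: int, year: int) -> bool:
        return (self.age_min <= age <= self.age_max
                and self.year_min <= year <= self.year_max)

    def index(self, age: int, year: int) -> tuple[int, int]:
        """(row, col) index of cell (age, year); raises if outside the grid."""
        if not self.contains(age, year):
            raise KeyError(f"cell (age={age}, year={year}) outside grid")
        return age - self.age_min, year - self.year_min


@dataclass(frozen=True)
class LexisCell:
    """One 1x1 Lexis cell. The cohort index ``year - age`` labels its diagonal."""

    age: int
    year: int

    @property
    def cohort(self) -> int:
        return self.year - self.age


class LexisGrid:
    """Event counts and person-time per (age, year, region) cell.

    Arrays are shaped ``(n_ages, n_years, 2)`` with the third axis indexing
    region 1 and region 2.  ``deaths`` holds incidence-based breast-cancer
    death counts, ``stage24_cases`` counts of stage 2-4 diagnoses, and
    ``women_years`` the exposure denominator (unit recorded in ``wy_unit``).
    """

    def __init__(
        self,
        spec: GridSpec | None = None,
        deaths: np.ndarray | None = None,
        stage24_cases: np.ndarray | None = None,
        women_years: np.ndarray | None = None,
        wy_unit: str = "women-years",
    ) -> None:
        self.spec = spec if spec is not None else GridSpec()
        shape = (self.spec.n_ages, self.spec.n_years, len(REGIONS))
        self.deaths = self._coerce(deaths, shape, integer=True)
        self.stage24_cases = self._coerce(stage24_cases, shape, integer=True)
        self.women_years = self._coerce(women_years, shape, integer=False)
        self.wy_unit = wy_unit
        self.validate()

    @staticmethod
    def _coerce(arr: np.ndarray | None, shape, integer: bool) -> np.ndarray:
        if arr is None:
            return np.zeros(shape)
        arr = np.asarray(arr, dtype=float)
        if arr.shape != shape:
            raise ValueError(f"array shape {arr.shape} != grid shape {shape}")
        return arr.copy()

    def validate(self) -> None:
        for name in ("deaths", "stage24_cases"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
        if np.any(self.women_years < 0):
            raise ValueError("women_years contains negative values")
        empty = self.women_years == 0
        if np.any((self.deaths[empty] > 0) | (self.stage24_cases[empty] > 0)):
            raise ValueError("cells with zero women-years must have zero counts")

    # -- long-format serialization ------------------------------------------

    COLUMNS = ["age", "year", "region", "deaths", "stage24_cases", "women_years"]

    def to_frame(self) -> pd.DataFrame:
        spec = self.spec
        age, year, region = np.meshgrid(
            spec.ages, spec.years, np.array(REGIONS), indexing="ij"
        )
        return pd.DataFrame(
            {
                "age": age.ravel(),
                "year": year.ravel(),
                "region": region.ravel(),
                "deaths": self.deaths.ravel().astype(int),
                "stage24_cases": self.stage24_cases.ravel().astype(int),
                "women_years": self.women_years.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, wy_unit: str = "women-years") -> "LexisGrid":
        missing = set(cls.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"grid table missing columns: {sorted(missing)}")
        if frame["women_years"].isna().any():
            raise ValueError("missing person-time is not allowed")
        spec = GridSpec(
            int(frame["age"].min()), int(frame["age"].max()),
            int(frame["year"].min()), int(frame["year"].max()),
        )
        grid = cls(spec, wy_unit=wy_unit)
        for row in frame.itertuples(index=False):
            i, j = spec.index(int(row.age), int(row.year))
            k = REGIONS.index(int(row.region))
            grid.deaths[i, j, k] = row.deaths
            grid.stage24_cases[i, j, k] = row.stage24_cases
            grid.women_years[i, j, k] = row.women_years
        grid.validate()
        return grid

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LexisGrid":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class EligibilityPartition:
    """Partition of a Lexis grid into eligible and too-old polygons.

    A cell (a, y) is *eligible* iff the cohort occupying it was at most
    ``cutoff_age`` in ``reference_year``, i.e. ``a - (y - reference_year)
    <= cutoff_age``; otherwise it is *too old*.  With the default 36 x 14
    grid, cutoff 64 and reference year 2000 this yields 301 eligible and
    203 too-old cells.
    """

    spec: GridSpec
    cutoff_age: int
    reference_year: int
    eligible: np.ndarray = field(repr=False)  # bool, (n_ages, n_years)

    @property
    def too_old(self) -> np.ndarray:
        return ~self.eligible

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())

    @property
    def n_too_old(self) -> int:
        return int(self.too_old.sum())

    def label(self, age: int, year: int) -> str:
        i, j = self.spec.index(age, year)
        return "eligible" if self.eligible[i, j] else "too_old"


def partition_cells(
    spec: GridSpec | None = None,
    cutoff_age: int = 64,
    reference_year: int = 2000,
) -> EligibilityPartition:
    """Classify every grid cell as screening-eligible or too old.

    The rule follows cohort diagonals: age in the reference year is
    ``a - (y - reference_year)``, and a cell is eligible iff that age does
    not exceed ``cutoff_age``.
    """
    spec = spec if spec is not None else GridSpec()
    if not spec.year_min <= reference_year <= spec.year_max:
        raise ValueError(
            f"reference year {reference_year} outside grid years "
            f"[{spec.year_min}, {spec.year_max}]"
        )
    age = spec.ages[:, None]
    year = spec.years[None, :]
    eligible = (age - (year - reference_year)) <= cutoff_age
    return EligibilityPartition(spec, cutoff_age, reference_year, eligible)


@dataclass(frozen=True)
class InvitationSchedule:
    """A region's screening invitation programme.

    Invitations go out every ``interval`` years starting in
    ``first_round_year`` to women whose attained age lies in
    ``[age_min, age_max]``.  A woman still under ``age_min`` at the first
    round is first invited in the calendar year she reaches ``age_min``
    and follows her own ``interval``-year clock thereafter.
    """

    first_round_year: int
    interval: int = 2
    age_min: int = 50
    age_max: int = 64
    last_followup_year: int = 2013

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("interval must be >= 1 year")
        if self.age_min > self.age_max:
            raise ValueError("invitation age window is empty")


def invitation_ages(
    age_at_reference: int,
    schedule: InvitationSchedule,
    reference_year: int = 2000,
) -> list[int]:
    """Ages at which a birth cohort is invited to screening.

    ``age_at_reference`` is the cohort's completed age in ``reference_year``
    (it may lie outside the grid, and may exceed the invitation window, in
    which case the list is empty).
    """
    if age_at_reference < 0:
        raise ValueError("cohort age must be non-negative")
    age_at_first_round = age_at_reference + (schedule.first_round_year - reference_year)
    if age_at_first_round >= schedule.age_min:
        start = schedule.first_round_year
    else:
        # personal clock: first invited the year she reaches the lower age bound
        start = schedule.first_round_year + (schedule.age_min - age_at_first_round)
    ages = []
    year = start
    while year <= schedule.last_followup_year:
        age = age_at_reference + (year - reference_year)
        if age > schedule.age_max:
            break
        if age >= schedule.age_min:
            ages.append(age)
        year += schedule.interval
    return ages


def invitation_counts(
    schedule: InvitationSchedule,
    ages_at_reference=range(30, 100),
    reference_year: int = 2000,
) -> dict[int, int]:
    """Number of invitations each cohort (keyed by age at reference) receives."""
    return {
        a: len(invitation_ages(a, schedule, reference_year)) for a in ages_at_reference
    }


def smooth_3x3(surface: np.ndarray) -> np.ndarray:
    """Moving 3x3 mean of a cell surface, truncated at the grid edges.

    Each output cell is the arithmetic mean of the input values in the
    3 x 3 window centred on it, intersected with the grid (so corner cells
    average 4 values, edge cells 6).  No padding values are invented.
    """
    surface = np.asarray(surface, dtype=float)
    if surface.ndim != 2 or surface.size == 0:
        raise ValueError("surface must be a non-empty 2-D array")
    kernel = np.ones((3, 3))
    sums = convolve2d(surface, kernel, mode="same")
    counts = convolve2d(np.ones_like(surface), kernel, mode="same")
    return sums / counts
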
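"""Population mortality ratetables.

A :class:`RateTable` stores a daily mortality hazard on a complete
age x calendar-year x sex grid, as published national life tables do
(after converting annual death probabilities to constant daily hazards).
Individuals are matched to the table through a :class:`DemographicProfile`
(age at entry, sex, calendar date of entry); both attained age and calendar
year advance with follow-up time, so each subject traces their own diagonal
path through the table.

Lookups at the table boundary clamp to the closest available cell; the
table is never extrapolated.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._constants import DAYS_PER_YEAR, MAX_ATTAINED_YEARS

__all__ = [
    "RateTable",
    "DemographicProfile",
    "PopHazardTrajectory",
    "read_ratetable",
    "write_ratetable",
    "make_gompertz_ratetable",
    "daily_hazard_at",
    "pop_cum_hazard",
    "sample_pop_death_time",
    "subject_daily_hazards",
    "sample_pop_death_times",
    "date_to_decimal_year",
]


def date_to_decimal_year(date: _dt.date | str | float) -> float:
    """Convert a calendar date to a decimal year (floats pass through)."""
    if isinstance(date, (int, float)):
        return float(date)
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    day_of_year = (date - _dt.date(date.year, 1, 1)).days
    return date.year + day_of_year / DAYS_PER_YEAR


@dataclass(frozen=True)
class RateTable:
    """Daily mortality hazard on an age x calendar-year x sex grid.

    Parameters
    ----------
    age_axis : array of int
        Contiguous ages in whole years, starting at 0, unit step.
    year_axis : array of int
        Contiguous calendar years, unit step.
    sex_levels : tuple of two str
        Labels of the two sexes, in the order of the last array axis.
    daily_hazard : array, shape (n_ages, n_years, 2)
        Non-negative hazard of death per day in each cell.
    """

    age_axis: np.ndarray
    year_axis: np.ndarray
    sex_levels: tuple[str, str]
    daily_hazard: np.ndarray

    def __post_init__(self):
        age = np.asarray(self.age_axis, dtype=int)
        year = np.asarray(self.year_axis, dtype=int)
        haz = np.asarray(self.daily_hazard, dtype=float)
        if age[0] != 0 or np.any(np.diff(age) != 1):
            raise ValueError("age_axis must be contiguous integers starting at 0")
        if np.any(np.diff(year) != 1):
            raise ValueError("year_axis must be contiguous integers")
        if len(self.sex_levels) != 2:
            raise ValueError("exactly two sex levels are required")
        if haz.shape != (age.size, year.size, 2):
            raise ValueError(
                f"daily_hazard shape {haz.shape} does not match axes "
                f"({age.size}, {year.size}, 2)"
            )
        if not np.all(np.isfinite(haz)) or np.any(haz < 0):
            raise ValueError("daily_hazard values must be finite and >= 0")
        object.__setattr__(self, "age_axis", age)
        object.__setattr__(self, "year_axis", year)
        object.__setattr__(self, "daily_hazard", haz)

    def sex_index(self, sex) -> int:
        try:
            return self.sex_levels.index(sex)
        except ValueError:
            raise ValueError(
                f"unknown sex {sex!r}; table levels are {self.sex_levels}"
            ) from None


@dataclass(frozen=True)
class DemographicProfile:
    """Demographics needed to match one subject to a ratetable.

    ``age_at_entry`` is in days; ``entry_date`` may be a date, an ISO
    string or a decimal year.
    """

    subject_id: object
    age_at_entry: float
    sex: object
    entry_date: object

    def __post_init__(self):
        if self.age_at_entry < 0:
            raise ValueError("age_at_entry must be >= 0")
        object.__setattr__(self, "entry_date", date_to_decimal_year(self.entry_date))


@dataclass(frozen=True)
class PopHazardTrajectory:
    """Cumulative population hazard of one subject over follow-up.

    Piecewise linear between daily knots; ``cum_hazard[0] == 0``.
    """

    subject_id: object
    grid: np.ndarray
    cum_hazard: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        ch = np.asarray(self.cum_hazard, dtype=float)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must start at 0 and be strictly increasing")
        if ch[0] != 0 or np.any(np.diff(ch) < 0):
            raise ValueError("cum_hazard must start at 0 and be non-decreasing")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "cum_hazard", ch)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_META_PREFIX = "# value:"


def read_ratetable(path, format: str = "annual_prob") -> RateTable:
    """Read a ratetable from tabular text.

    Formats
    -------
    ``annual_prob`` / ``daily_hazard``
        CSV with columns ``age,year,sex,value`` preceded by a metadata
        comment line ``# value: annual_prob`` (or ``daily_hazard``); the
        metadata line, when present, overrides ``format``.  Annual death
        probabilities ``q`` are converted to a constant daily hazard
        ``-log(1 - q) / 365.241``.
    ``hmd_lifetable``
        Whitespace-delimited period life-table text with columns
        ``Year, Age, qx`` plus a ``Sex`` column; ages like ``"110+"``
        are accepted.

    The age x year x sex grid must be complete; gaps are reported.
    """
    if format == "hmd_lifetable":
        df = pd.read_csv(path, sep=r"\s+", comment="#")
        df.columns = [c.lower() for c in df.columns]
        df = df.rename(columns={"qx": "value"})
        df["age"] = df["age"].astype(str).str.rstrip("+").astype(int)
        value_kind = "annual_prob"
    else:
        with open(path) as fh:
            text = fh.read()
        value_kind = format
        lines = text.splitlines()
        if lines and lines[0].startswith(_META_PREFIX):
            value_kind = lines[0][len(_META_PREFIX):].strip()
            text = "\n".join(lines[1:])
        df = pd.read_csv(io.StringIO(text))
    if value_kind not in ("annual_prob", "daily_hazard"):
        raise ValueError(f"unknown ratetable value kind {value_kind!r}")
    return ratetable_from_frame(df, value_kind)


def ratetable_from_frame(df: pd.DataFrame, value_kind: str) -> RateTable:
    """Build a :class:`RateTable` from a long frame with age,year,sex,value."""
    required = {"age", "year", "sex", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"ratetable needs columns {sorted(required)}")
    ages = np.arange(0, int(df["age"].max()) + 1)
    if int(df["age"].min()) != 0:
        raise ValueError("ratetable ages must start at 0")
    years = np.arange(int(df["year"].min()), int(df["year"].max()) + 1)
    sex_levels = tuple(sorted(df["sex"].astype(str).unique()))
    if len(sex_levels) != 2:
        raise ValueError(f"expected two sex levels, found {sex_levels}")

    pivot = df.set_index(["age", "year", "sex"])["value"]
    full = pd.MultiIndex.from_product(
        [ages, years, sex_levels], names=["age", "year", "sex"]
    )
    missing = full.difference(pivot.index)
    if len(missing):
        raise ValueError(
            f"ratetable grid has {len(missing)} missing cells, e.g. "
            f"{list(missing[:5])}"
        )
    values = pivot.reindex(full).to_numpy().reshape(ages.size, years.size, 2)
    if value_kind == "annual_prob":
        if np.any(values >= 1) or np.any(values < 0):
            raise ValueError("annual death probabilities must lie in [0, 1)")
        values = -np.log1p(-values) / DAYS_PER_YEAR
    return RateTable(ages, years, sex_levels, values)


def write_ratetable(rt: RateTable, path, format: str = "daily_hazard") -> None:
    """Write a ratetable as CSV with a metadata line (inverse of reading)."""
    values = rt.daily_hazard
    if format == "annual_prob":
        values = -np.expm1(-values * DAYS_PER_YEAR)
    elif format != "daily_hazard":
        raise ValueError(f"unknown output format {format!r}")
    idx = pd.MultiIndex.from_product(
        [rt.age_axis, rt.year_axis, rt.sex_levels], names=["age", "year", "sex"]
    )
    df = pd.DataFrame({"value": values.reshape(-1)}, index=idx).reset_index()
    with open(path, "w") as fh:
        fh.write(f"{_META_PREFIX} {format}\n")
        df.to_csv(fh, index=False)


def make_gompertz_ratetable(
    years=(1985, 2015),
    max_age: int = 110,
    level: float = 1e-4,
    slope: float = 0.09,
    sex_factors: tuple[float, float] = (0.8, 1.5),
    year_trend: float = -0.005,
    sex_levels: tuple[str, str] = ("female", "male"),
) -> RateTable:
    """Synthetic national-style mortality table with Gompertz age shape.

    Annual hazard ``level * exp(slope * age) * sex_factor *
    exp(year_trend * (year - 1995))``, capped at 0.7/year, converted to a
    constant daily hazard per cell.  The shape and magnitude mimic a
    European population table (e.g. ~5%/year at age 70 for men) without
    bundling any external data.
    """
    ages = np.arange(0, max_age + 1)
    yrs = np.arange(years[0], years[1] + 1)
    annual = (
        level
        * np.exp(slope * ages)[:, None, None]
        * np.exp(year_trend * (yrs - 1995))[None, :, None]
        * np.asarray(sex_factors)[None, None, :]
    )
    annual = np.minimum(annual, 0.7)
    return RateTable(ages, yrs, sex_levels, annual / DAYS_PER_YEAR)


# ---------------------------------------------------------------------------
# Lookup and integration
# ---------------------------------------------------------------------------

def _cell_indices(rt: RateTable, age_days, entry_year, u):
    """Clamped (age, year) table indices at follow-up day ``u``."""
    age_idx = np.floor((age_days + u) / DAYS_PER_YEAR).astype(int)
    age_idx = np.clip(age_idx, 0, rt.age_axis.size - 1)
    year_idx = np.floor(entry_year + u / DAYS_PER_YEAR).astype(int) - rt.year_axis[0]
    year_idx = np.clip(year_idx, 0, rt.year_axis.size - 1)
    return age_idx, year_idx


def daily_hazard_at(rt: RateTable, profile: DemographicProfile, u) -> float:
    """Table hazard per day for ``profile`` at follow-up time ``u`` (days).

    Uses attained age ``floor((age_at_entry + u) / 365.241)`` and the
    calendar year of ``entry_date + u``, clamped to the table.
    """
    if np.any(np.asarray(u) < 0):
        raise ValueError("follow-up time u must be >= 0")
    ai, yi = _cell_indices(rt, profile.age_at_entry, profile.entry_date, np.asarray(u))
    return rt.daily_hazard[ai, yi, rt.sex_index(profile.sex)]


def pop_cum_hazard(rt: RateTable, profile: DemographicProfile, t: float) -> float:
    """Cumulative population hazard of one subject at follow-up day ``t``.

    Left-aligned daily rectangles: the hazard over day ``(u-1, u]`` is the
    table value at day ``u-1``, so the cumulative hazard is piecewise
    linear with (at most) daily knots.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    full = int(np.floor(t))
    total = 0.0
    if full > 0:
        total = float(np.sum(daily_hazard_at(rt, profile, np.arange(full))))
    frac = t - full
    if frac > 0:
        total += frac * float(daily_hazard_at(rt, profile, full))
    return total


def pop_hazard_trajectory(
    rt: RateTable, profile: DemographicProfile, n_days: int
) -> PopHazardTrajectory:
    """Daily-knot cumulative hazard trajectory over ``n_days`` of follow-up."""
    daily = daily_hazard_at(rt, profile, np.arange(int(n_days)))
    cum = np.concatenate([[0.0], np.cumsum(daily)])
    return PopHazardTrajectory(profile.subject_id, np.arange(int(n_days) + 1), cum)


def sample_pop_death_time(
    rt: RateTable,
    profile: DemographicProfile,
    left_truncation: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Draw a population death time conditional on survival to ``left_truncation``.

    Inverts the subject's piecewise-linear cumulative hazard against an
    exponential deviate: ``P(T > t | T > L) = exp(-(Lambda(t) - Lambda(L)))``.
    Returns ``inf`` if the (clamped) table cannot accumulate the deviate
    within 200 attained years.
    """
    if left_truncation < 0:
        raise ValueError("left_truncation must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    target = pop_cum_hazard(rt, profile, left_truncation) - np.log(rng.uniform())
    max_days = int(
        np.ceil(MAX_ATTAINED_YEARS * DAYS_PER_YEAR - profile.age_at_entry)
    )
    cum = 0.0
    day = 0
    block = 4096
    while day < max_days:
        upto = min(day + block, max_days)
        daily = daily_hazard_at(rt, profile, np.arange(day, upto))
        csum = cum + np.cumsum(daily)
        hit = np.nonzero(csum >= target)[0]
        if hit.size:
            k = hit[0]
            prev = csum[k] - daily[k]
            # linear within the day; daily[k] > 0 whenever csum crosses target
            return day + k + (target - prev) / daily[k]
        cum = csum[-1] if daily.size else cum
        day = upto
    return float("inf")


# ---------------------------------------------------------------------------
# Vectorized bulk paths (shared by the estimators and the simulator)
# ---------------------------------------------------------------------------

def subject_daily_hazards(
    rt: RateTable,
    age_days: np.ndarray,
    sex_idx: np.ndarray,
    entry_year: np.ndarray,
    n_days: int,
    chunk: int = 2048,
) -> np.ndarray:
    """Matrix of daily hazards, shape (n_subjects, n_days).

    ``H[i, d]`` is the table hazard for subject ``i`` over follow-up day
    ``(d, d+1]`` (evaluated at day-start ``u = d``), so
    ``cumsum(H, axis=1)`` gives each subject's cumulative hazard at whole
    days 1..n_days.
    """
    age_days = np.asarray(age_days, dtype=float)
    sex_idx = np.asarray(sex_idx, dtype=int)
    entry_year = np.asarray(entry_year, dtype=float)
    n = age_days.size
    days = np.arange(int(n_days))
    out = np.empty((n, int(n_days)))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        ai, yi = _cell_indices(
            rt, age_days[lo:hi, None], entry_year[lo:hi, None], days[None, :]
        )
        out[lo:hi] = rt.daily_hazard[ai, yi, sex_idx[lo:hi, None]]
    return out


def sample_pop_death_times(
    H: np.ndarray,
    left_truncation: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized death-time sampler on precomputed daily hazards.

    ``H`` is the matrix from :func:`subject_daily_hazards`; times beyond
    its horizon are returned as ``inf`` (callers only ever need deaths
    inside the follow-up window).
    """
    n, D = H.shape
    L = np.asarray(left_truncation, dtype=float)
    if np.any(L >= D):
        raise ValueError("left truncation beyond the hazard-matrix horizon")
    cum = np.cumsum(H, axis=1)  # Lambda at whole days 1..D
    # Lambda(L): full days below L plus a fraction of the current day.
    dL = np.floor(L).astype(int)
    lamL = np.where(
        dL > 0, np.take_along_axis(cum, np.maximum(dL - 1, 0)[:, None], 1)[:, 0], 0.0
    )
    lamL = lamL + (L - dL) * np.take_along_axis(
        H, np.minimum(dL, D - 1)[:, None], 1
    )[:, 0]
    target = lamL - np.log(rng.uniform(size=n))
    k = (cum < target[:, None]).sum(axis=1)
    out = np.full(n, np.inf)
    inside = k < D
    ki = k[inside]
    prev = np.where(
        ki > 0,
        np.take_along_axis(cum[inside], np.maximum(ki - 1, 0)[:, None], 1)[:, 0],
        0.0,
    )
    step = np.take_along_axis(H[inside], ki[:, None], 1)[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (target[inside] - prev) / step
    out[inside] = ki + np.where(step > 0, frac, 0.0)
    return out
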
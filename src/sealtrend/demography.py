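"""Colony count series, haul-out correction, log-linear trends and population scaling.

The demographic core of the package: northern elephant seal colony censuses are
either direct February pup counts or January adult-female counts.  Female counts
are converted to pup production with a parametric attendance (haul-out) curve and
a birth rate ``B``; trends are ordinary least-squares fits of ln(count) on year,
reported as the annual rate of increase ``λ = exp(r)``; series long enough for a
regime change are scanned for an optimal two-segment breakpoint; and total pup
production is scaled to total population size with a λ-dependent multiplier M.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CountKind",
    "CountRecord",
    "ColonyCountSeries",
    "HaulOutModel",
    "TrendFit",
    "BreakpointResult",
    "PopulationScaling",
    "PopulationEstimate",
    "AttendanceWindowError",
    "proportion_ashore",
    "estimate_pup_production",
    "fit_loglinear",
    "scan_breakpoint",
    "scale_population",
    "colony_shares",
    "round_half_away",
]


class AttendanceWindowError(ValueError):
    """Raised when a count date falls outside the attendance window (no females ashore)."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (not banker's rounding)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


class CountKind(str, Enum):
    PUP_FEB = "pup_feb"
    FEMALE_JAN = "female_jan"


@dataclass(frozen=True)
class CountRecord:
    year: int
    value: int
    kind: CountKind = CountKind.PUP_FEB
    count_day: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"count must be non-negative, got {self.value}")


@dataclass
class ColonyCountSeries:
    """Yearly census series for one colony, with count-type provenance per record."""

    colony_id: str
    records: list[CountRecord]

    def __post_init__(self) -> None:
        years = [r.year for r in self.records]
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError(f"{self.colony_id}: years must be strictly increasing")

    @property
    def years(self) -> np.ndarray:
        return np.array([r.year for r in self.records], dtype=int)

    @property
    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], dtype=float)

    def subset(self, period: tuple[int, int] | None) -> "ColonyCountSeries":
        if period is None:
            return self
        lo, hi = period
        recs = [r for r in self.records if lo <= r.year <= hi]
        return ColonyCountSeries(self.colony_id, recs)

    def positive_records(self) -> list[CountRecord]:
        dropped = [r for r in self.records if r.value <= 0]
        if dropped:
            logger.warning(
                "%s: excluding %d zero count(s) (years %s) from log-linear fit",
                self.colony_id, len(dropped), [r.year for r in dropped],
            )
        return [r for r in self.records if r.value > 0]


@dataclass(frozen=True)
class HaulOutModel:
    """Normal-arrival / fixed-residence attendance model for breeding females.

    Females arrive on days distributed N(arrival_mean, arrival_sd) and each stays
    ashore exactly ``residence_days``, so the expected fraction ashore on day t is
    Φ((t−μ)/σ) − Φ((t−μ−D)/σ).  ``birth_rate_mean`` is the fraction B of
    season-total females that produce a pup.
    """

    arrival_mean: float
    arrival_sd: float
    residence_days: float
    birth_rate_mean: float = 0.7419
    birth_rate_sd: float = 0.0345

    def __post_init__(self) -> None:
        if self.arrival_sd < 0:
            raise ValueError("arrival_sd must be >= 0")
        if self.residence_days <= 0:
            raise ValueError("residence_days must be > 0")
        if not 0 < self.birth_rate_mean <= 1:
            raise ValueError("birth rate B must be in (0, 1]")


def proportion_ashore(t: float, model: HaulOutModel) -> float:
    """Expected proportion of season-total females ashore on day-of-season ``t``.

    Bounded in [0, 1], unimodal, and → 0 at both season extremes.  The
    ``arrival_sd → 0`` limit is the indicator of ``arrival_mean ≤ t < mean + D``.
    """
    if not np.isfinite(t):
        raise ValueError(f"count day must be finite, got {t}")
    mu, sd, d = model.arrival_mean, model.arrival_sd, model.residence_days
    if sd == 0:
        return float(mu <= t < mu + d)
    p = stats.norm.cdf((t - mu) / sd) - stats.norm.cdf((t - mu - d) / sd)
    return float(min(max(p, 0.0), 1.0))


def estimate_pup_production(
    female_count: int,
    t: float,
    model: HaulOutModel,
    birth_rate: float | None = None,
) -> tuple[int, float]:
    """Convert a single-day female count into estimated pup production.

    Season-total females = count / proportion_ashore(t); pups = total × B.
    Returns ``(rounded, unrounded)`` with half-away-from-zero rounding.
    """
    if female_count <= 0:
        raise ValueError("female_count must be positive")
    b = model.birth_rate_mean if birth_rate is None else birth_rate
    p = proportion_ashore(t, model)
    if p <= 1e-12:
        raise AttendanceWindowError(
            f"count day {t} is outside the attendance window (proportion ashore = 0)"
        )
    unrounded = female_count / p * b
    return round_half_away(unrounded), unrounded


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of ln(count) on year: slope r, λ=e^r, R², and slope uncertainty.

    Both coefficient-of-variation conventions are carried because the field uses
    either normalisation; ``cv`` aliases the configured one.
    """

    period: tuple[int, int]
    n: int
    r: float
    lambda_: float
    r2: float
    se_slope: float
    intercept: float
    cv_slope_over_se: float
    cv_se_over_slope: float
    cv_convention: str = "slope_over_se"

    @property
    def cv(self) -> float:
        return (
            self.cv_slope_over_se
            if self.cv_convention == "slope_over_se"
            else self.cv_se_over_slope
        )


def _ols_log(years: np.ndarray, values: np.ndarray) -> tuple[float, float, float, float, float]:
    """Return (slope, intercept, r2, se_slope, rss) of ln(values) ~ years."""
    x = np.asarray(years, dtype=float)
    y = np.log(np.asarray(values, dtype=float))
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise ValueError("all observations in the same year; cannot fit a trend")
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float((resid**2).sum())
    sst = float(((y - ym) ** 2).sum())
    r2 = 1.0 - rss / sst if sst > 0 else 0.0
    se = math.sqrt(rss / (n - 2) / sxx) if n > 2 else 0.0
    return slope, intercept, r2, se, rss


def fit_loglinear(
    series: ColonyCountSeries,
    period: tuple[int, int] | None = None,
    cv_convention: str = "slope_over_se",
) -> TrendFit:
    """Log-linear trend fit over ``period`` (inclusive); zero counts are excluded.

    λ equals ``exp(slope)`` exactly (definitional); R² is clamped to 0 for a
    zero-variance response (constant series).
    """
    sub = series.subset(period)
    recs = sub.positive_records()
    if len(recs) < 2:
        raise ValueError(
            f"{series.colony_id}: need >=2 positive counts in period, got {len(recs)}"
        )
    years = np.array([r.year for r in recs])
    values = np.array([r.value for r in recs], dtype=float)
    slope, intercept, r2, se, _ = _ols_log(years, values)
    return TrendFit(
        period=(int(years.min()), int(years.max())),
        n=len(recs),
        r=slope,
        lambda_=math.exp(slope),
        r2=r2,
        se_slope=se,
        intercept=intercept,
        cv_slope_over_se=slope / se if se > 0 else math.inf * np.sign(slope or 1.0),
        cv_se_over_slope=se / slope if slope != 0 else math.inf,
        cv_convention=cv_convention,
    )


@dataclass
class BreakpointResult:
    breakpoint_year: int
    left_fit: TrendFit
    right_fit: TrendFit
    rss: float
    single_rss: float
    candidates_evaluated: list[tuple[int, float]] = field(default_factory=list)


def scan_breakpoint(
    series: ColonyCountSeries,
    min_per_side: int = 2,
    include_break_year_in: str = "left",
) -> BreakpointResult:
    """Exhaustive two-segment breakpoint search on a log-linear series.

    Candidate break years are the observed years leaving at least
    ``min_per_side`` points on each side; the candidate minimising the summed
    residual sum of squares of the two independent segment fits wins, ties going
    to the earlier year.  Requires n ≥ 10 positive counts; shorter series should
    be fitted as a single segment.
    """
    if include_break_year_in not in ("left", "right"):
        raise ValueError("include_break_year_in must be 'left' or 'right'")
    recs = series.positive_records()
    if len(recs) < 10:
        raise ValueError(
            f"{series.colony_id}: breakpoint scan needs n >= 10 positive counts "
            f"(got {len(recs)}); fit a single segment instead"
        )
    years = np.array([r.year for r in recs])
    values = np.array([r.value for r in recs], dtype=float)
    *_, single_rss = _ols_log(years, values)

    best: tuple[float, int] | None = None
    candidates: list[tuple[int, float]] = []
    for b in years:
        left = years <= b if include_break_year_in == "left" else years < b
        right = ~left
        if left.sum() < min_per_side or right.sum() < min_per_side:
            continue
        try:
            *_, rss_l = _ols_log(years[left], values[left])
            *_, rss_r = _ols_log(years[right], values[right])
        except ValueError:
            continue
        rss = rss_l + rss_r
        candidates.append((int(b), rss))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, int(b))
    if best is None:
        raise ValueError(f"{series.colony_id}: no admissible breakpoint candidate")

    rss, b = best
    left = years <= b if include_break_year_in == "left" else years < b
    left_fit = fit_loglinear(
        ColonyCountSeries(series.colony_id, [r for r, m in zip(recs, left) if m])
    )
    right_fit = fit_loglinear(
        ColonyCountSeries(series.colony_id, [r for r, m in zip(recs, left) if not m])
    )
    return BreakpointResult(
        breakpoint_year=b,
        left_fit=left_fit,
        right_fit=right_fit,
        rss=rss,
        single_rss=single_rss,
        candidates_evaluated=candidates,
    )


@dataclass(frozen=True)
class PopulationScaling:
    """λ-dependent multiplier M converting pup production to total population."""

    M: float
    M_CI: tuple[float, float]
    lambda_ref: float

    def __post_init__(self) -> None:
        lo, hi = self.M_CI
        if not (0 < lo <= self.M <= hi):
            raise ValueError("require 0 < CI.low <= M <= CI.high")

    @staticmethod
    def from_table(
        table: Sequence[tuple[float, float, float, float]], lambda_value: float
    ) -> "PopulationScaling":
        """Nearest-λ lookup in a user-supplied (λ, M, lo, hi) table.

        The multiplier table is external input (it is derived elsewhere from a
        full demographic model); callers must document its provenance.
        """
        if not table:
            raise ValueError("empty M table")
        lam, m, lo, hi = min(table, key=lambda row: abs(row[0] - lambda_value))
        return PopulationScaling(M=m, M_CI=(lo, hi), lambda_ref=lam)


@dataclass(frozen=True)
class PopulationEstimate:
    point: int
    ci: tuple[int, int]
    point_unrounded: float


def scale_population(
    total_pups: int,
    scaling: PopulationScaling,
    ci_from_rounded_point: bool = True,
) -> PopulationEstimate:
    """Total population = pups × M, with a 95% CI from the multiplier's CI.

    With ``ci_from_rounded_point`` (default) the CI endpoints are the rounded
    point estimate rescaled by ``M_CI / M``; otherwise they are ``pups × M_CI``
    directly.  The two differ by at most one individual but the former is the
    package's reporting convention (see docs/methods.md).
    """
    if total_pups < 0:
        raise ValueError("total_pups must be >= 0")
    unrounded = total_pups * scaling.M
    point = round_half_away(unrounded)
    lo_m, hi_m = scaling.M_CI
    if ci_from_rounded_point:
        ci = (round_half_away(point * lo_m / scaling.M), round_half_away(point * hi_m / scaling.M))
    else:
        ci = (round_half_away(total_pups * lo_m), round_half_away(total_pups * hi_m))
    return PopulationEstimate(point=point, ci=ci, point_unrounded=unrounded)


def colony_shares(counts_by_colony: Mapping[str, float]) -> dict[str, tuple[int, float]]:
    """Percent share of births per colony: ``{colony: (rounded %, unrounded %)}``."""
    if any(v < 0 for v in counts_by_colony.values()):
        raise ValueError("counts must be >= 0")
    total = sum(counts_by_colony.values())
    if total <= 0:
        raise ValueError("at least one colony count must be > 0")
    return {
        c: (round_half_away(100.0 * v / total), 100.0 * v / total)
        for c, v in counts_by_colony.items()
    }
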
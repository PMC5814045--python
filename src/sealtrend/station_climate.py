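"""Daily weather-station processing: gap-aware seasonal aggregation, trend
tests, anomaly baselines, heat-wave detection and period comparison.

Daily maximum/minimum/mean air temperatures (with missing days) are averaged to
months and then seasons using standard meteorological seasons (winter = DJF with
December attached to the following year, spring = MAM, summer = JJA,
autumn = SON).  Seasonal series feed the same Mann-Kendall / Sen's-slope
machinery used for the gridded SST fields.  A heat wave is a single day whose
maximum temperature reaches a threshold (default 25.1 °C, the upper critical
air temperature for dry weaned harbour seal pups), evaluated inside the
December–April birthing and post-weaning window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .trends import MannKendallResult, mann_kendall, sens_slope

__all__ = [
    "StationSeries",
    "SeasonalSeries",
    "HeatWaveRecord",
    "HeatWaveResult",
    "CoverageRules",
    "aggregate",
    "seasonal_trend",
    "anomalies",
    "detect_heat_waves",
    "compare_period_frequencies",
]

SEASON_MONTHS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}
VARIABLES = ("tmean", "tmax", "tmin")


@dataclass
class StationSeries:
    """Daily Tmax/Tmin/Tmean record with per-day gaps (NaN).

    ``frame`` is indexed by calendar date with columns ``tmax, tmin, tmean``.
    """

    frame: pd.DataFrame
    station_id: str = ""
    lat: float | None = None
    lon: float | None = None
    elevation: float | None = None

    def __post_init__(self) -> None:
        if self.frame.empty:
            raise ValueError("empty station series")
        missing = [c for c in VARIABLES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"station frame missing columns {missing}")
        idx = pd.DatetimeIndex(self.frame.index)
        if not idx.is_monotonic_increasing or idx.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        self.frame = self.frame.copy()
        self.frame.index = idx
        f = self.frame
        complete = f[list(VARIABLES)].notna().all(axis=1)
        bad = complete & ~((f.tmin <= f.tmean + 1e-9) & (f.tmean <= f.tmax + 1e-9))
        if bad.any():
            raise ValueError(
                f"tmin <= tmean <= tmax violated on {bad.sum()} day(s), "
                f"first {f.index[bad][0].date()}"
            )


@dataclass
class SeasonalSeries:
    """One season's (or the annual) yearly mean values for one variable."""

    season: str  # winter|spring|summer|autumn|annual
    variable: str
    values: pd.Series  # indexed by year, NaN where coverage rule failed

    @property
    def n_years(self) -> int:
        return int(self.values.notna().sum())


@dataclass(frozen=True)
class CoverageRules:
    """Minimum data coverage for an aggregate to be reported."""

    min_days_per_month: int = 20
    min_months_per_season: int = 3
    min_months_per_year: int = 10


def _monthly_means(s: pd.Series, rules: CoverageRules) -> pd.Series:
    grp = s.groupby([s.index.year, s.index.month])
    m = grp.mean()
    n = grp.count()
    m[n < rules.min_days_per_month] = np.nan
    m.index = pd.MultiIndex.from_tuples(m.index, names=["year", "month"])
    return m


def aggregate(
    series: StationSeries, rules: CoverageRules = CoverageRules()
) -> dict[str, dict[str, SeasonalSeries]]:
    """Daily → monthly → seasonal/annual means with coverage rules.

    A month needs ``min_days_per_month`` days, a season all three of its months
    (December counting toward the *following* year's winter), and the annual
    mean ``min_months_per_year`` calendar months.  Returns
    ``{variable: {season: SeasonalSeries}}``.
    """
    out: dict[str, dict[str, SeasonalSeries]] = {}
    for var in VARIABLES:
        monthly = _monthly_means(series.frame[var], rules)
        years = np.arange(series.frame.index.year.min(), series.frame.index.year.max() + 2)
        per_season: dict[str, SeasonalSeries] = {}
        for season, months in SEASON_MONTHS.items():
            vals = {}
            for y in years:
                member = [
                    monthly.get((y - 1, m) if m == 12 else (y, m), np.nan)
                    for m in months
                ]
                ok = int(np.sum(np.isfinite(member)))
                vals[y] = (
                    float(np.nanmean(member))
                    if ok >= rules.min_months_per_season
                    else np.nan
                )
            per_season[season] = SeasonalSeries(season, var, pd.Series(vals))
        annual_vals = {}
        for y in years[:-1]:
            member = [monthly.get((y, m), np.nan) for m in range(1, 13)]
            ok = int(np.sum(np.isfinite(member)))
            annual_vals[y] = float(np.nanmean(member)) if ok >= rules.min_months_per_year else np.nan
        per_season["annual"] = SeasonalSeries("annual", var, pd.Series(annual_vals))
        out[var] = per_season
    return out


@dataclass
class SeasonalTrendResult:
    mk: MannKendallResult
    slope: float | None  # °C/yr, reported only when p < 0.05
    slope_withheld: bool


def seasonal_trend(seasonal: SeasonalSeries, alpha: float = 0.05) -> SeasonalTrendResult:
    """Mann-Kendall test on the yearly series; Sen's slope (°C/yr) is reported
    only when the trend is significant at ``alpha``, per the reporting rule for
    the station record."""
    s = seasonal.values.dropna()
    if len(s) < 4:
        raise ValueError(f"{seasonal.season} {seasonal.variable}: need >= 4 years")
    mk = mann_kendall(s.values)
    if mk.p < alpha:
        slope = sens_slope(s.values, s.index.values.astype(float)).slope
        return SeasonalTrendResult(mk=mk, slope=float(slope), slope_withheld=False)
    return SeasonalTrendResult(mk=mk, slope=None, slope_withheld=True)


def anomalies(values: pd.Series, baseline: tuple[int, int] = (1961, 1990)) -> pd.Series:
    """Departures from the mean over the baseline year window."""
    lo, hi = baseline
    base = values[(values.index >= lo) & (values.index <= hi)].dropna()
    if base.empty:
        raise ValueError(f"no data inside baseline {lo}-{hi}")
    return values - base.mean()


@dataclass(frozen=True)
class HeatWaveRecord:
    date: pd.Timestamp
    tmax: float


@dataclass
class HeatWaveResult:
    records: list[HeatWaveRecord]
    n_events: int
    n_days_with_data: int
    threshold: float

    @property
    def frequency(self) -> float:
        return self.n_events / self.n_days_with_data


def detect_heat_waves(
    series: StationSeries,
    months: tuple[int, ...] = (12, 1, 2, 3, 4),
    threshold: float = 25.1,
    period: tuple[int, int] | None = None,
) -> HeatWaveResult:
    """Single-day heat waves: in-window days with tmax ≥ threshold (inclusive).

    The frequency denominator counts only in-window days with a non-missing
    tmax.  ``period`` restricts to calendar years (inclusive).
    """
    f = series.frame
    sel = f.index.month.isin(months)
    if period is not None:
        sel &= (f.index.year >= period[0]) & (f.index.year <= period[1])
    tmax = f.loc[sel, "tmax"]
    with_data = tmax.dropna()
    if with_data.empty:
        raise ValueError("no in-window days with tmax data")
    hot = with_data[with_data >= threshold]
    return HeatWaveResult(
        records=[HeatWaveRecord(d, float(v)) for d, v in hot.items()],
        n_events=len(hot),
        n_days_with_data=len(with_data),
        threshold=threshold,
    )


def compare_period_frequencies(
    events_a: int, days_a: int, events_b: int, days_b: int, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2×2 (events / non-events) × (period A / B)
    table; Yates continuity correction off by default.  Returns (χ², p)."""
    if days_a <= 0 or days_b <= 0:
        raise ValueError("day counts must be positive")
    table = np.array(
        [[events_a, days_a - events_a], [events_b, days_b - events_b]], dtype=float
    )
    if (table < 0).any():
        raise ValueError("events cannot exceed days")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (zero margin)")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)
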
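"""Seeded synthetic-data generators with planted ground truth, plus the packaged
colony census fixture.

Every generator is fully determined by its arguments and seed and returns the
planted truth alongside the data, so each pipeline stage has a recovery test:
piecewise-exponential colony counts with multiplicative lognormal noise,
monthly SST fields built from an annual cycle + linear trend + planted
oscillatory spatial modes + white noise, and daily station temperatures with a
seasonal cycle, linear trend, missing days and controlled threshold
exceedances.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from .climate_field import GriddedField
from .demography import ColonyCountSeries, CountKind, CountRecord
from .station_climate import StationSeries

__all__ = [
    "CountTruth",
    "SSTTruth",
    "StationTruth",
    "gen_count_series",
    "gen_sst_field",
    "gen_station_daily",
    "load_table1_fixture",
    "TABLE1_SHA256",
]

TABLE1_SHA256 = "6f6242510ce98a69168fca43b0ae09ef17bfbf9297d6c2c6479c6dfcf4e4d4cf"


@dataclass(frozen=True)
class CountTruth:
    lambda1: float
    lambda2: float
    break_year: int
    start_value: float
    noise_sd: float
    seed: int
    expected_values: np.ndarray  # noise-free series


def gen_count_series(
    lambda1: float,
    lambda2: float,
    break_year: int,
    start_value: float,
    years: range,
    noise_sd: float,
    seed: int,
    colony_id: str = "synthetic",
) -> tuple[ColonyCountSeries, CountTruth]:
    """Piecewise-exponential yearly counts with multiplicative lognormal noise.

    Growth multiplies by ``lambda1`` per year up to and including ``break_year``
    and by ``lambda2`` afterwards; counts are rounded to integers ≥ 1.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("growth rates must be positive")
    if start_value < 1:
        raise ValueError("start_value must be >= 1")
    rng = np.random.default_rng(seed)
    ys = np.array(list(years))
    lam = np.where(ys[:-1] < break_year, lambda1, lambda2)
    expected = start_value * np.concatenate([[1.0], np.cumprod(lam)])
    noisy = expected * np.exp(rng.normal(0.0, noise_sd, size=len(ys))) if noise_sd > 0 else expected
    counts = np.maximum(np.rint(noisy).astype(int), 1)
    series = ColonyCountSeries(
        colony_id, [CountRecord(int(y), int(c), CountKind.PUP_FEB) for y, c in zip(ys, counts)]
    )
    truth = CountTruth(lambda1, lambda2, break_year, start_value, noise_sd, seed, expected)
    return series, truth


@dataclass(frozen=True)
class SSTTruth:
    trend_per_decade: np.ndarray  # (lat, lon)
    mode_patterns: list[np.ndarray]
    mode_signals: list[np.ndarray]
    annual_cycle_amp: float
    noise_sd: float
    seed: int


def gen_sst_field(
    lats: np.ndarray,
    lons: np.ndarray,
    n_months: int,
    trend_per_decade=0.0,
    modes: list[tuple[np.ndarray, float, float]] | None = None,
    noise_sd: float = 0.1,
    annual_cycle_amp: float = 1.5,
    mean_sst: float = 18.0,
    land_mask: np.ndarray | None = None,
    start: str = "1897-01-01",
    seed: int = 0,
) -> tuple[GriddedField, SSTTruth]:
    """Monthly SST field = mean + annual cycle + linear trend + planted
    oscillatory spatial modes + white noise.

    ``modes`` is a list of ``(pattern 2-D, period_months, amplitude)``; each
    contributes ``amplitude · pattern · sin(2πt/period)``.  ``trend_per_decade``
    may be a scalar or a 2-D map.  ``land_mask`` (True = land) is applied as NaN.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if lats.size < 2 or lons.size < 2:
        raise ValueError("grid must have at least 2x2 points")
    modes = modes or []
    if any(period <= 2 for _, period, _ in modes):
        raise ValueError("oscillation periods must exceed 2 months")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months, dtype=float)
    trend_map = np.broadcast_to(np.asarray(trend_per_decade, dtype=float), (lats.size, lons.size))
    values = (
        mean_sst
        + annual_cycle_amp * np.cos(2 * np.pi * t / 12.0)[:, None, None]
        + (t / 120.0)[:, None, None] * trend_map[None, :, :]
    )
    signals = []
    for pattern, period, amp in modes:
        sig = amp * np.sin(2 * np.pi * t / period)
        signals.append(sig)
        values = values + sig[:, None, None] * np.asarray(pattern, dtype=float)[None, :, :]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    if land_mask is not None:
        values = np.where(np.asarray(land_mask, bool)[None, :, :], np.nan, values)
    da = xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": pd.date_range(start, periods=n_months, freq="MS"),
            "lat": lats,
            "lon": lons,
        },
        name="sst",
        attrs={"units": "degC"},
    )
    truth = SSTTruth(
        trend_per_decade=np.array(trend_map),
        mode_patterns=[np.asarray(p, dtype=float) for p, _, _ in modes],
        mode_signals=signals,
        annual_cycle_amp=annual_cycle_amp,
        noise_sd=noise_sd,
        seed=seed,
    )
    return GriddedField(da), truth


@dataclass(frozen=True)
class StationTruth:
    mean_level: float
    seasonal_amplitude: float
    trend_per_year: float
    noise_sd: float
    gap_fraction: float
    exceedance_prob_winter: float | None
    threshold: float
    seed: int


def gen_station_daily(
    start_year: int,
    end_year: int,
    mean_level: float = 19.0,
    seasonal_amplitude: float = 5.0,
    trend_per_year: float = 0.0,
    noise_sd: float = 1.5,
    gap_fraction: float = 0.0,
    exceedance_prob_winter: float | None = None,
    threshold: float = 25.1,
    seed: int = 0,
    station_id: str = "synthetic",
) -> tuple[StationSeries, StationTruth]:
    """Daily station record: sinusoidal annual cycle + linear trend + noise,
    with seeded gaps and (optionally) a controlled December–April probability
    that tmax reaches the heat threshold.

    The mean temperature carries the planted trend; tmax/tmin are fixed offsets
    (±4 °C) plus independent noise, re-ordered so tmin ≤ tmean ≤ tmax always
    holds.  With ``exceedance_prob_winter`` set, each in-window day's tmax is
    replaced, with that probability, by a draw at or above ``threshold`` —
    otherwise it is capped below the threshold — giving an exact planted
    exceedance rate.
    """
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must be in [0, 1)")
    if end_year < start_year:
        raise ValueError("end_year must be >= start_year")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    doy = dates.dayofyear.values
    t_years = (dates - dates[0]).days.values / 365.25
    # coldest in late January (phase ~ day 25), warmest in late July
    cycle = -seasonal_amplitude * np.cos(2 * np.pi * (doy - 25) / 365.25)
    tmean = mean_level + cycle + trend_per_year * t_years + rng.normal(0, noise_sd, len(dates))
    tmax = tmean + 4.0 + np.abs(rng.normal(0, noise_sd / 2, len(dates)))
    tmin = tmean - 4.0 - np.abs(rng.normal(0, noise_sd / 2, len(dates)))

    if exceedance_prob_winter is not None:
        in_window = dates.month.isin((12, 1, 2, 3, 4))
        hot = rng.random(len(dates)) < exceedance_prob_winter
        bump = np.abs(rng.normal(0, 2.0, len(dates)))
        tmax = np.where(
            in_window & hot,
            threshold + bump,
            np.where(in_window, np.minimum(tmax, threshold - 0.1), tmax),
        )
        tmean = np.minimum(tmean, tmax - 0.1)
        tmin = np.minimum(tmin, tmean - 0.1)

    frame = pd.DataFrame({"tmax": tmax, "tmin": tmin, "tmean": tmean}, index=dates)
    if gap_fraction > 0:
        gaps = rng.random(len(dates)) < gap_fraction
        frame.loc[gaps, :] = np.nan
    series = StationSeries(frame, station_id=station_id)
    truth = StationTruth(
        mean_level, seasonal_amplitude, trend_per_year, noise_sd, gap_fraction,
        exceedance_prob_winter, threshold, seed,
    )
    return series, truth


def load_table1_fixture() -> dict[str, ColonyCountSeries]:
    """Load the packaged 1965–2016 Baja California colony census table.

    Values are pup production per colony and year; the ``kind`` flag records
    whether a value is a direct February pup count or was derived from a
    January adult-female count.  The file is checksum-pinned against silent
    corruption.
    """
    ref = resources.files("sealtrend").joinpath("data/table1_counts.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise RuntimeError(
            f"census fixture checksum mismatch ({digest}); reinstall the package"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    out: dict[str, ColonyCountSeries] = {}
    for colony, grp in df.groupby("colony", sort=False):
        recs = [
            CountRecord(
                int(row.year),
                int(row.count_),
                CountKind(row.kind),
                None if pd.isna(row.count_day) else float(row.count_day),
            )
            for row in grp.rename(columns={"count": "count_"}).itertuples()
        ]
        out[colony] = ColonyCountSeries(colony, recs)
    return out
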
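"""End-to-end workflows tying the modules into the two analyses: colony
demography (trend table, breakpoints, pooled trend, population size) and
regional climate (SST filter → REOF → ENSO removal → trend maps; station
trends, anomalies and heat waves)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate_field import (
    GriddedField,
    TrendMap,
    compute_reof,
    detrend_linear,
    lanczos_weights,
    lowpass,
    remove_mode,
    windowed_trend_map,
)
from .config import RunConfig
from .demography import (
    BreakpointResult,
    ColonyCountSeries,
    PopulationEstimate,
    PopulationScaling,
    TrendFit,
    colony_shares,
    fit_loglinear,
    scale_population,
    scan_breakpoint,
)
from .station_climate import (
    CoverageRules,
    HeatWaveResult,
    SeasonalTrendResult,
    StationSeries,
    aggregate,
    anomalies,
    detect_heat_waves,
    seasonal_trend,
)
from .synthetic import load_table1_fixture

__all__ = ["DemographyReport", "ClimateReport", "run_demography_workflow", "run_climate_workflow"]


@dataclass
class DemographyReport:
    fits: dict[str, list[TrendFit]]
    breakpoints: dict[str, BreakpointResult]
    pooled_fit: TrendFit
    pooled_years: list[int]
    reference_year: int
    pups_by_colony: dict[str, int]
    total_pups: int
    shares: dict[str, tuple[int, float]]
    population: PopulationEstimate
    config_hash: str

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for colony, fits in self.fits.items():
            for f in fits:
                rows.append(
                    {
                        "colony": colony,
                        "period": f"{f.period[0]}-{f.period[1]}",
                        "n": f.n,
                        "R2": f.r2,
                        "lambda": f.lambda_,
                        "cv": f.cv,
                    }
                )
        rows.append(
            {
                "colony": "all",
                "period": f"{self.pooled_fit.period[0]}-{self.pooled_fit.period[1]}",
                "n": self.pooled_fit.n,
                "R2": self.pooled_fit.r2,
                "lambda": self.pooled_fit.lambda_,
                "cv": self.pooled_fit.cv,
            }
        )
        return pd.DataFrame(rows)


def pooled_series(
    counts: dict[str, ColonyCountSeries], require_positive: bool = True
) -> tuple[ColonyCountSeries, list[int]]:
    """Sum colony counts over the years in which *every* colony was counted
    (and, by default, counted a positive number of pups)."""
    year_sets = []
    for s in counts.values():
        ok = [r.year for r in s.records if (r.value > 0 or not require_positive)]
        year_sets.append(set(ok))
    years = sorted(set.intersection(*year_sets))
    if len(years) < 2:
        raise ValueError("fewer than 2 common census years across colonies")
    totals = {
        y: sum(r.value for s in counts.values() for r in s.records if r.year == y)
        for y in years
    }
    from .demography import CountRecord

    series = ColonyCountSeries(
        "all", [CountRecord(y, totals[y]) for y in years]
    )
    return series, years


def run_demography_workflow(
    config: RunConfig, counts: dict[str, ColonyCountSeries] | None = None
) -> DemographyReport:
    """Census table in, population status out.

    Per-colony: breakpoint scan (series with n ≥ 10 only) and log-linear fits
    over the configured windows.  Pooled: fit over years where all colonies
    have positive counts.  Reference year: total pups, colony shares and the
    M-scaled population estimate with CI.
    """
    if counts is None:
        counts = load_table1_fixture()
    if not counts:
        raise ValueError("no colony count series supplied")

    fits: dict[str, list[TrendFit]] = {}
    breakpoints: dict[str, BreakpointResult] = {}
    for colony, series in counts.items():
        periods = config.fit_periods.get(colony, [])
        fits[colony] = [
            fit_loglinear(series, tuple(p), cv_convention=config.cv_convention)
            for p in periods
        ]
        if len(series.positive_records()) >= 10:
            breakpoints[colony] = scan_breakpoint(
                series,
                min_per_side=config.breakpoint_min_per_side,
                include_break_year_in=config.include_break_year_in.get(colony, "left"),
            )

    pooled, years = pooled_series(counts)
    pooled_fit = fit_loglinear(pooled, cv_convention=config.cv_convention)

    ref = config.reference_year
    pups = {}
    for colony, series in counts.items():
        match = [r.value for r in series.records if r.year == ref]
        if not match:
            raise ValueError(f"{colony}: no count in reference year {ref}")
        pups[colony] = match[0]
    total = sum(pups.values())
    shares = colony_shares(pups)
    scaling = PopulationScaling.from_table(
        [tuple(r) for r in config.m_table], pooled_fit.lambda_
    )
    population = scale_population(total, scaling, config.ci_from_rounded_point)

    return DemographyReport(
        fits=fits,
        breakpoints=breakpoints,
        pooled_fit=pooled_fit,
        pooled_years=years,
        reference_year=ref,
        pups_by_colony=pups,
        total_pups=total,
        shares=shares,
        population=population,
        config_hash=config.config_hash(),
    )


@dataclass
class ClimateReport:
    residual_field: GriddedField | None
    variance_fractions: list[float] | None
    rotated_variance_fractions: list[float] | None
    trend_maps: list[TrendMap] = field(default_factory=list)
    station_trends: dict[str, dict[str, SeasonalTrendResult]] = field(default_factory=dict)
    station_anomalies: dict[str, pd.Series] = field(default_factory=dict)
    heat_waves: HeatWaveResult | None = None
    config_hash: str = ""


def run_climate_workflow(
    config: RunConfig,
    sst: GriddedField | None = None,
    station: StationSeries | None = None,
) -> ClimateReport:
    """Gridded chain: low-pass filter → detrend → REOF(varimax) → remove the
    ENSO mode from the filtered (not detrended) field → windowed trend maps.
    Station chain: aggregate → MK/Sen per season → anomalies → heat waves."""
    residual = None
    var_frac = rot_frac = None
    maps: list[TrendMap] = []
    if sst is not None:
        spec = lanczos_weights(config.filter_cutoff_months, config.filter_n_weights)
        filtered = lowpass(sst, spec)
        detrended, _slopes = detrend_linear(filtered)
        if np.nanmax(np.abs(detrended.values)) < 1e-10:
            # zero-variance (constant) field: nothing to decompose or remove
            residual = filtered
        else:
            ref = tuple(config.reof_reference_point) if config.reof_reference_point else None
            decomp = compute_reof(
                detrended, config.reof_k, area_weight=config.reof_area_weight,
                reference_point=ref,
            )
            residual = remove_mode(filtered, decomp, config.enso_mode_index)
            var_frac = [float(x) for x in decomp.variance_fractions[: config.reof_k]]
            rot_frac = [float(x) for x in decomp.rot_variance_fractions]
        windows = config.trend_windows
        if isinstance(windows, list):
            windows = [tuple(w) for w in windows]
        maps = windowed_trend_map(residual, windows, config.trend_min_coverage)

    trends: dict[str, dict[str, SeasonalTrendResult]] = {}
    anoms: dict[str, pd.Series] = {}
    hw = None
    if station is not None:
        rules = CoverageRules(
            config.min_days_per_month,
            config.min_months_per_season,
            config.min_months_per_year,
        )
        agg = aggregate(station, rules)
        for var, seasons in agg.items():
            trends[var] = {}
            for season, ss in seasons.items():
                if ss.n_years >= 4:
                    trends[var][season] = seasonal_trend(ss)
            anoms[var] = anomalies(
                agg[var]["annual"].values, tuple(config.anomaly_baseline)
            )
        hw = detect_heat_waves(
            station, tuple(config.heatwave_months), config.heatwave_threshold
        )

    return ClimateReport(
        residual_field=residual,
        variance_fractions=var_frac,
        rotated_variance_fractions=rot_frac,
        trend_maps=maps,
        station_trends=trends,
        station_anomalies=anoms,
        heat_waves=hw,
        config_hash=config.config_hash(),
    )
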
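"""Readers and writers for the package's file dialects.

Colony counts and station records travel as plain CSV; gridded fields and trend
maps as CF-style netCDF (``sst(time, lat, lon)``), written through xarray's
scipy backend (NETCDF3 classic).  Outputs embed the package version and, when a
config is supplied, its hash.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .climate_field import GriddedField, TrendMap
from .demography import ColonyCountSeries, CountKind, CountRecord
from .station_climate import StationSeries

__all__ = [
    "read_counts_csv",
    "write_counts_csv",
    "read_station_csv",
    "write_station_csv",
    "read_sst_netcdf",
    "write_sst_netcdf",
    "write_trend_maps_netcdf",
]

_COUNT_COLUMNS = ["colony", "year", "count", "kind", "count_day"]


def read_counts_csv(path: str | Path) -> dict[str, ColonyCountSeries]:
    """Read a ``colony,year,count,kind,count_day`` census table.

    ``count_day`` is required (non-blank) for ``female_jan`` rows whose value
    still needs haul-out conversion; rows already expressed as pup production
    may leave it blank.
    """
    df = pd.read_csv(path)
    missing = set(_COUNT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns {sorted(missing)}")
    if "count_day" not in df.columns:
        df["count_day"] = np.nan
    out: dict[str, ColonyCountSeries] = {}
    for colony, grp in df.groupby("colony", sort=False):
        recs = []
        for _, row in grp.iterrows():
            recs.append(
                CountRecord(
                    int(row["year"]),
                    int(row["count"]),
                    CountKind(row["kind"]),
                    None if pd.isna(row["count_day"]) else float(row["count_day"]),
                )
            )
        out[str(colony)] = ColonyCountSeries(str(colony), recs)
    return out


def write_counts_csv(series_by_colony: dict[str, ColonyCountSeries], path: str | Path) -> None:
    rows = [
        {
            "colony": s.colony_id,
            "year": r.year,
            "count": r.value,
            "kind": r.kind.value,
            "count_day": "" if r.count_day is None else r.count_day,
        }
        for s in series_by_colony.values()
        for r in s.records
    ]
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, index=False)


def read_station_csv(path: str | Path, station_id: str = "") -> StationSeries:
    """Read a ``date,tmax,tmin,tmean`` daily record; blank cells are missing."""
    df = pd.read_csv(path, parse_dates=["date"])
    needed = {"date", "tmax", "tmin", "tmean"}
    if not needed <= set(df.columns):
        raise ValueError(f"station CSV needs columns {sorted(needed)}")
    df = df.set_index("date")
    return StationSeries(df[["tmax", "tmin", "tmean"]], station_id=station_id)


def write_station_csv(series: StationSeries, path: str | Path) -> None:
    out = series.frame.copy()
    out.index.name = "date"
    out.to_csv(path, date_format="%Y-%m-%d")


def _attrs(config=None) -> dict:
    a = {"package": f"sealtrend {__version__}"}
    if config is not None:
        a["config_hash"] = config.config_hash()
    return a


def read_sst_netcdf(path: str | Path, var: str = "sst") -> GriddedField:
    """Read ``var(time, lat, lon)`` honouring ``missing_value``/``_FillValue``."""
    with xr.open_dataset(path) as ds:
        if var not in ds:
            raise ValueError(f"variable {var!r} not in {path}")
        da = ds[var].load()
    rename = {}
    for want, aliases in {"lat": ("latitude",), "lon": ("longitude",)}.items():
        for a in aliases:
            if a in da.dims:
                rename[a] = want
    if rename:
        da = da.rename(rename)
    return GriddedField(da.transpose("time", "lat", "lon").astype(float))


def write_sst_netcdf(field: GriddedField, path: str | Path, config=None) -> None:
    ds = field.data.to_dataset(name=field.data.name or "sst")
    ds.attrs.update(_attrs(config))
    ds.to_netcdf(path, engine="scipy")


def write_trend_maps_netcdf(maps: list[TrendMap], path: str | Path, config=None) -> None:
    """Stack per-window trend maps into one file with a ``significance`` byte
    layer (0 none, 1 p<0.05, 2 p<0.01)."""
    ds = xr.Dataset(
        {
            "trend": xr.concat([m.slopes for m in maps], dim="window"),
            "significance": xr.concat([m.significance for m in maps], dim="window"),
        },
        coords={
            "window": np.arange(len(maps)),
            "window_start": ("window", [m.window[0] for m in maps]),
            "window_end": ("window", [m.window[1] for m in maps]),
        },
    )
    ds["trend"].attrs["units"] = "degC/decade"
    ds.attrs.update(_attrs(config))
    ds.to_netcdf(path, engine="scipy")
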
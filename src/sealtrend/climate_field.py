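"""Gridded-SST signal processing: low-pass filtering, EOF/REOF decomposition,
ENSO-mode removal and windowed nonparametric trend maps.

The pipeline mirrors the standard climate-diagnostics chain for monthly SST
fields: a low-pass Lanczos filter removes the semi-annual and annual cycles, the
filtered and detrended anomalies are decomposed into empirical orthogonal
functions with varimax rotation of the leading modes, the mode capturing ENSO is
reconstructed and subtracted from the filtered (but not detrended) field, and
decadal trends with Mann-Kendall significance are mapped over 30-year windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .trends import mann_kendall, sens_slope

logger = logging.getLogger(__name__)

__all__ = [
    "GriddedField",
    "FilterSpec",
    "REOFDecomposition",
    "TrendMap",
    "lanczos_weights",
    "lowpass",
    "detrend_linear",
    "compute_reof",
    "remove_mode",
    "windowed_trend_map",
]


@dataclass
class GriddedField:
    """Monthly lat×lon field with a time-constant missing-value (land) mask.

    Wraps an ``xarray.DataArray`` with dims ``(time, lat, lon)``; masked cells
    are NaN at every time step.
    """

    data: xr.DataArray

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError(f"expected dims (time, lat, lon), got {self.data.dims}")
        for c in ("lat", "lon"):
            v = self.data[c].values
            if len(v) > 1 and not (np.all(np.diff(v) > 0) or np.all(np.diff(v) < 0)):
                raise ValueError(f"coordinate {c} must be monotone")
        finite = np.isfinite(self.data.values)
        if finite.size and not np.all(finite.all(axis=0) | (~finite).all(axis=0)):
            raise ValueError("missing-value mask must be constant in time")

    @property
    def lats(self) -> np.ndarray:
        return self.data["lat"].values

    @property
    def lons(self) -> np.ndarray:
        return self.data["lon"].values

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data["time"].values)

    @property
    def mask(self) -> np.ndarray:
        """2-D boolean, True where the cell is masked (land)."""
        return ~np.isfinite(self.data.values).all(axis=0)

    @property
    def values(self) -> np.ndarray:
        return self.data.values


@dataclass(frozen=True)
class FilterSpec:
    """Symmetric unit-sum low-pass filter weights."""

    cutoff_months: float
    n_weights: int
    weights: np.ndarray

    def response(self, freq_cycles_per_month: float) -> float:
        """Gain of the filter at a given frequency, by direct Fourier sum."""
        k = np.arange(self.n_weights) - self.n_weights // 2
        return float(np.sum(self.weights * np.cos(2 * np.pi * freq_cycles_per_month * k)))


def lanczos_weights(cutoff_months: float, n_weights: int) -> FilterSpec:
    """Lanczos low-pass weights: sinc response tapered by the sigma factor.

    ``cutoff_months`` is the cutoff *period*; frequencies above 1/cutoff are
    suppressed.  Weights are normalised to unit sum so the gain at frequency
    zero is exactly 1.  A cutoff at or below 2 months (the Nyquist period of
    monthly data) is rejected.
    """
    if n_weights % 2 == 0 or n_weights < 3:
        raise ValueError("n_weights must be odd and >= 3")
    if cutoff_months <= 2:
        raise ValueError("cutoff period must exceed 2 months (Nyquist)")
    if n_weights == 3:
        warnings.warn("3-weight Lanczos filter is nearly all-pass", stacklevel=2)
    fc = 1.0 / cutoff_months
    half = n_weights // 2
    k = np.arange(-half, half + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.sinc(2 * fc * k) * 2 * fc * np.sinc(k / (half + 1))
    w /= w.sum()
    return FilterSpec(cutoff_months=cutoff_months, n_weights=n_weights, weights=w)


def _lowpass_1d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.convolve(x, w, mode="valid")


def lowpass(obj, spec: FilterSpec):
    """Convolve along time with the filter weights, trimming a half-window at
    each end.  Accepts a 1-D array, a DataArray with a ``time`` dim, or a
    :class:`GriddedField`; returns the same type with shortened time axis.
    """
    w = spec.weights
    half = spec.n_weights // 2
    if isinstance(obj, GriddedField):
        return GriddedField(lowpass(obj.data, spec))
    if isinstance(obj, xr.DataArray):
        if obj.sizes["time"] <= spec.n_weights:
            raise ValueError("series shorter than the filter window")
        vals = np.apply_along_axis(_lowpass_1d, obj.get_axis_num("time"), obj.values, w)
        coords = {k: (obj["time"].values[half:-half] if k == "time" else obj[k]) for k in obj.coords}
        return xr.DataArray(vals, dims=obj.dims, coords=coords, name=obj.name, attrs=obj.attrs)
    x = np.asarray(obj, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series, a DataArray or a GriddedField")
    if len(x) <= spec.n_weights:
        raise ValueError("series shorter than the filter window")
    return _lowpass_1d(x, w)


def detrend_linear(field: GriddedField) -> tuple[GriddedField, xr.DataArray]:
    """Remove a per-gridpoint least-squares line (including the mean).

    Returns the anomaly field and the removed slopes in °C per month of the
    time index.  All-masked gridpoints stay masked.
    """
    v = field.values
    nt = v.shape[0]
    if nt < 2:
        raise ValueError("need >= 2 time steps to detrend")
    t = np.arange(nt, dtype=float)
    X = np.column_stack([np.ones(nt), t])
    flat = v.reshape(nt, -1)
    ocean = np.isfinite(flat).all(axis=0)
    coef = np.zeros((2, flat.shape[1]))
    coef[:, ocean] = np.linalg.lstsq(X, flat[:, ocean], rcond=None)[0]
    resid = np.full_like(flat, np.nan)
    resid[:, ocean] = flat[:, ocean] - X @ coef[:, ocean]
    slopes = np.full(flat.shape[1], np.nan)
    slopes[ocean] = coef[1, ocean]
    anom = field.data.copy(data=resid.reshape(v.shape))
    slope_da = xr.DataArray(
        slopes.reshape(v.shape[1:]),
        dims=("lat", "lon"),
        coords={"lat": field.data["lat"], "lon": field.data["lon"]},
        name="slope_per_month",
    )
    return GriddedField(anom), slope_da


@dataclass
class REOFDecomposition:
    """EOF decomposition of a space-time anomaly field with optional varimax
    rotation of the leading ``n_rotated`` modes.

    Patterns live in the (optionally √cos-latitude weighted) flattened ocean
    space; use :meth:`pattern_map` to re-grid one with land as NaN.  Unrotated
    patterns are orthonormal and ordered by explained variance; rotated
    patterns are loadings (variance-carrying) whose summed explained variance
    equals that of the unrotated k-mode subspace.
    """

    rotation: str  # "none" | "varimax"
    n_rotated: int
    patterns: np.ndarray  # (n_space, n_modes) unrotated orthonormal EOFs
    coefficients: np.ndarray  # (n_time, n_modes) unrotated PCs (= U S)
    variance_fractions: np.ndarray  # per unrotated mode
    rot_patterns: np.ndarray | None  # (n_space, k) rotated loadings
    rot_coefficients: np.ndarray | None  # (n_time, k), orthonormal columns
    rot_variance_fractions: np.ndarray | None
    total_variance: float
    weights: np.ndarray  # (n_space,) area weights applied before the SVD
    ocean: np.ndarray  # flat boolean ocean mask
    grid_shape: tuple[int, int]
    lats: np.ndarray = dc_field(repr=False, default=None)
    lons: np.ndarray = dc_field(repr=False, default=None)

    def _mode(self, mode: int, rotated: bool) -> tuple[np.ndarray, np.ndarray]:
        if rotated:
            if self.rot_patterns is None:
                raise ValueError("decomposition was not rotated")
            if not 0 <= mode < self.n_rotated:
                raise IndexError(f"rotated mode {mode} out of range")
            return self.rot_patterns[:, mode], self.rot_coefficients[:, mode]
        if not 0 <= mode < self.patterns.shape[1]:
            raise IndexError(f"mode {mode} out of range")
        return self.patterns[:, mode], self.coefficients[:, mode]

    def pattern_map(self, mode: int, rotated: bool = True) -> np.ndarray:
        p, _ = self._mode(mode, rotated)
        out = np.full(self.ocean.shape, np.nan)
        out[self.ocean] = p
        return out.reshape(self.grid_shape)

    def expansion_coefficient(self, mode: int, rotated: bool = True) -> np.ndarray:
        return self._mode(mode, rotated)[1]

    def reconstruct_mode(self, mode: int, rotated: bool = True) -> np.ndarray:
        """Physical-units (unweighted) anomaly contribution of one mode,
        shape (time, n_ocean)."""
        p, c = self._mode(mode, rotated)
        return np.outer(c, p / self.weights)

    def reconstruct(self) -> np.ndarray:
        """Full reconstruction from all unrotated modes (time, n_ocean),
        physical units."""
        return (self.coefficients @ self.patterns.T) / self.weights


def _varimax_rotation(L: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal rotation matrix maximising the varimax criterion of ``L``."""
    p, k = L.shape
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return R


def compute_reof(
    field: GriddedField,
    k: int,
    area_weight: bool = True,
    reference_point: tuple[float, float] | None = None,
) -> REOFDecomposition:
    """EOFs by SVD of the (area-weighted) anomaly matrix; varimax-rotate the
    leading ``k`` loadings.

    ``reference_point`` (lat, lon) pins the sign of every mode so the pattern
    value nearest that point is positive; by default the gridpoint of maximum
    absolute loading of each mode is pinned positive.  EOF signs are otherwise
    arbitrary, and a reproducible convention is required for testing.
    """
    v = field.values
    nt = v.shape[0]
    flat = v.reshape(nt, -1)
    ocean = np.isfinite(flat).all(axis=0)
    n_space = int(ocean.sum())
    if n_space == 0:
        raise ValueError("field is fully masked")
    lat_w = np.sqrt(np.clip(np.cos(np.deg2rad(field.lats)), 0, None))
    w2d = np.repeat(lat_w[:, None], len(field.lons), axis=1).ravel()
    weights = w2d[ocean] if area_weight else np.ones(n_space)
    Z = flat[:, ocean] * weights
    if not (1 <= k <= min(Z.shape)):
        raise ValueError(f"k must be in [1, {min(Z.shape)}], got {k}")

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the anomaly matrix")
    total = float((S**2).sum())
    patterns = Vt.T  # orthonormal columns
    coefficients = U * S

    # sign convention on unrotated modes
    if reference_point is not None:
        ref = _flat_ref_index(field, ocean, reference_point)
    else:
        ref = None
    for m in range(patterns.shape[1]):
        idx = ref if ref is not None else int(np.argmax(np.abs(patterns[:, m])))
        if patterns[idx, m] < 0:
            patterns[:, m] *= -1
            coefficients[:, m] *= -1

    L = patterns[:, :k] * S[:k]
    R = _varimax_rotation(L)
    rot_patterns = L @ R
    rot_coefficients = (coefficients[:, :k] / S[:k]) @ R
    for m in range(k):
        idx = ref if ref is not None else int(np.argmax(np.abs(rot_patterns[:, m])))
        if rot_patterns[idx, m] < 0:
            rot_patterns[:, m] *= -1
            rot_coefficients[:, m] *= -1
    rot_var = (rot_patterns**2).sum(axis=0)
    order = np.argsort(rot_var)[::-1]
    rot_patterns = rot_patterns[:, order]
    rot_coefficients = rot_coefficients[:, order]
    rot_var = rot_var[order]

    return REOFDecomposition(
        rotation="varimax",
        n_rotated=k,
        patterns=patterns,
        coefficients=coefficients,
        variance_fractions=S**2 / total,
        rot_patterns=rot_patterns,
        rot_coefficients=rot_coefficients,
        rot_variance_fractions=rot_var / total,
        total_variance=total,
        weights=weights,
        ocean=ocean,
        grid_shape=(len(field.lats), len(field.lons)),
        lats=field.lats,
        lons=field.lons,
    )


def _flat_ref_index(field: GriddedField, ocean: np.ndarray, point: tuple[float, float]) -> int:
    iy = int(np.argmin(np.abs(field.lats - point[0])))
    ix = int(np.argmin(np.abs(field.lons - point[1])))
    flat_idx = iy * len(field.lons) + ix
    if not ocean[flat_idx]:
        raise ValueError("reference point falls on a masked gridpoint")
    return int(np.cumsum(ocean)[flat_idx] - 1)


def remove_mode(field: GriddedField, decomp: REOFDecomposition, mode: int,
                rotated: bool = True) -> GriddedField:
    """Subtract one mode's reconstruction from ``field`` (e.g. the ENSO mode
    from the filtered-but-not-detrended SST).

    The decomposition may come from a detrended version of the field; only the
    time length and grid must match.  Removing a mode whose coefficients are
    all zero returns the field unchanged.
    """
    v = field.values
    flat = v.reshape(v.shape[0], -1)
    if flat.shape[0] != decomp.coefficients.shape[0]:
        raise ValueError("field time length does not match the decomposition")
    recon = decomp.reconstruct_mode(mode, rotated=rotated)
    out = flat.copy()
    out[:, decomp.ocean] = out[:, decomp.ocean] - recon
    return GriddedField(field.data.copy(data=out.reshape(v.shape)))


@dataclass
class TrendMap:
    """Per-gridpoint Sen's slope (°C per decade) with MK significance class
    (0 none, 1 p<0.05, 2 p<0.01) over one time window."""

    window: tuple[int, int]
    slopes: xr.DataArray  # °C / decade
    significance: xr.DataArray  # int8


def auto_windows(times: pd.DatetimeIndex, length_years: int = 30) -> list[tuple[int, int]]:
    """Consecutive non-overlapping windows of ``length_years`` from the start
    of the record; a trailing partial window is dropped."""
    y0 = times[0].year if times[0].month == 1 else times[0].year + 1
    y1 = times[-1].year if times[-1].month == 12 else times[-1].year - 1
    out = []
    s = y0
    while s + length_years - 1 <= y1:
        out.append((s, s + length_years - 1))
        s += length_years
    return out


def windowed_trend_map(
    field: GriddedField,
    windows: Sequence[tuple[int, int]] | str = "auto30",
    min_coverage: float = 0.8,
) -> list[TrendMap]:
    """Sen's-slope trend maps with Mann-Kendall significance per 30-yr window.

    A gridpoint is evaluated when at least ``min_coverage`` of the window's
    months are present; otherwise it is masked.  Slopes are converted from
    per-month to °C per decade.
    """
    times = field.times
    if windows == "auto30":
        windows = auto_windows(times, 30)
    out = []
    v = field.values
    for (y0, y1) in windows:
        sel = (times.year >= y0) & (times.year <= y1)
        n_expect = 12 * (y1 - y0 + 1)
        if sel.sum() < n_expect:
            raise ValueError(f"window {y0}-{y1} not fully covered by the record")
        sub = v[sel]
        nt = sub.shape[0]
        t_years = np.arange(nt) / 12.0
        slopes = np.full(sub.shape[1:], np.nan)
        sig = np.zeros(sub.shape[1:], dtype=np.int8)
        for iy in range(sub.shape[1]):
            for ix in range(sub.shape[2]):
                x = sub[:, iy, ix]
                good = np.isfinite(x)
                if good.sum() < min_coverage * nt or good.sum() < 4:
                    continue
                res = sens_slope(x[good], t_years[good])
                slopes[iy, ix] = res.slope * 10.0  # per decade
                sig[iy, ix] = mann_kendall(x[good]).significance_level()
        coords = {"lat": field.data["lat"], "lon": field.data["lon"]}
        out.append(
            TrendMap(
                window=(y0, y1),
                slopes=xr.DataArray(slopes, dims=("lat", "lon"), coords=coords, name="trend"),
                significance=xr.DataArray(sig, dims=("lat", "lon"), coords=coords, name="significance"),
            )
        )
    return out
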
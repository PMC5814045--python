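"""Nonparametric trend statistics shared by the gridded-SST and station pipelines.

Single source of truth for Sen's slope (median of all pairwise slopes, via
``scipy.stats.theilslopes``) and the Mann-Kendall monotone-trend test with tie
correction and continuity correction.  Missing values (NaN) are simply dropped,
which reduces the effective sample size — the appropriate treatment for gappy
observational series.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SenSlopeResult", "MannKendallResult", "sens_slope", "mann_kendall"]


@dataclass(frozen=True)
class SenSlopeResult:
    slope: float
    intercept: float
    n: int


@dataclass(frozen=True)
class MannKendallResult:
    S: int
    var_S: float
    Z: float
    p: float
    n: int
    trend: str  # "increasing" | "decreasing" | "none"

    def significance_level(self) -> int:
        """0 = not significant, 1 = p<0.05, 2 = p<0.01."""
        if self.p < 0.01:
            return 2
        if self.p < 0.05:
            return 1
        return 0


def _clean(values, times):
    x = np.asarray(values, dtype=float)
    if times is None:
        t = np.arange(len(x), dtype=float)
    else:
        t = np.asarray(times, dtype=float)
        if len(t) != len(x):
            raise ValueError("times and values must have equal length")
    keep = np.isfinite(x)
    return x[keep], t[keep]


def sens_slope(values, times=None) -> SenSlopeResult:
    """Sen's slope: median of (x_j − x_i)/(t_j − t_i) over all pairs i<j.

    NaNs are dropped; at least two finite points are required.  Units are value
    per unit of ``times`` (index steps if ``times`` is omitted).
    """
    x, t = _clean(values, times)
    if len(x) < 2:
        raise ValueError("sens_slope needs >= 2 non-missing points")
    slope, intercept, _, _ = stats.theilslopes(x, t)
    return SenSlopeResult(slope=float(slope), intercept=float(intercept), n=len(x))


def _mk_s_and_ties(x: np.ndarray) -> tuple[int, np.ndarray]:
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    return s, counts[counts > 1]


def mann_kendall(values, times=None, method: str = "normal") -> MannKendallResult:
    """Mann-Kendall test for a monotone trend, two-sided.

    S = Σ_{i<j} sign(x_j − x_i); Var(S) carries the standard tie correction;
    Z applies the ±1 continuity correction.  ``method='exact'`` replaces the
    normal approximation with the exact permutation null of S (n ≤ 9 only,
    valid for tie-free data).  Requires ≥ 4 non-missing points; an all-equal
    series returns S=0, Z=0, p=1.
    """
    x, _t = _clean(values, times)
    n = len(x)
    if n < 4:
        raise ValueError(f"mann_kendall needs >= 4 non-missing points, got {n}")
    s, tie_counts = _mk_s_and_ties(x)
    var_s = (n * (n - 1) * (2 * n + 5) - sum(t * (t - 1) * (2 * t + 5) for t in tie_counts)) / 18.0

    if var_s <= 0:  # all values tied
        return MannKendallResult(S=s, var_S=0.0, Z=0.0, p=1.0, n=n, trend="none")

    if method == "exact":
        if n > 9:
            raise ValueError("exact permutation null supported for n <= 9")
        if len(tie_counts):
            raise ValueError("exact null assumes tie-free data")
        null_s = np.array(
            [_mk_s_and_ties(np.array(perm))[0] for perm in itertools.permutations(x)]
        )
        p = float(np.mean(np.abs(null_s) >= abs(s)))
        z = (s - np.sign(s)) / math.sqrt(var_s) if s != 0 else 0.0
    elif method == "normal":
        z = (s - np.sign(s)) / math.sqrt(var_s) if s != 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        raise ValueError(f"unknown method {method!r}")

    trend = "none"
    if p < 0.05:
        trend = "increasing" if s > 0 else "decreasing"
    return MannKendallResult(S=s, var_S=float(var_s), Z=float(z), p=float(p), n=n, trend=trend)
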
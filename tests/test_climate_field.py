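"""Gridded-SST machinery: filter design, detrending, REOF/varimax, mode removal
and windowed trend maps, validated against planted-truth synthetic fields."""

import subprocess
import textwrap

import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as hst

from sealtrend import (
    GriddedField,
    compute_reof,
    detrend_linear,
    lanczos_weights,
    lowpass,
    remove_mode,
    windowed_trend_map,
)
from sealtrend.climate_field import _varimax_rotation, auto_windows
from sealtrend.synthetic import gen_sst_field

LATS = np.arange(10.0, 41.0, 5.0)
LONS = np.arange(200.0, 241.0, 5.0)


def dft_gain(weights, freq):
    """Independent oracle: modulus of the weights' transfer function."""
    k = np.arange(len(weights)) - len(weights) // 2
    return abs(np.sum(weights * np.exp(-2j * np.pi * freq * k)))


class TestLanczosWeights:
    @given(
        n=hst.integers(2, 40).map(lambda i: 2 * i + 1),
        cutoff=hst.floats(3.0, 60.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_unit_sum_and_symmetry(self, n, cutoff):
        spec = lanczos_weights(cutoff, n)
        assert spec.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(spec.weights, spec.weights[::-1])

    def test_annual_cycle_suppressed_at_default_window(self):
        """DFT oracle: the 61-weight, 14.4-month-cutoff filter passes the mean
        (gain 1 at f=0) and suppresses the annual harmonic below 0.1."""
        spec = lanczos_weights(14.4, 61)
        assert dft_gain(spec.weights, 0.0) == pytest.approx(1.0, abs=1e-12)
        g = dft_gain(spec.weights, 1.0 / 12.0)
        assert g < 0.1
        assert spec.response(1.0 / 12.0) == pytest.approx(g, abs=1e-9)

    def test_degenerate_three_weight_filter_warns(self):
        with pytest.warns(UserWarning):
            spec = lanczos_weights(14.4, 3)
        assert spec.weights.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("n,cutoff", [(4, 14.4), (10, 14.4), (37, 2.0), (37, 1.0)])
    def test_invalid_specs_rejected(self, n, cutoff):
        with pytest.raises(ValueError):
            lanczos_weights(cutoff, n)


class TestLowpass:
    SPEC_N = 61

    def test_constant_series_unchanged(self):
        spec = lanczos_weights(14.4, self.SPEC_N)
        out = lowpass(np.full(200, 15.0), spec)
        assert np.allclose(out, 15.0)
        assert len(out) == 200 - (self.SPEC_N - 1)

    def test_annual_sinusoid_attenuated_to_filter_gain(self):
        spec = lanczos_weights(14.4, self.SPEC_N)
        t = np.arange(600)
        out = lowpass(np.sin(2 * np.pi * t / 12.0), spec)
        expected = dft_gain(spec.weights, 1 / 12)
        assert np.abs(out).max() <= expected + 1e-9
        assert np.abs(out).max() < 0.1

    def test_linear_ramp_slope_preserved(self):
        spec = lanczos_weights(14.4, self.SPEC_N)
        out = lowpass(0.03 * np.arange(300) + 2.0, spec)
        assert np.allclose(np.diff(out), 0.03, atol=1e-9)

    def test_commutes_with_constant_offset(self):
        spec = lanczos_weights(14.4, self.SPEC_N)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 300)
        assert np.allclose(lowpass(x + 7.5, spec), lowpass(x, spec) + 7.5)

    def test_field_time_axis_trimmed(self):
        field, _ = gen_sst_field(LATS, LONS, 120, seed=0)
        spec = lanczos_weights(14.4, self.SPEC_N)
        out = lowpass(field, spec)
        half = self.SPEC_N // 2
        assert out.values.shape[0] == 120 - 2 * half
        assert out.times[0] == field.times[half]

    def test_too_short_series_rejected(self):
        spec = lanczos_weights(14.4, self.SPEC_N)
        with pytest.raises(ValueError):
            lowpass(np.zeros(40), spec)


class TestDetrend:
    def test_pure_line_gives_zero_anomalies(self):
        t = np.arange(60, dtype=float)
        vals = np.broadcast_to((0.01 * t + 3.0)[:, None, None], (60, LATS.size, LONS.size))
        field = GriddedField(
            xr.DataArray(
                np.array(vals), dims=("time", "lat", "lon"),
                coords={"time": np.arange(60), "lat": LATS, "lon": LONS},
            )
        )
        anom, slopes = detrend_linear(field)
        assert np.allclose(anom.values, 0.0, atol=1e-10)
        assert np.allclose(slopes.values, 0.01)

    def test_masked_gridpoint_stays_masked(self):
        mask = np.zeros((LATS.size, LONS.size), bool)
        mask[2, 3] = True
        field, _ = gen_sst_field(LATS, LONS, 60, land_mask=mask, seed=1)
        anom, slopes = detrend_linear(field)
        assert np.isnan(anom.values[:, 2, 3]).all()
        assert np.isnan(slopes.values[2, 3])
        assert np.isfinite(anom.values[:, 0, 1]).all()

    def test_white_noise_residual_slope_near_zero(self, rng):
        vals = rng.normal(0, 1, (240, 4, 4))
        field = GriddedField(
            xr.DataArray(
                vals, dims=("time", "lat", "lon"),
                coords={"time": np.arange(240), "lat": LATS[:4], "lon": LONS[:4]},
            )
        )
        anom, _ = detrend_linear(field)
        _, refit = detrend_linear(anom)
        assert np.abs(refit.values).max() < 1e-12


def _planted_field(seed=3, noise=0.1, amp=1.5):
    pattern = np.outer(np.exp(-(((LATS - 15) / 8.0) ** 2)), np.cos(np.linspace(0, np.pi, LONS.size)))
    field, truth = gen_sst_field(
        LATS, LONS, 480, trend_per_decade=0.0, modes=[(pattern, 42.0, amp)],
        noise_sd=noise, annual_cycle_amp=0.0, seed=seed,
    )
    return detrend_linear(field)[0], truth


class TestREOF:
    def test_planted_mode_coefficient_recovered(self):
        anom, truth = _planted_field()
        dec = compute_reof(anom, k=3)
        corr = np.corrcoef(dec.expansion_coefficient(0), truth.mode_signals[0])[0, 1]
        assert abs(corr) >= 0.99

    def test_unrotated_patterns_orthonormal_and_fractions_ordered(self):
        anom, _ = _planted_field()
        dec = compute_reof(anom, k=3)
        gram = dec.patterns.T @ dec.patterns
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert (np.diff(dec.variance_fractions) <= 1e-12).all()

    def test_varimax_preserves_subspace_variance(self):
        anom, _ = _planted_field(noise=0.3)
        k = 5
        dec = compute_reof(anom, k=k)
        unrot = dec.variance_fractions[:k].sum()
        rot = dec.rot_variance_fractions.sum()
        assert abs(rot - unrot) <= 1e-8 * unrot

    def test_sign_flip_of_input_leaves_reconstruction_identical(self):
        anom, _ = _planted_field()
        flipped = GriddedField(anom.data * -1.0)
        d1 = compute_reof(anom, k=2)
        d2 = compute_reof(flipped, k=2)
        assert np.allclose(d1.reconstruct(), -d2.reconstruct(), atol=1e-9)

    def test_k_beyond_rank_rejected(self):
        anom, _ = _planted_field()
        with pytest.raises(ValueError):
            compute_reof(anom, k=10**6)

    def test_varimax_matches_r_reference(self, tmp_path):
        """Cross-check the varimax rotation against R's stats::varimax on a
        fixed loading matrix: same criterion value, same subspace."""
        rng = np.random.default_rng(42)
        L = rng.normal(0, 1, (12, 3))
        R = _varimax_rotation(L)
        ours = L @ R

        def criterion(A):
            sq = A**2
            return (sq**2).sum(axis=0).sum() - (sq.sum(axis=0) ** 2).sum() / A.shape[0]

        csv = tmp_path / "L.csv"
        np.savetxt(csv, L, delimiter=",")
        rscript = textwrap.dedent(
            f"""
            L <- as.matrix(read.csv("{csv}", header=FALSE))
            v <- varimax(L, normalize=FALSE, eps=1e-12)
            write.table(unclass(v$loadings), "{tmp_path / 'out.csv'}",
                        sep=",", row.names=FALSE, col.names=FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        theirs = np.loadtxt(tmp_path / "out.csv", delimiter=",")
        assert criterion(ours) == pytest.approx(criterion(theirs), rel=1e-6)
        # identical column spans: cross-projection is orthogonal
        q_ours, _ = np.linalg.qr(ours)
        q_theirs, _ = np.linalg.qr(theirs)
        s = np.linalg.svd(q_ours.T @ q_theirs, compute_uv=False)
        assert np.allclose(s, 1.0, atol=1e-8)


class TestRemoveMode:
    def test_zero_coefficient_mode_is_identity(self):
        anom, _ = _planted_field()
        dec = compute_reof(anom, k=2)
        dec.rot_coefficients[:, 1] = 0.0
        out = remove_mode(anom, dec, 1)
        assert np.array_equal(out.values, anom.values, equal_nan=True)

    def test_full_reconstruction_subtracts_to_zero(self):
        anom, _ = _planted_field(noise=0.2)
        dec = compute_reof(anom, k=2)
        flat = anom.values.reshape(anom.values.shape[0], -1)[:, dec.ocean]
        resid = flat - dec.reconstruct()
        assert np.abs(resid).max() < 1e-8 * np.abs(flat).max()

    def test_out_of_range_mode_rejected(self):
        anom, _ = _planted_field()
        dec = compute_reof(anom, k=2)
        with pytest.raises(IndexError):
            remove_mode(anom, dec, 5)

    def test_planted_trend_survives_enso_removal(self):
        """Removing the planted oscillatory mode from a trending field leaves
        the planted trend at every gridpoint."""
        pattern = np.outer(np.exp(-(((LATS - 15) / 8.0) ** 2)), np.ones(LONS.size))
        field, truth = gen_sst_field(
            LATS, LONS, 480, trend_per_decade=0.12, modes=[(pattern, 42.0, 1.5)],
            noise_sd=0.05, annual_cycle_amp=0.0, start="1960-01-01", seed=9,
        )
        detrended, _ = detrend_linear(field)
        dec = compute_reof(detrended, k=2)
        resid = remove_mode(field, dec, 0)
        maps = windowed_trend_map(resid, [(1960, 1989)])
        slopes = maps[0].slopes.values
        assert np.nanmedian(np.abs(slopes - 0.12)) < 0.03


class TestWindowedTrends:
    def test_constant_field_flat_and_unflagged(self):
        field, _ = gen_sst_field(
            LATS[:4], LONS[:4], 360, noise_sd=0.0, annual_cycle_amp=0.0,
            start="1900-01-01", seed=0,
        )
        maps = windowed_trend_map(field, [(1900, 1929)])
        assert np.allclose(maps[0].slopes.values, 0.0, atol=1e-12)
        assert (maps[0].significance.values == 0).all()

    def test_planted_spatial_trend_pattern_recovered(self):
        trend_map = np.where(LATS[:, None] < 30.0, 0.12, 0.0) * np.ones((1, LONS.size))
        field, _ = gen_sst_field(
            LATS, LONS, 360, trend_per_decade=trend_map, noise_sd=0.05,
            annual_cycle_amp=0.0, start="1900-01-01", seed=11,
        )
        maps = windowed_trend_map(field, [(1900, 1929)])
        south = LATS < 30
        slopes = maps[0].slopes.values
        sig = maps[0].significance.values
        assert np.all(slopes[south] > 0.08)
        assert np.abs(slopes[~south]).max() < 0.04
        assert (sig[south] > 0).mean() >= 0.9

    def test_incomplete_window_rejected(self):
        field, _ = gen_sst_field(LATS[:3], LONS[:3], 120, start="1900-01-01", seed=0)
        with pytest.raises(ValueError, match="not fully covered"):
            windowed_trend_map(field, [(1900, 1929)])

    def test_auto_windows_are_consecutive_thirty_year_spans(self):
        field, _ = gen_sst_field(LATS[:3], LONS[:3], 12 * 95, start="1897-01-01", seed=0)
        wins = auto_windows(field.times)
        assert wins == [(1897, 1926), (1927, 1956), (1957, 1986)]
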
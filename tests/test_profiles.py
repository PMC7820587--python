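import numpy as np
import pytest

import lambold as lb
from lambold.profiles import (
    DepthSeries,
    activation_metrics,
    filter_by_thickness,
    gm_pial_ratio,
    highpass_cutoff,
    highpass_filter,
    integrate_depth,
    normalize_profiles,
    te_over_t2s,
)
from lambold.protocol import alternating_paradigm


def tiny_depth_series(signal, paradigm, depth_bins=(8, 13), te=(20.0, 40.0)):
    return DepthSeries(
        depth_bins=np.asarray(depth_bins),
        signal=np.asarray(signal, dtype=float),
        n_voxels=np.full(len(depth_bins), 1),
        echo_times_ms=np.asarray(te),
        volume_tr=97.0,
        paradigm=tuple(paradigm),
        n_depth_bins_total=15,
    )


class TestThicknessFilter:
    def test_identity_when_all_thin(self):
        g = lb.make_default_grid(30, thickness_mm=2.0)
        out, removed = filter_by_thickness(g, 2.5)
        assert removed == 0 and out.n_voxels == 30

    def test_threshold_rule(self):
        g = lb.VoxelGrid(
            n_voxels=3,
            depth_bin=(8, 8, 8),
            in_v1=(True,) * 3,
            in_activation_mask=(True,) * 3,
            thickness=(2.0, 2.6, 3.0),
        )
        out, removed = filter_by_thickness(g)  # default 2.5 mm
        assert removed == 2 and out.n_voxels == 1
        assert out.thickness == (2.0,)

    def test_requires_thickness(self):
        g = lb.make_default_grid(5, thickness_mm=None)
        with pytest.raises(ValueError, match="thickness"):
            filter_by_thickness(g)


class TestHighpass:
    def test_cutoff_formula(self):
        assert highpass_cutoff(97.0) == pytest.approx(1.0 / (2.1 * 97.0))
        assert highpass_cutoff(97.0) == pytest.approx(4.91e-3, rel=0.01)
        with pytest.raises(ValueError):
            highpass_cutoff(0.0)

    def test_constant_preserved(self):
        x = np.full(100, 7.0)
        assert np.allclose(highpass_filter(x, 0.02, 1.0), x)

    def test_sinusoid_above_cutoff_passes(self):
        # cosine at 2 f_c on the drift-basis frequency grid: exactly
        # orthogonal to every drift regressor, so it passes untouched
        n = 200
        t = np.arange(n, dtype=float)
        f_c = 0.02
        k = int(2 * f_c * 2 * n)  # DCT index at frequency 2 f_c
        x = np.cos(np.pi * k * (t + 0.5) / n)
        y = highpass_filter(x, f_c, 1.0)
        assert np.max(np.abs(y - x)) < 1e-8

    def test_slow_drift_removed(self):
        t = np.arange(200, dtype=float)
        f_c = 0.02
        drift = 5.0 * np.cos(2 * np.pi * 0.005 * t + 0.3)
        y = highpass_filter(10.0 + drift, f_c, 1.0)
        assert np.std(y) < 0.1 * np.std(drift)
        assert y.mean() == pytest.approx(10.0 + drift.mean(), rel=1e-6)

    def test_short_series_identity_with_warning(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="shorter"):
            y = highpass_filter(x, 0.02, 1.0)
        assert np.array_equal(x, y)


class TestIntegrateDepth:
    def test_single_voxel_roi(self, noiseless_ts7):
        roi = np.zeros(noiseless_ts7.grid.n_voxels, dtype=bool)
        roi[5] = True
        ds = integrate_depth(noiseless_ts7, roi)
        assert ds.signal.shape[0] == 1
        assert np.array_equal(ds.signal[0], noiseless_ts7.signal[5])

    def test_two_voxel_mean(self, noiseless_ts7):
        depth = noiseless_ts7.grid.depth_bin_array
        idx = np.flatnonzero(depth == 8)[:2]
        roi = np.zeros(depth.size, dtype=bool)
        roi[idx] = True
        ds = integrate_depth(noiseless_ts7, roi)
        expected = noiseless_ts7.signal[idx].mean(axis=0)
        assert np.allclose(ds.signal[ds.depth_bins == 8][0], expected)

    def test_round_trip_vs_noiseless(self, noiseless_ts7, tissue7_v0, protocol7):
        ds = integrate_depth(noiseless_ts7)
        for k, b in enumerate(ds.depth_bins):
            for t, state in enumerate(protocol7.paradigm):
                expected = lb.simulate_noiseless(protocol7, tissue7_v0, int(b), state)
                assert np.allclose(ds.signal[k, :, t], expected, rtol=1e-12)

    def test_empty_roi_rejected(self, noiseless_ts7):
        with pytest.raises(ValueError, match="empty"):
            integrate_depth(noiseless_ts7, np.zeros(noiseless_ts7.grid.n_voxels, bool))


class TestActivationMetrics:
    def test_cnr_unity_when_delta_equals_sigma(self):
        # rest volumes alternate 99/101 (SD sqrt(2)), active shifted by sqrt(2)
        rest = np.array([99.0, 101.0, 99.0, 101.0])
        shift = rest.std(ddof=1)
        sig = np.empty((1, 1, 8))
        sig[0, 0, ::2] = rest
        sig[0, 0, 1::2] = rest + shift
        ds = tiny_depth_series(sig, alternating_paradigm(8), depth_bins=(8,), te=(20.0,))
        prof = activation_metrics(ds)
        assert prof.cnr[0, 0] == pytest.approx(1.0)

    def test_no_change_gives_zero_delta_and_t(self):
        sig = np.tile(np.array([5.0, 6.0, 6.0, 5.0]), (1, 1, 1))
        ds = tiny_depth_series(sig, ("rest", "active", "rest", "active"), depth_bins=(8,), te=(20.0,))
        prof = activation_metrics(ds)
        assert prof.delta_s[0, 0] == pytest.approx(0.0)
        assert prof.t_score[0, 0] == pytest.approx(0.0)

    def test_zero_rest_sd_flags_cnr_nan(self):
        sig = np.zeros((1, 1, 4))
        sig[0, 0] = [1.0, 2.0, 1.0, 2.0]
        ds = tiny_depth_series(sig, ("rest", "active", "rest", "active"), depth_bins=(8,), te=(20.0,))
        with pytest.warns(UserWarning, match="CNR"):
            prof = activation_metrics(ds)
        assert np.isnan(prof.cnr[0, 0])
        assert np.isfinite(prof.delta_s[0, 0])

    def test_noiseless_synthetic_profiles_ascend(self, noiseless_ts7):
        ds = integrate_depth(noiseless_ts7)
        prof = activation_metrics(ds)
        assert np.all(np.diff(prof.delta_s, axis=0) >= 0)

    def test_t_score_grows_with_sqrt_volumes(self, tissue7):
        """At fixed CNR the Welch t scales roughly with sqrt(n volumes)."""
        grid = lb.make_default_grid(120)
        tvals = {}
        for n in (40, 160):
            p = lb.make_default_protocol(7, n_volumes=n)
            ts = lb.simulate_timeseries(p, tissue7, lb.NoiseParams(sigma_thermal=10.0, seed=9), grid)
            prof = activation_metrics(integrate_depth(ts, grid.mask_array))
            tvals[n] = np.median(prof.t_score)
        assert tvals[160] / tvals[40] == pytest.approx(2.0, rel=0.35)


class TestNormalize:
    def test_constant_surface_becomes_ones(self):
        assert np.allclose(normalize_profiles(np.full((11, 10), 3.7)), 1.0)

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 2.0, size=(11, 10))
        n1 = normalize_profiles(x)
        assert np.allclose(normalize_profiles(5.0 * x), n1)
        assert np.allclose(normalize_profiles(n1), n1)
        assert n1.mean() == pytest.approx(1.0)

    def test_proportional_subjects_collapse(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.5, 2.0, size=(11, 10))
        assert np.allclose(normalize_profiles(x), normalize_profiles(2.3 * x))

    def test_zero_grand_mean_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_profiles(np.array([[1.0, -1.0]]))


class TestGmPialRatio:
    def test_equal_depths_give_unity(self):
        bins = np.arange(3, 14)
        delta = np.ones((11, 4))
        assert np.allclose(gm_pial_ratio(delta, bins), 1.0)

    def test_point_sixty_five(self):
        bins = np.array([8, 13])
        delta = np.array([[0.65], [1.0]])
        assert gm_pial_ratio(delta, bins)[0] == pytest.approx(0.65)

    def test_ascending_profile_below_unity(self, noiseless_ts7):
        prof = activation_metrics(integrate_depth(noiseless_ts7))
        ratio = prof.gm_pial_ratio()
        assert np.all(ratio < 1.0)

    def test_missing_bin_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            gm_pial_ratio(np.ones((2, 3)), np.array([8, 12]))

    def test_te_normalisation_axis(self):
        te = np.array([27.9, 55.8])
        assert np.allclose(te_over_t2s(te, 27.9), [1.0, 2.0])
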
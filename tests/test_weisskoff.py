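import numpy as np
import pytest

import lambold as lb
from lambold.weisskoff import (
    _detect_plateau_1d,
    detect_plateau,
    noise_vs_te,
    roi_arithmetic,
    voxels_for_volume,
    weisskoff_curve,
    weisskoff_curve_from_array,
)

from conftest import analytic_weisskoff_curve


def crossing_oracle(sigma_p, sigma_t, epsilon=0.05):
    """Closed-form band crossing of sqrt(p^2 + t^2/i)."""
    return sigma_t**2 / (sigma_p**2 * ((1 + epsilon) ** 2 - 1))


class TestCurve:
    def test_constant_series_gives_zero(self):
        x = np.tile(np.array([500.0]), (20, 1, 12))
        r = weisskoff_curve_from_array(x, [27.9], reference_index=0)
        assert np.allclose(r.sigma_n, 0.0)

    def test_thermal_only_follows_inverse_sqrt_law(self):
        """Average over seeds matches sigma_n(1)/sqrt(i)."""
        curves = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x = 1000.0 + rng.normal(0, 10.0, size=(300, 1, 150))
            r = weisskoff_curve_from_array(x, [27.9], reference_index=0, seed=seed)
            curves.append(r.sigma_n[:, 0])
        mean_curve = np.mean(curves, axis=0)
        law = mean_curve[0] / np.sqrt(np.arange(1, 301))
        assert np.max(np.abs(mean_curve / law - 1.0)) < 0.1

    def test_shared_only_curve_is_flat(self):
        rng = np.random.default_rng(0)
        shared = rng.normal(0, 5.0, size=150)
        x = 1000.0 + np.tile(shared, (200, 1, 1))
        r = weisskoff_curve_from_array(x, [27.9], reference_index=0)
        c = r.sigma_n[:, 0]
        assert c.max() / c.min() == pytest.approx(1.0, abs=1e-9)

    def test_full_roi_value_is_permutation_invariant(self):
        rng = np.random.default_rng(1)
        x = 1000.0 + rng.normal(0, 10.0, size=(64, 1, 60))
        vals = [
            weisskoff_curve_from_array(x, [27.9], reference_index=0, seed=s).sigma_n[-1, 0]
            for s in range(5)
        ]
        assert np.allclose(vals, vals[0])

    def test_seed_and_order_reproduce_curve(self):
        rng = np.random.default_rng(2)
        x = 1000.0 + rng.normal(0, 10.0, size=(50, 1, 40))
        a = weisskoff_curve_from_array(x, [27.9], reference_index=0, seed=3)
        b = weisskoff_curve_from_array(x, [27.9], reference_index=0, seed=3)
        assert np.array_equal(a.voxel_order, b.voxel_order)
        assert np.array_equal(a.sigma_n, b.sigma_n)

    def test_reference_echo_near_t2s(self, noiseless_ts7):
        r = weisskoff_curve(noiseless_ts7, seed=0)
        te_ref = r.echo_times_ms[r.reference_te_index]
        assert te_ref == pytest.approx(27.6)  # nearest acquired TE to 27.9 ms

    def test_far_reference_warns_and_falls_back(self):
        rng = np.random.default_rng(3)
        x = 1000.0 + rng.normal(0, 1.0, size=(20, 2, 12))
        with pytest.warns(UserWarning, match="nearest"):
            r = weisskoff_curve_from_array(x, [5.0, 8.0], t2s_ref_ms=50.0)
        assert r.reference_te_index == 1

    def test_input_validation(self):
        with pytest.raises(ValueError, match="voxels"):
            weisskoff_curve_from_array(np.ones((1, 1, 12)), [20.0])
        with pytest.raises(ValueError, match="resting"):
            weisskoff_curve_from_array(np.ones((5, 1, 3)), [20.0])


class TestDetectPlateau:
    def test_analytic_crossing_matches_closed_form(self):
        sigma_p, sigma_t = 1.0, np.sqrt(10.25)  # i* = 100 at epsilon = 0.05
        curve = analytic_weisskoff_curve(1000, sigma_p, sigma_t)
        n_phys, plateau = _detect_plateau_1d(curve, 0.2, 0.05)
        i_star = crossing_oracle(sigma_p, sigma_t)
        assert i_star == pytest.approx(100.0)
        assert abs(n_phys - i_star) <= 0.2 * i_star

    def test_flat_curve_detected_at_one(self):
        n_phys, plateau = _detect_plateau_1d(np.full(50, 0.01), 0.2, 0.05)
        assert n_phys == 1 and plateau == pytest.approx(0.01)

    def test_pure_thermal_curve_undetected(self):
        curve = analytic_weisskoff_curve(500, 0.0, 1.0)
        n_phys, _ = _detect_plateau_1d(curve, 0.2, 0.05)
        assert n_phys is None

    def test_pathological_curve_returns_undetected(self):
        n_phys, _ = _detect_plateau_1d(np.full(30, np.nan), 0.2, 0.05)
        assert n_phys is None

    def test_more_thermal_noise_delays_detection(self):
        """Monotone mixing: raising sigma_t at fixed sigma_p raises n_phys."""
        detections = []
        for sigma_t in (1.0, 2.0, 4.0):
            curve = analytic_weisskoff_curve(2000, 0.5, sigma_t)
            n_phys, _ = _detect_plateau_1d(curve, 0.2, 0.05)
            detections.append(n_phys)
        assert detections == sorted(detections) and detections[0] < detections[-1]

    def test_multi_seed_detection_stabilises(self):
        """The median over seeds recovers the closed-form crossing."""
        sigma_p, sigma_t = 1.0, np.sqrt(10.25)
        found = []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            x = (
                1000.0
                + np.tile(rng.normal(0, sigma_p, size=(1, 1, 250)), (600, 1, 1))
                + rng.normal(0, sigma_t, size=(600, 1, 250))
            )
            r = weisskoff_curve_from_array(x, [27.9], reference_index=0, seed=seed)
            n_phys, _ = detect_plateau(r)
            if n_phys is not None:
                found.append(n_phys)
        assert len(found) >= 15
        assert np.median(found) == pytest.approx(100, rel=0.25)


class TestNoiseVsTe:
    def _simulate(self, noise, n_volumes=160, n_voxels=300):
        p = lb.make_default_protocol(7, n_volumes=n_volumes)
        t = lb.make_default_tissue(7)
        g = lb.make_default_grid(n_voxels)
        return lb.simulate_timeseries(p, t, noise, g)

    def test_multiplicative_noise_classified_non_bold_like(self):
        ts = self._simulate(lb.NoiseParams(sigma_thermal=2.0, sigma_nonbold=0.01, seed=21))
        regime = noise_vs_te(weisskoff_curve(ts, seed=0))
        assert regime.classification == "non-BOLD-like dominated"
        # plateau tracks S(TE)
        usable = regime.table.dropna(subset=["n_phys"])
        corr = np.corrcoef(usable["s_te"], usable["plateau_level"])[0, 1]
        assert corr > 0.9

    def test_rate_fluctuation_noise_classified_bold_like(self):
        ts = self._simulate(lb.NoiseParams(sigma_thermal=2.0, sigma_delta_r2s=0.3, seed=22))
        regime = noise_vs_te(weisskoff_curve(ts, seed=0))
        assert regime.classification == "BOLD-like dominated"

    def test_no_physiological_noise_withholds_classification(self):
        ts = self._simulate(lb.NoiseParams(sigma_thermal=10.0, seed=23), n_volumes=60)
        regime = noise_vs_te(weisskoff_curve(ts, seed=0))
        assert regime.classification is None


class TestRoiArithmetic:
    @pytest.mark.parametrize(
        "volume, area, length",
        [(40.0, 53, 7.3), (60.0, 80, 8.9), (100.0, 133, 11.5)],
    )
    def test_patch_geometry_from_printed_volumes(self, volume, area, length):
        n = voxels_for_volume(volume, 0.75)
        geom = roi_arithmetic(n, 0.75)
        assert round(geom["area_mm2"]) == area
        assert round(geom["length_mm"], 1) == pytest.approx(length, abs=0.05)

    def test_unit_voxel_identity(self):
        geom = roi_arithmetic(1, 1.0)
        assert geom == {"volume_mm3": 1.0, "area_mm2": 1.0, "length_mm": 1.0}

    def test_inverse(self):
        assert voxels_for_volume(roi_arithmetic(237)["volume_mm3"]) == 237
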
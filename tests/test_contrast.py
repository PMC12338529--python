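"""Noise-corrected contrast decomposition, derived series, and gain calibration."""

import numpy as np
import pytest

from scos import contrast, preprocess, simcam
from scos.contrast import (ChannelSeries, contrast_components, delta_od,
                           demultiplex, estimate_gain_ptc, frame_intensity,
                           rdb_minus_one, weighted_kf2)
from scos.preprocess import (DarkStats, MeanImageStats, WindowStats,
                             dark_stats, subtract_dark, window_statistics)
from scos.simcam import (CameraSpec, FrameStack, MultiplexSchedule,
                         SimScenario, SpeckleGroundTruth,
                         simulate_dark_frames, simulate_frames,
                         sp_from_contrast)

from conftest import corrected_kf2_windows, mean_and_se


def _manual_ws(mean, var, dark_tvar, sources=None, ksp2=None):
    """Hand-assembled WindowStats/DarkStats pair for closed-form checks."""
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    var = np.atleast_2d(np.asarray(var, dtype=float))
    n_f, n_w = mean.shape
    src = np.zeros(n_f, dtype=int) if sources is None else np.asarray(sources)
    mis = None
    if ksp2 is not None:
        mi_mean = np.full((1, n_w), 100.0)
        mi_var = np.asarray(ksp2, dtype=float) * mi_mean ** 2
        mis = MeanImageStats(np.array([0]), mi_mean, mi_var, np.array([n_f]))
    ws = WindowStats(mean, var, np.arange(n_f) * 0.01, src,
                     np.ones(n_f, dtype=bool), 7, (1, n_w), 4e-3,
                     CameraSpec(), mis)
    dark = DarkStats(np.zeros((7, 7 * n_w)), np.full(n_w, dark_tvar))
    return ws, dark


class TestContrastComponents:
    def test_hand_evaluated_decomposition(self):
        # <I>=100, sigma^2=150, G=0.5, dark tvar 4, Ksp^2=1e-4
        ws, dark = _manual_ws([[100.0]], [[150.0]], 4.0, ksp2=[[1.0e-4]])
        comp = contrast_components(ws, dark, CameraSpec(gain_G=0.5))
        assert comp.k_raw2[0, 0] == pytest.approx(1.5e-2)
        assert comp.k_s2[0, 0] == pytest.approx(5.0e-3)
        assert comp.k_r2[0, 0] == pytest.approx(3.9167e-4, rel=1e-4)
        assert comp.k_q2[0, 0] == pytest.approx(8.333e-6, rel=1e-3)
        assert comp.k_sp2[0, 0] == pytest.approx(1.0e-4)
        assert comp.k_f2_window[0, 0] == pytest.approx(9.4999e-3, rel=1e-4)

    def test_decomposition_identity_exact(self):
        rng = np.random.default_rng(0)
        ws, dark = _manual_ws(rng.uniform(10, 200, (5, 8)),
                              rng.uniform(1, 400, (5, 8)), 3.0,
                              ksp2=np.full((1, 8), 2e-4))
        comp = contrast_components(ws, dark, CameraSpec())
        np.testing.assert_allclose(
            comp.k_f2_window,
            comp.k_raw2 - comp.k_s2 - comp.k_r2 - comp.k_q2 - comp.k_sp2,
            rtol=0, atol=0)

    def test_nonpositive_intensity_flagged_invalid(self):
        ws, dark = _manual_ws([[50.0, -2.0]], [[10.0, 10.0]], 3.0,
                              ksp2=[[0.0, 0.0]])
        comp = contrast_components(ws, dark, CameraSpec())
        assert comp.valid[0, 0] and not comp.valid[0, 1]
        assert np.isnan(comp.k_f2_window[0, 1])

    def test_static_phantom_recovery(self, camera, dark35,
                                     single_source_schedule):
        """Static scene: corrected contrast returns the coherence parameter
        and the polarization calibration closes to the measured 0.69."""
        scen = SimScenario(
            SpeckleGroundTruth(sp_ratio=0.69, mean_flux=150,
                               heterogeneity_rms=0.0), seed=31)
        stack = simulate_frames(scen, single_source_schedule, camera,
                                (35, 35), 18.0, method="field")
        comp, _ = corrected_kf2_windows(stack, dark35)
        m, se = mean_and_se(comp.k_f2_window)
        beta = simcam.beta_from_sp(0.69)
        assert m == pytest.approx(beta, abs=3 * se)
        assert sp_from_contrast(m) == pytest.approx(0.69, rel=0.02)


class TestWeightedKf2:
    def test_uniform_intensity_is_plain_mean(self):
        ws, dark = _manual_ws([[100.0, 100.0]], [[1.0, 3.0]], 0.0 + 1 / 12)
        comp = contrast_components(ws, dark, CameraSpec(), include_sp=False)
        comp.k_f2_window = np.array([[0.01, 0.03]])
        assert weighted_kf2(comp, ws, weighting="per_frame")[0] == \
            pytest.approx(0.02, abs=1e-15)

    def test_hand_weighted_example(self):
        ws, dark = _manual_ws([[100.0, 200.0]], [[1.0, 3.0]], 0.0 + 1 / 12)
        comp = contrast_components(ws, dark, CameraSpec(), include_sp=False)
        comp.k_f2_window = np.array([[0.01, 0.03]])
        # (100^2*0.01 + 200^2*0.03) / (100^2 + 200^2)
        assert weighted_kf2(comp, ws, weighting="per_frame")[0] == \
            pytest.approx(0.026, abs=1e-15)

    def test_single_window_returns_itself(self):
        ws, dark = _manual_ws([[123.0]], [[4.0]], 0.0 + 1 / 12)
        comp = contrast_components(ws, dark, CameraSpec(), include_sp=False)
        comp.k_f2_window = np.array([[0.0123]])
        assert weighted_kf2(comp, ws, weighting="per_frame")[0] == \
            pytest.approx(0.0123)

    def test_all_windows_invalid_gives_missing(self):
        ws, dark = _manual_ws([[-5.0, -1.0]], [[1.0, 1.0]], 1.0)
        comp = contrast_components(ws, dark, CameraSpec(), include_sp=False)
        assert np.isnan(weighted_kf2(comp, ws, weighting="per_frame")[0])


class TestFluxInvariance:
    def test_corrected_contrast_is_flux_independent(self, camera, dark35,
                                                    single_source_schedule):
        """Quadrupling the photon flux leaves corrected contrast unchanged
        while the uncorrected raw contrast shifts by the shot-noise term
        (the negative control)."""
        res = {}
        for flux in (25.0, 100.0):
            scen = SimScenario(
                SpeckleGroundTruth(beta=0.16, mean_flux=flux,
                                   heterogeneity_rms=0.0), seed=17)
            stack = simulate_frames(scen, single_source_schedule, camera,
                                    (35, 35), 18.0, method="field")
            comp, _ = corrected_kf2_windows(stack, dark35)
            res[flux] = (mean_and_se(comp.k_f2_window),
                         mean_and_se(comp.k_raw2))
        (m1, s1), (r1, rs1) = res[25.0]
        (m2, s2), (r2, rs2) = res[100.0]
        combined = np.hypot(s1, s2)
        assert abs(m1 - m2) < 3 * combined
        assert abs(r1 - r2) > 10 * np.hypot(rs1, rs2)   # raw is flux-dependent


class TestDerivedSeries:
    def _series(self, values, kind="intensity", rate=14.3):
        values = np.atleast_2d(values)
        t = np.arange(values.shape[1]) / rate
        return ChannelSeries(t, values, list(range(values.shape[0])), kind, rate)

    def test_delta_od_identity_and_log(self):
        s = self._series(np.full((1, 50), 80.0))
        assert np.allclose(delta_od(s).values, 0.0)
        v = np.full(50, 100.0)
        v[10] = 100.0 * np.exp(-0.017)
        v[20] = 50.0
        out = delta_od(self._series(v), baseline=(0.0, 0.5))
        assert out.values[0, 10] == pytest.approx(1.7e-2, abs=1e-6)
        assert out.values[0, 20] == pytest.approx(np.log(2), rel=1e-9)

    def test_rdb_constant_is_zero_and_halving_doubles(self):
        v = np.full(40, 0.02)
        out = rdb_minus_one(self._series(v, kind="kf2"))
        assert np.allclose(out.values, 0.0)
        v2 = v.copy()
        v2[30] = 0.01
        out = rdb_minus_one(self._series(v2, kind="kf2"), baseline=(0.0, 1.0))
        assert out.values[0, 30] == pytest.approx(1.0, rel=1e-12)

    def test_rdb_baseline_interval_mean_zero(self):
        rng = np.random.default_rng(2)
        v = 0.02 + 0.002 * rng.standard_normal(100)
        out = rdb_minus_one(self._series(v, kind="kf2"), baseline=(0.0, 2.0))
        sel = out.baseline_slice((0.0, 2.0))
        # reciprocal transform is nonlinear, so exact zero only to O(cv^2)
        assert abs(np.nanmean(out.values[0, sel])) < 0.02 ** 2 * 50

    def test_nonpositive_contrast_propagates_missing(self):
        v = np.array([[0.02, -0.001, 0.02]])
        out = rdb_minus_one(self._series(v, kind="kf2"))
        assert np.isnan(out.values[0, 1])

    def test_kind_checked(self):
        with pytest.raises(ValueError):
            delta_od(self._series(np.ones(5), kind="kf2"))
        with pytest.raises(ValueError):
            rdb_minus_one(self._series(np.ones(5), kind="intensity"))

    def test_tau_halving_gives_unit_flow_change(self, camera, dark35,
                                                single_source_schedule):
        """Halving the decorrelation time in the fast-dynamics regime (x=10)
        doubles the flow index: rDB-1 = 1 within 10%."""
        sch = single_source_schedule
        means = {}
        for x in (10.0, 20.0):
            scen = SimScenario(
                SpeckleGroundTruth(beta=0.16, tau_c=sch.exposure_s / x,
                                   mean_flux=150, heterogeneity_rms=0.0),
                seed=41)
            stack = simulate_frames(scen, sch, camera, (35, 35), 8.0,
                                    method="field")
            comp, _ = corrected_kf2_windows(stack, dark35)
            means[x] = mean_and_se(comp.k_f2_window)[0]
        rdb = means[10.0] / means[20.0] - 1.0
        assert rdb == pytest.approx(1.0, abs=0.10)


class TestDemultiplex:
    def test_sources_split_into_channels(self, camera, schedule):
        gts = {s: SpeckleGroundTruth(beta=0.16, mean_flux=20 * (s + 1),
                                     heterogeneity_rms=0.0)
               for s in range(7)}
        stack = simulate_frames(SimScenario(gts, seed=5), schedule, camera,
                                (14, 14), 2.1)
        dark = dark_stats(simulate_dark_frames(camera, 200, (14, 14), seed=6))
        ws = window_statistics(subtract_dark(stack, dark))
        series = demultiplex(frame_intensity(ws), ws, schedule, "intensity")
        assert series.n_channels == 7
        assert series.rate_hz == pytest.approx(100.0 / 7.0)
        levels = np.nanmean(series.values, axis=1)
        np.testing.assert_allclose(levels, 0.5 * 20 * np.arange(1, 8),
                                   rtol=0.05)


class TestGainCalibration:
    @staticmethod
    def _flux_ladder(camera, fluxes, n_frames=400, shape=(21, 21), seed=0):
        stacks = []
        for i, f in enumerate(fluxes):
            # near-zero contrast: an integrating-sphere flat field
            scen = SimScenario(
                SpeckleGroundTruth(beta=1e-6, mean_flux=f,
                                   heterogeneity_rms=0.0), seed=seed + i)
            stacks.append(simulate_frames(
                scen, MultiplexSchedule(n_sources=1, slot_ms=70,
                                        camera_rate_hz=100 / 7),
                camera, shape, n_frames * 0.07))
        return stacks

    def test_gain_recovered_within_two_percent(self, camera):
        # speckle contrast ~1e-4 emulates the integrating-sphere flat field
        fluxes = np.geomspace(5, 1200, 9)
        stacks = self._flux_ladder(camera, fluxes, seed=50)
        dark = dark_stats(simulate_dark_frames(camera, 600, (21, 21), seed=51))
        cal = estimate_gain_ptc(stacks, dark)
        assert cal.gain_adu_per_e == pytest.approx(camera.gain_G, rel=0.02)
        expected_intercept = (camera.gain_G * camera.read_noise_e) ** 2 + 1 / 12
        assert cal.intercept_adu2 == pytest.approx(expected_intercept, rel=0.25)

    def test_pure_poisson_unit_gain(self):
        # G=1, no read noise: ADU are exact electron counts, so the photon
        # transfer curve is variance = mean with no noise floor (rounding an
        # integer signal adds nothing; the 1/12 quantization floor requires a
        # continuous, read-noise-dithered signal)
        cam = CameraSpec(gain_G=1.0, black_level=10, read_noise_e=0.0)
        stacks = self._flux_ladder(cam, np.geomspace(20, 800, 8), seed=60)
        dark = dark_stats(simulate_dark_frames(cam, 600, (21, 21), seed=61))
        cal = estimate_gain_ptc(stacks, dark)
        assert cal.gain_adu_per_e == pytest.approx(1.0, rel=0.02)
        assert abs(cal.intercept_adu2) < 0.2

    def test_quantization_floor_without_read_noise(self):
        # fractional gain, no read noise: the intercept is set by the
        # quantizer alone; for a discrete input lattice the rounding residual
        # correlates with the signal, so the floor is only of order 1/12
        cam = CameraSpec(gain_G=0.618, black_level=10, read_noise_e=0.0)
        stacks = self._flux_ladder(cam, np.geomspace(30, 900, 8), seed=65)
        dark = dark_stats(simulate_dark_frames(cam, 600, (21, 21), seed=66))
        cal = estimate_gain_ptc(stacks, dark)
        assert cal.gain_adu_per_e == pytest.approx(0.618, rel=0.02)
        assert -0.05 < cal.intercept_adu2 < 2.5 / 12

    def test_saturated_level_excluded(self, camera):
        fluxes = list(np.geomspace(10, 800, 8)) + [5000.0]
        with pytest.warns(RuntimeWarning):
            stacks = self._flux_ladder(camera, fluxes, n_frames=200, seed=70)
        dark = dark_stats(simulate_dark_frames(camera, 400, (21, 21), seed=71))
        cal = estimate_gain_ptc(stacks, dark)
        assert not cal.level_used[-1]
        assert cal.gain_adu_per_e == pytest.approx(camera.gain_G, rel=0.03)

    def test_too_few_levels_rejected(self, camera):
        stacks = self._flux_ladder(camera, [50.0, 100.0], n_frames=50, seed=80)
        dark = dark_stats(simulate_dark_frames(camera, 100, (21, 21), seed=81))
        with pytest.raises(ValueError, match="usable"):
            estimate_gain_ptc(stacks, dark)
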
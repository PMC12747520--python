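"""Generators: determinism, geometry contracts, and noiseless closures."""

import dataclasses

import numpy as np
import pytest

from pamox import flowmetry, oximetry, synthetic
from pamox.types import DEFAULT_EXTINCTION, FlowCalibration, SceneGeometryError


class TestMakeScene:
    def test_seed_determinism(self):
        a = synthetic.make_scene(seed=7)
        b = synthetic.make_scene(seed=7)
        assert len(a.vessels) == len(b.vessels)
        for va, vb in zip(a.vessels, b.vessels):
            assert va.diameter_um == vb.diameter_um
            assert va.peak_speed_mm_s == vb.peak_speed_mm_s
            assert np.array_equal(va.centerline_um, vb.centerline_um)

    def test_classes_and_parameters_preserved(self):
        cfg = synthetic.default_scene_config()
        cfg["jitter"] = {}
        cfg["vessels"] = [
            dict(id="a", x_um=300, diameter_um=80, peak_speed_mm_s=1.0,
                 so2=0.95, vessel_class="artery", region="ipsilateral",
                 chb_g_per_L=120.0),
            dict(id="v", x_um=900, diameter_um=80, peak_speed_mm_s=1.0,
                 so2=0.65, vessel_class="vein", region="ipsilateral",
                 chb_g_per_L=120.0),
        ]
        scene = synthetic.make_scene(cfg, seed=1)
        assert [v.vessel_class for v in scene.vessels] == ["artery", "vein"]
        assert [v.so2 for v in scene.vessels] == [0.95, 0.65]

    @pytest.mark.parametrize("seed", range(20))
    def test_vessels_within_field(self, seed):
        scene = synthetic.make_scene(seed=seed)
        fx, fy = scene.field_size_um
        for v in scene.vessels:
            r = v.radius_um
            assert (v.centerline_um[:, 0] >= r).all()
            assert (v.centerline_um[:, 0] <= fx - r).all()
            assert (v.centerline_um[:, 1] >= r).all()
            assert (v.centerline_um[:, 1] <= fy - r).all()

    def test_vessel_outside_field_rejected(self):
        cfg = synthetic.default_scene_config()
        cfg["jitter"] = {}
        cfg["vessels"] = [dict(
            id="bad", x_um=100, diameter_um=80, peak_speed_mm_s=1.0,
            so2=0.9, vessel_class="artery", region="ipsilateral",
            chb_g_per_L=120.0,
            centerline_um=[[100, -50], [100, 500]])]
        with pytest.raises(SceneGeometryError):
            synthetic.make_scene(cfg, seed=0)

    def test_overlapping_vessels_warn(self):
        cfg = synthetic.compact_scene_config()
        cfg["jitter"] = {}
        cfg["vessels"][1]["x_um"] = cfg["vessels"][0]["x_um"] + 20.0
        with pytest.warns(UserWarning, match="closer than"):
            scene = synthetic.make_scene(cfg, seed=0)
        assert scene.overlap_warning


class TestRenderDualWavelength:
    def test_pure_oxy_channel_ratio(self):
        cfg = synthetic.compact_scene_config()
        cfg["noise_snr_db"] = None
        cfg["psf_fwhm_um"] = 0.0
        cfg["jitter"] = {}
        cfg["vessels"] = [cfg["vessels"][0] | {"so2": 1.0}]
        scene = synthetic.make_scene(cfg, seed=0)
        img = synthetic.render_dual_wavelength(scene)
        m = synthetic.vessel_mask(scene, scene.vessels[0])
        ratio = img.a558[m] / img.a532[m]
        expected = DEFAULT_EXTINCTION.eps_oxy[558] / DEFAULT_EXTINCTION.eps_oxy[532]
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_background_zero_noiseless(self, noiseless_scene):
        img = synthetic.render_dual_wavelength(noiseless_scene)
        occupied = np.zeros(noiseless_scene.grid_shape, bool)
        for v in noiseless_scene.vessels:
            occupied |= synthetic.vessel_mask(noiseless_scene, v)
        # away from the PSF skirt the background is exactly zero
        from scipy.ndimage import binary_dilation
        far = ~binary_dilation(occupied, iterations=10)
        assert img.a532[far].max() == 0.0
        assert img.a558[far].max() == 0.0

    def test_generate_then_unmix_recovers_so2(self):
        cfg = synthetic.compact_scene_config()
        cfg["noise_snr_db"] = None
        cfg["jitter"] = {}
        cfg["vessels"] = [cfg["vessels"][0] | {"so2": 0.5}]
        scene = synthetic.make_scene(cfg, seed=0)
        img = synthetic.render_dual_wavelength(scene)
        m = synthetic.vessel_mask(scene, scene.vessels[0])
        so2, _ = oximetry.unmix(img.a532[m], img.a558[m])
        np.testing.assert_allclose(so2, 0.5, atol=1e-10)

    def test_missing_wavelength_errors(self, noiseless_scene):
        from pamox.types import ExtinctionTable

        bad = ExtinctionTable(wavelengths_nm=(532,), eps_oxy={532: 1.0},
                              eps_deoxy={532: 2.0})
        with pytest.raises(KeyError):
            synthetic.render_dual_wavelength(noiseless_scene, bad)

    def test_render_deterministic_given_seed(self, default_scene):
        a = synthetic.render_dual_wavelength(default_scene)
        b = synthetic.render_dual_wavelength(default_scene)
        np.testing.assert_array_equal(a.a532, b.a532)


class TestAlineEnsemble:
    def test_zero_speed_full_correlation(self):
        e = synthetic.render_aline_ensemble(0.0, seed=1)
        lags, corr = flowmetry.decorrelation_curve(e)
        assert (corr >= 0.99).all()

    def test_tau_c_halves_when_speed_doubles(self):
        cal = FlowCalibration()
        taus = []
        for v in (1.0, 2.0):
            e = synthetic.render_aline_ensemble(v, seed=4)
            lags, corr = flowmetry.decorrelation_curve(e)
            _, fit = flowmetry.fit_speed(lags, corr, cal, full_output=True)
            taus.append(fit.tau_c_s)
        assert taus[1] == pytest.approx(taus[0] / 2, rel=1e-6)

    def test_seed_determinism(self):
        a = synthetic.render_aline_ensemble(1.0, seed=9, noise_snr_db=20.0)
        b = synthetic.render_aline_ensemble(1.0, seed=9, noise_snr_db=20.0)
        np.testing.assert_array_equal(a.lines, b.lines)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            synthetic.render_aline_ensemble(1.0, dt_s=0.0)

    def test_noiseless_correlation_matches_model(self):
        e = synthetic.render_aline_ensemble(1.0, seed=3)
        lags, corr = flowmetry.decorrelation_curve(e)
        np.testing.assert_allclose(corr, np.exp(-((lags / 0.002) ** 2)),
                                   atol=1e-6)


class TestRespiroTrace:
    def test_noiseless_piecewise_line_exact(self):
        p = synthetic.RespiroParams(
            o2_start_nmol_per_ml=200.0,
            segment_slopes={"basal": 0.0, "state2": 0.0, "state3": -10.0,
                            "state4": -2.5, "uncoupled": -2.5},
            event_times_s={"substrate": 10.0, "ADP": 20.0},
            adp_exhaustion_s=400.0, duration_s=600.0)
        tr = synthetic.synth_respiro_trace(p)
        t = tr.time_s
        seg3 = (t >= 20) & (t < 400)
        expected = 200.0 - 10.0 / 60.0 * (t[seg3] - 20.0)
        np.testing.assert_allclose(tr.o2_nmol_per_ml[seg3], expected)
        # slope changes exactly at the exhaustion breakpoint
        seg4 = t >= 400
        o2_400 = 200.0 - 10.0 / 60.0 * 380.0
        np.testing.assert_allclose(
            tr.o2_nmol_per_ml[seg4], o2_400 - 2.5 / 60.0 * (t[seg4] - 400.0))

    def test_state3_steeper_than_state4_by_default(self):
        tr = synthetic.synth_respiro_trace()
        s = tr.meta["segment_slopes"]
        assert abs(s["state3"]) > abs(s["state4"])

    def test_noisy_window_slopes_within_5pct(self):
        p = synthetic.RespiroParams(noise_sd=0.5, seed=3)
        tr = synthetic.synth_respiro_trace(p)
        from scipy.stats import linregress

        for state, (t0, t1) in (("state3", (190.0, 390.0)),
                                ("state4", (410.0, 690.0))):
            sel = (tr.time_s >= t0) & (tr.time_s < t1)
            slope = linregress(tr.time_s[sel], tr.o2_nmol_per_ml[sel]).slope * 60
            assert slope == pytest.approx(p.segment_slopes[state], rel=0.05)

    def test_chamber_anoxia_detected(self):
        p = synthetic.RespiroParams(o2_start_nmol_per_ml=10.0)
        with pytest.raises(ValueError, match="anoxia"):
            synthetic.synth_respiro_trace(p)

    def test_event_times_must_increase(self):
        with pytest.raises(ValueError):
            synthetic.RespiroParams(
                event_times_s={"substrate": 100.0, "ADP": 50.0, "DNP": 700.0})


class TestFluoroTrace:
    def test_rh123_ground_truth_in_metadata(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="rh123", baseline_level_au=100.0, quenched_level_au=60.0))
        assert tr.meta["delta_f_au"] == 40.0

    def test_mitosox_initial_slope_exact(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="mitosox", initial_rate_au_per_s=5.0))
        sel = tr.time_s < 300
        slopes = np.diff(tr.fluorescence_au[sel]) / np.diff(tr.time_s[sel])
        np.testing.assert_allclose(slopes, 5.0)

    def test_amplex_calibration_steps_recoverable(self):
        # step heights proportional to added amounts -> slope 100 a.u./nmol
        additions = np.array([0.1, 0.2, 0.4])
        responses = additions * 100.0
        from scipy.stats import linregress

        res = linregress(additions, responses)
        assert res.slope == pytest.approx(100.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_wrong_event_set_rejected(self):
        with pytest.raises(ValueError, match="does not match kind"):
            synthetic.FluoroParams(kind="amplex",
                                   event_times_s={"substrate": 300.0})

    def test_amplex_rate_changes_at_events(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="amplex", rates_au_per_s=(0.8, 0.3, 0.05)))
        t, f = tr.time_s, tr.fluorescence_au
        for (t0, t1), rate in zip(((0, 400), (400, 600), (600, 800)),
                                  (0.8, 0.3, 0.05)):
            sel = (t >= t0) & (t < t1)
            np.testing.assert_allclose(np.diff(f[sel]), rate, atol=1e-9)
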
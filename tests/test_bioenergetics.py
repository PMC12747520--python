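"""Respirometry and fluorometry trace estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pamox import bioenergetics, synthetic
from pamox.types import FluoroTrace, RespiroTrace


def simple_trace(slopes=None, annotate=False, noise_sd=0.0, seed=0):
    p = synthetic.RespiroParams(noise_sd=noise_sd, seed=seed,
                                annotate_exhaustion=annotate)
    if slopes:
        p.segment_slopes.update(slopes)
    return synthetic.synth_respiro_trace(p)


class TestSegmentStates:
    def test_annotated_exhaustion_passthrough(self):
        tr = simple_trace(annotate=True)
        w = bioenergetics.segment_states(tr)
        assert w["state3"] == (190.0, 400.0)
        assert w["state4"][0] == 410.0

    def test_changepoint_detected_within_10s(self):
        tr = simple_trace()   # true boundary at 400 s
        w = bioenergetics.segment_states(tr)
        assert abs(w["state3"][1] - 400.0) <= 10.0

    def test_no_adp_event_only_basal_windows(self):
        p = synthetic.RespiroParams(event_times_s={"substrate": 60.0},
                                    duration_s=400.0)
        tr = synthetic.synth_respiro_trace(p)
        w = bioenergetics.segment_states(tr)
        assert "state3" not in w and "state4" not in w
        assert "basal" in w and "state2" in w


class TestOcr:
    def test_hand_arithmetic(self):
        # slope -10 nmol/mL/min, 0.5 mL chamber, 0.05 mg protein -> 100
        t = np.arange(0.0, 300.0)
        tr = RespiroTrace(time_s=t, o2_nmol_per_ml=200 - 10 / 60 * t,
                          events=[], protein_mg=0.05, chamber_ml=0.5)
        assert bioenergetics.ocr(tr, (0, 300)) == pytest.approx(100.0)

    def test_flat_trace_zero(self):
        t = np.arange(0.0, 100.0)
        tr = RespiroTrace(time_s=t, o2_nmol_per_ml=np.full_like(t, 150.0),
                          events=[], protein_mg=0.05, chamber_ml=0.5)
        assert bioenergetics.ocr(tr, (0, 100)) == 0.0

    def test_rising_o2_clipped_with_warning(self):
        t = np.arange(0.0, 100.0)
        tr = RespiroTrace(time_s=t, o2_nmol_per_ml=100 + t, events=[],
                          protein_mg=0.05, chamber_ml=0.5)
        with pytest.warns(UserWarning, match="clipped"):
            assert bioenergetics.ocr(tr, (0, 100)) == 0.0

    def test_noiseless_generated_closure(self):
        tr = simple_trace(annotate=True)
        w = bioenergetics.segment_states(tr)
        # generating slope -12 nmol/mL/min -> 12 * 0.5 / 0.05 = 120
        assert bioenergetics.ocr(tr, w["state3"]) == pytest.approx(120.0)
        assert bioenergetics.ocr(tr, w["state4"]) == pytest.approx(30.0)

    @given(shift_s=st.floats(-50, 50), offset=st.floats(-20, 20))
    def test_invariant_to_time_shift_and_o2_offset(self, shift_s, offset):
        t = np.arange(0.0, 200.0)
        base = RespiroTrace(time_s=t, o2_nmol_per_ml=180 - 8 / 60 * t,
                            events=[], protein_mg=0.05, chamber_ml=0.5)
        moved = RespiroTrace(time_s=t + shift_s,
                             o2_nmol_per_ml=base.o2_nmol_per_ml + offset,
                             events=[], protein_mg=0.05, chamber_ml=0.5)
        a = bioenergetics.ocr(base, (0, 200))
        b = bioenergetics.ocr(moved, (shift_s, 200 + shift_s))
        assert b == pytest.approx(a, rel=1e-9)


class TestRcr:
    def test_arithmetic(self):
        assert bioenergetics.rcr(100.0, 25.0) == 4.0
        assert bioenergetics.rcr(30.0, 30.0) == 1.0

    def test_zero_state4_rejected(self):
        with pytest.raises(ValueError):
            bioenergetics.rcr(100.0, 0.0)

    def test_noiseless_slope_ratio_exact(self):
        tr = simple_trace(annotate=True)
        res = bioenergetics.analyze_respiro(tr)
        assert res.rcr == pytest.approx(12.0 / 3.0, rel=1e-12)

    def test_monte_carlo_rcr_within_2pct_at_1pct_noise(self):
        # 1% of the O2 scale (~200 nmol/mL) as additive noise
        rcrs = []
        for seed in range(30):
            tr = simple_trace(annotate=True, noise_sd=2.0, seed=seed)
            rcrs.append(bioenergetics.analyze_respiro(tr).rcr)
        assert np.mean(rcrs) == pytest.approx(4.0, rel=0.02)


class TestH2o2:
    def test_exact_calibration_line(self):
        cal = bioenergetics.h2o2_calibration([0.1, 0.2, 0.4], [10, 20, 40])
        assert cal.slope_au_per_nmol == pytest.approx(100.0)
        assert cal.intercept_au == pytest.approx(0.0, abs=1e-9)
        assert cal.r2 == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            bioenergetics.h2o2_calibration([0.1, 0.2], [10, 20])

    def test_calibration_slope_bias_below_2pct(self, rng):
        additions = np.array([0.1, 0.2, 0.4, 0.8])
        slopes = []
        for _ in range(100):
            responses = additions * 100.0 + 5.0 + rng.normal(0, 1, 4)
            cal = bioenergetics.h2o2_calibration(additions, responses)
            slopes.append(cal.slope_au_per_nmol)
        assert abs(np.mean(slopes) / 100.0 - 1) < 0.02

    def test_rate_hand_arithmetic(self):
        t = np.arange(0.0, 700.0)
        f = 50.0 / 60.0 * t   # 50 a.u./min
        tr = FluoroTrace(kind="amplex", time_s=t, fluorescence_au=f,
                         events=[(400.0, "rotenone"), (600.0, "antimycin")])
        cal = bioenergetics.h2o2_calibration([0.1, 0.2, 0.4], [10, 20, 40])
        assert bioenergetics.h2o2_rate(tr, cal, 0.05) == pytest.approx(10.0)

    def test_flat_fluorescence_zero_rate(self):
        t = np.arange(0.0, 700.0)
        tr = FluoroTrace(kind="amplex", time_s=t,
                         fluorescence_au=np.full_like(t, 30.0),
                         events=[(400.0, "rotenone")])
        cal = bioenergetics.h2o2_calibration([0.1, 0.2, 0.4], [10, 20, 40])
        assert bioenergetics.h2o2_rate(tr, cal, 0.05) == 0.0

    def test_missing_rotenone_rejected(self):
        t = np.arange(0.0, 700.0)
        tr = FluoroTrace(kind="amplex", time_s=t, fluorescence_au=t,
                         events=[])
        cal = bioenergetics.h2o2_calibration([0.1, 0.2, 0.4], [10, 20, 40])
        with pytest.raises(ValueError, match="rotenone"):
            bioenergetics.h2o2_rate(tr, cal, 0.05)

    def test_generated_trace_exact_recovery(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="amplex", rates_au_per_s=(0.8, 0.3, 0.05)))
        cal = bioenergetics.h2o2_calibration([0.1, 0.2, 0.4], [10, 20, 40])
        expected = 0.8 * 60 / 100.0 / 0.05
        assert bioenergetics.h2o2_rate(tr, cal, 0.05) == pytest.approx(expected)

    @given(scale=st.floats(0.5, 4.0))
    def test_rate_scales_with_slope_and_inverse_calibration(self, scale):
        t = np.arange(0.0, 700.0)
        base = FluoroTrace(kind="amplex", time_s=t, fluorescence_au=0.5 * t,
                           events=[(400.0, "rotenone")])
        cal = bioenergetics.h2o2_calibration([0.1, 0.2, 0.4], [10, 20, 40])
        r0 = bioenergetics.h2o2_rate(base, cal, 0.05)
        scaled = FluoroTrace(kind="amplex", time_s=t,
                             fluorescence_au=scale * 0.5 * t,
                             events=[(400.0, "rotenone")])
        assert bioenergetics.h2o2_rate(scaled, cal, 0.05) == pytest.approx(
            scale * r0, rel=1e-9)
        assert bioenergetics.h2o2_rate(base, cal, 0.05 * scale) == pytest.approx(
            r0 / scale, rel=1e-9)


class TestMitosox:
    def test_linear_trace_slope_times_60(self):
        t = np.arange(0.0, 400.0)
        tr = FluoroTrace(kind="mitosox", time_s=t, fluorescence_au=5.0 * t,
                         events=[])
        assert bioenergetics.mitosox_rate(tr) == pytest.approx(300.0)

    def test_constant_trace_zero(self):
        t = np.arange(0.0, 400.0)
        tr = FluoroTrace(kind="mitosox", time_s=t,
                         fluorescence_au=np.full_like(t, 7.0), events=[])
        assert bioenergetics.mitosox_rate(tr) == 0.0

    def test_window_longer_than_trace_rejected(self):
        t = np.arange(0.0, 100.0)
        tr = FluoroTrace(kind="mitosox", time_s=t, fluorescence_au=t, events=[])
        with pytest.raises(ValueError):
            bioenergetics.mitosox_rate(tr, window_s=300.0)

    def test_saturating_trace_recovered_within_3pct(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="mitosox", initial_rate_au_per_s=5.0,
            saturation_time_s=1500.0, noise_sd=2.0, seed=4))
        assert bioenergetics.mitosox_rate(tr) == pytest.approx(300.0, rel=0.03)


class TestRh123:
    def test_quench_depth_construction(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="rh123", baseline_level_au=100.0, quenched_level_au=60.0,
            release_level_au=95.0))
        delta, release = bioenergetics.rh123_delta(tr)
        assert delta == pytest.approx(40.0, abs=0.1)
        assert release == pytest.approx(35.0, abs=0.1)

    def test_no_quench_zero_delta(self):
        t = np.arange(0.0, 900.0)
        tr = FluoroTrace(kind="rh123", time_s=t,
                         fluorescence_au=np.full_like(t, 100.0),
                         events=[(300.0, "substrate")])
        delta, release = bioenergetics.rh123_delta(tr)
        assert delta == 0.0
        assert release is None

    def test_short_baseline_rejected(self):
        t = np.arange(0.0, 500.0)
        tr = FluoroTrace(kind="rh123", time_s=t, fluorescence_au=t,
                         events=[(200.0, "substrate")])
        with pytest.raises(ValueError, match="300 s"):
            bioenergetics.rh123_delta(tr)

    def test_estimators_deterministic(self):
        tr = synthetic.synth_fluoro_trace(synthetic.FluoroParams(
            kind="rh123", noise_sd=1.0, seed=8))
        assert bioenergetics.rh123_delta(tr) == bioenergetics.rh123_delta(tr)
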
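"""AP feature extraction, afterdepolarization detection and STV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myophys import ap, synthetic
from myophys.datatypes import VoltageTrace


def triangle_trace(rate_khz=10.0, repol_ms=300.0):
    """Instantaneous rise -80 -> +40 mV then linear decline over repol_ms."""
    t = np.arange(0, int(500 * rate_khz)) / rate_khz
    v = np.full(t.size, -80.0)
    on = t >= 50.0
    v[on] = 40.0 - 120.0 * np.clip((t[on] - 50.0) / repol_ms, 0.0, 1.0)
    return VoltageTrace(v, rate_khz)


class TestSegmentation:
    def test_thirty_beat_train_gives_thirty_segments(self, clean_ap_train):
        trace, _ = clean_ap_train
        assert len(ap.segment_aps(trace)) == 30

    def test_flat_trace_yields_no_segments(self):
        flat = VoltageTrace(np.full(20000, -80.0), 10.0)
        assert ap.segment_aps(flat) == []

    def test_annotation_free_segmentation_matches_annotated(self, clean_ap_train):
        trace, _ = clean_ap_train
        with_ann = ap.segment_aps(trace)
        without = ap.segment_aps(VoltageTrace(trace.samples, trace.sampling_rate))
        assert len(with_ann) == len(without)
        t_a = [s.take_off_time for s in with_ann]
        t_b = [s.take_off_time for s in without]
        assert np.allclose(t_a, t_b, atol=trace.dt)


class TestAPFeatures:
    def test_triangle_closed_form_apd(self):
        segs = ap.segment_aps(triangle_trace())
        f = ap.ap_features(segs[0])
        dt = 0.1
        assert abs(f.apd50 - 150.0) <= dt + 1e-9
        assert abs(f.apd90 - 270.0) <= dt + 1e-9
        assert f.e_diast == pytest.approx(-80.0, abs=0.01)

    def test_linear_upstroke_dvdt(self):
        # 120 mV in 1.2 ms linear -> 100 V/s
        rate = 10.0
        t = np.arange(0, 3000) / rate
        v = np.full(t.size, -80.0)
        ramp = (t >= 100.0) & (t < 101.2)
        v[ramp] = -80.0 + 100.0 * (t[ramp] - 100.0)
        v[t >= 101.2] = 40.0 - 0.4 * (t[t >= 101.2] - 101.2)
        segs = ap.segment_aps(VoltageTrace(v, rate))
        f = ap.ap_features(segs[0])
        assert f.dvdt_max == pytest.approx(100.0, rel=1e-6)

    @pytest.mark.parametrize("plateau", [0.0, 80.0])
    def test_generator_round_trip_within_one_sample(self, plateau):
        spec = synthetic.APTrainSpec(n_beats=10, apd90_sd=10.0, seed=3,
                                     plateau_ms=plateau)
        trace, truth = synthetic.gen_ap_train(spec)
        feats = [ap.ap_features(s) for s in ap.segment_aps(trace)]
        for f, a90, a50 in zip(feats, truth.apd90, truth.apd50):
            assert abs(f.apd90 - a90) <= trace.dt
            assert abs(f.apd50 - a50) <= trace.dt

    def test_apd90_never_below_apd50(self):
        spec = synthetic.APTrainSpec(n_beats=20, apd90_sd=15.0, noise_sd=0.2, seed=5)
        trace, _ = synthetic.gen_ap_train(spec)
        for seg in ap.segment_aps(trace):
            f = ap.ap_features(seg)
            assert f.apd90 >= f.apd50 > 0

    def test_non_repolarizing_ap_flagged_missing(self):
        rate = 10.0
        v = np.full(5000, -80.0)
        v[1000:] = 40.0  # depolarizes, never comes back
        segs = ap.segment_aps(VoltageTrace(v, rate))
        f = ap.ap_features(segs[0])
        assert math.isnan(f.apd90)


class TestDADs:
    @pytest.mark.parametrize("amp,expected", [(0.9, 0), (1.0, 1), (1.5, 1)])
    def test_one_mv_rule_boundary(self, amp, expected):
        spec = synthetic.APTrainSpec(n_beats=2, dad_probability=1.0,
                                     dad_amplitude=amp, seed=1)
        trace, _ = synthetic.gen_ap_train(spec)
        segs = ap.segment_aps(trace)
        dads = ap.detect_dads(trace, segs)
        assert len(dads) == 2 * expected  # one per diastole

    def test_recall_and_precision_under_noise(self):
        hits = total = false = 0
        for seed in range(8):
            spec = synthetic.APTrainSpec(n_beats=10, dad_probability=0.6,
                                         dad_amplitude=1.5, noise_sd=0.2, seed=seed)
            trace, truth = synthetic.gen_ap_train(spec)
            dads = ap.detect_dads(trace, ap.segment_aps(trace))
            total += truth.dad_times.size
            matched = set()
            for d in dads:
                m = [i for i, t0 in enumerate(truth.dad_times)
                     if abs(d.time - t0) < 20.0 and i not in matched]
                if m:
                    matched.add(m[0])
                    hits += 1
                else:
                    false += 1
        assert total > 20
        assert hits == total  # recall 1
        assert false == 0  # precision 1


class TestEADs:
    def test_monotonic_repolarization_has_no_eads(self, clean_ap_train):
        trace, _ = clean_ap_train
        for seg in ap.segment_aps(trace)[:5]:
            assert ap.detect_eads(seg) == []

    def test_plateau_deflection_detected_once(self):
        spec = synthetic.APTrainSpec(n_beats=3, plateau_ms=80.0, seed=0)
        trace, truth = synthetic.gen_ap_train(spec)
        t = trace.times
        center = truth.take_off_times[1] + 40.0
        trace.samples += 5.0 * np.exp(-0.5 * ((t - center) / 8.0) ** 2)
        counts = [len(ap.detect_eads(s)) for s in ap.segment_aps(trace)]
        assert counts == [0, 1, 0]

    def test_deflection_below_setting_ignored(self):
        spec = synthetic.APTrainSpec(n_beats=3, plateau_ms=80.0, seed=0)
        trace, truth = synthetic.gen_ap_train(spec)
        t = trace.times
        center = truth.take_off_times[1] + 40.0
        trace.samples += 5.0 * np.exp(-0.5 * ((t - center) / 8.0) ** 2)
        counts = [len(ap.detect_eads(s, min_deflection=6.0))
                  for s in ap.segment_aps(trace)]
        assert counts == [0, 0, 0]


class TestSTV:
    def test_constant_sequence_is_zero(self):
        assert ap.stv([250.0] * 30).stv == 0.0

    def test_alternating_sequence_oracle(self):
        # sum |diff| = 29 * 10 = 290 over 30 beats
        seq = [200.0, 210.0] * 15
        res = ap.stv(seq)
        assert res.stv == pytest.approx(290.0 / (30.0 * math.sqrt(2.0)), rel=1e-12)
        assert len(res.poincare_pairs) == 29

    def test_two_variant_denominator(self):
        seq = [200.0, 210.0] * 15
        assert ap.stv(seq, denominator="two").stv == pytest.approx(290.0 / 60.0)

    def test_too_few_beats_error(self):
        with pytest.raises(ValueError):
            ap.stv([250.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(100.0, 400.0), min_size=2, max_size=40),
        st.floats(-50.0, 50.0),
        st.floats(0.1, 5.0),
    )
    def test_translation_invariance_and_linear_scaling(self, seq, offset, scale):
        base = ap.stv(seq).stv
        shifted = ap.stv([x + offset for x in seq]).stv
        scaled = ap.stv([x * scale for x in seq]).stv
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-9)
        assert base >= 0


class TestSTVRegression:
    def test_exact_colinearity(self):
        pts = [(a, 0.05 * a) for a in (200.0, 250.0, 300.0, 350.0)]
        slope, intercept, r = ap.stv_apd_regression(pts)
        assert slope == pytest.approx(0.05)
        assert r == pytest.approx(1.0)

    def test_two_points_interpolate_exactly(self):
        slope, intercept, _ = ap.stv_apd_regression([(200.0, 4.0), (300.0, 9.0)])
        assert slope == pytest.approx(0.05)
        assert intercept == pytest.approx(-6.0)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ap.stv_apd_regression([(250.0, 4.0), (250.0, 5.0), (250.0, 6.0)])

    def test_common_slope_recovered_across_groups(self):
        rng = np.random.default_rng(0)
        slopes = []
        for _ in range(3):
            apd = rng.uniform(200.0, 350.0, 25)
            stv_vals = 0.05 * apd + rng.normal(0.0, 0.5, 25)
            s, _, _ = ap.stv_apd_regression(list(zip(apd, stv_vals)))
            slopes.append(s)
        assert np.allclose(slopes, 0.05, atol=0.01)
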
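"""F/F0 normalization, transient kinetics, caffeine analysis, resting events."""

import math

import numpy as np
import pandas as pd
import pytest

from myophys import synthetic, transients
from myophys.datatypes import FluorescenceTrace
from myophys.synthetic import WaveEvent
from myophys.transients import FitError


class TestNormalization:
    def test_constant_trace_maps_to_unity(self):
        tr = FluorescenceTrace(np.full(2000, 500.0), 2000.0, background=0.0)
        norm, f0 = transients.normalize_f(tr)
        assert f0 == 500.0
        assert np.allclose(norm.samples, 1.0)

    def test_peak_df_over_f0(self):
        tr, _ = synthetic.gen_ca_trace(stim_rate=1.0, transient_amplitude=1.0,
                                       noise_sd=0.0, background=0.0)
        norm, _ = transients.normalize_f(tr)
        assert norm.samples.max() == pytest.approx(2.0, rel=0.02)

    def test_round_trip_amplitude_within_two_percent(self):
        tr, truth = synthetic.gen_ca_trace(stim_rate=1.0, transient_amplitude=0.7)
        norm, _ = transients.normalize_f(tr)
        feats = transients.transient_features(norm)
        assert feats[-1].amplitude == pytest.approx(truth.amplitude, rel=0.02)

    def test_affine_gain_offset_invariance(self):
        tr, _ = synthetic.gen_ca_trace(stim_rate=1.0, transient_amplitude=0.8)
        norm_a, _ = transients.normalize_f(tr)
        gained = FluorescenceTrace(tr.samples * 3.0 + 120.0, tr.sampling_rate,
                                   background=tr.background * 3.0 + 120.0,
                                   stim_times=tr.stim_times)
        norm_b, _ = transients.normalize_f(gained)
        assert np.allclose(norm_a.samples, norm_b.samples, atol=1e-9)

    def test_background_above_diastole_rejected(self):
        tr = FluorescenceTrace(np.full(1000, 100.0), 2000.0, background=150.0)
        with pytest.raises(ValueError, match="background"):
            transients.normalize_f(tr)


class TestTransientKinetics:
    def test_half_time_equals_tau_ln2(self):
        # 0.5 Hz pacing leaves no residual between beats
        tr, _ = synthetic.gen_ca_trace(stim_rate=0.5, decay_tau=200.0,
                                       duration=8000.0)
        norm, _ = transients.normalize_f(tr)
        feats = transients.transient_features(norm)
        dt = norm.dt
        for f in feats:
            assert abs(f.t_half_decay - 200.0 * math.log(2.0)) <= dt + 1e-9

    def test_no_transient_is_skipped_not_crashed(self):
        tr, _ = synthetic.gen_ca_trace(stim_rate=1.0, transient_amplitude=0.0,
                                       duration=5000.0)
        norm, _ = transients.normalize_f(
            FluorescenceTrace(tr.samples, tr.sampling_rate,
                              stim_times=[500.0, 1500.0, 2500.0]))
        feats = transients.transient_features(norm)
        assert feats == []

    def test_rate_dependent_decay_ordering_recovered(self):
        halves = []
        for rate, tau in ((1.0, 250.0), (2.0, 180.0), (4.0, 110.0)):
            tr, _ = synthetic.gen_ca_trace(stim_rate=rate, decay_tau=tau,
                                           duration=6000.0, noise_sd=0.01, seed=2)
            norm, _ = transients.normalize_f(tr)
            feats = transients.transient_features(norm)
            halves.append(transients.steady_state_summary(feats)["t_half_decay"])
        assert halves[0] > halves[1] > halves[2]

    def test_undecayed_transient_flagged_missing(self):
        tr, _ = synthetic.gen_ca_trace(stim_rate=4.0, decay_tau=2000.0,
                                       duration=4000.0)
        norm, _ = transients.normalize_f(tr)
        feats = transients.transient_features(norm)
        assert any(f.t_half_decay is None for f in feats)


@pytest.fixture(scope="module")
def caffeine_trace():
    tr, truth = synthetic.gen_ca_trace(
        stim_rate=1.0, caffeine_time=6000.0, duration=12000.0,
        caffeine_amplitude=0.8, caffeine_tau=800.0)
    norm, _ = transients.normalize_f(tr)
    return norm, truth


class TestCaffeine:
    def test_noiseless_tau_recovered_exactly(self, caffeine_trace):
        norm, truth = caffeine_trace
        res = transients.caffeine_analysis(norm)
        assert res.ncx_tau == pytest.approx(800.0, abs=1.0)

    def test_casr_matches_ground_truth(self, caffeine_trace):
        norm, truth = caffeine_trace
        res = transients.caffeine_analysis(norm)
        assert res.casr == pytest.approx(0.8, rel=0.02)

    def test_tau_within_five_percent_at_five_percent_noise(self):
        tr, _ = synthetic.gen_ca_trace(
            stim_rate=1.0, caffeine_time=6000.0, duration=12000.0,
            caffeine_amplitude=0.8, caffeine_tau=800.0,
            noise_sd=0.05 * 0.8, seed=11)
        norm, _ = transients.normalize_f(tr)
        res = transients.caffeine_analysis(norm)
        assert res.ncx_tau == pytest.approx(800.0, rel=0.05)

    @pytest.mark.parametrize("tau", [100.0, 500.0, 2000.0])
    def test_fit_recovers_tau_across_range(self, tau):
        tr, _ = synthetic.gen_ca_trace(
            stim_rate=0.0, caffeine_time=2000.0, duration=2000.0 + 6 * tau,
            caffeine_amplitude=1.0, caffeine_tau=tau)
        norm, _ = transients.normalize_f(
            FluorescenceTrace(tr.samples, tr.sampling_rate,
                              caffeine_time=2000.0))
        res = transients.caffeine_analysis(norm)
        assert res.ncx_tau == pytest.approx(tau, rel=0.05)

    def test_non_decaying_segment_raises(self):
        x = np.ones(8000)
        x[4000:] = np.linspace(1.0, 2.0, 4000)  # rises forever
        norm = FluorescenceTrace(x, 2000.0, normalized=True)
        with pytest.raises((FitError, ValueError)):
            transients.caffeine_analysis(norm, caffeine_time=2000.0)


class TestRestingEvents:
    def _trace(self, amplitudes_sd, noise_sd=0.05, seed=5):
        events = [WaveEvent(10000.0 + 15000.0 * i, a * noise_sd)
                  for i, a in enumerate(amplitudes_sd)]
        tr, _ = synthetic.gen_ca_trace(stim_rate=0.0, duration=60000.0,
                                       noise_sd=noise_sd, wave_events=events,
                                       seed=seed)
        norm, _ = transients.normalize_f(tr)
        return norm

    def test_three_sd_rule_boundary(self):
        assert transients.detect_resting_events(self._trace([2.9])) == []
        events = transients.detect_resting_events(self._trace([3.5]))
        assert len(events) == 1
        assert events[0].kind == "wave"

    def test_cutoff_robustness_for_large_events(self):
        norm = self._trace([6.0, 6.0, 6.0], seed=6)
        counts = [len(transients.detect_resting_events(norm, sd_cutoff=c))
                  for c in (3.0, 4.0, 5.0)]
        assert counts == [3, 3, 3]

    def test_no_false_positives_on_noise(self):
        fp = 0
        for seed in range(30):
            tr, _ = synthetic.gen_ca_trace(stim_rate=0.0, duration=20000.0,
                                           noise_sd=0.05, seed=seed)
            norm, _ = transients.normalize_f(tr)
            fp += len(transients.detect_resting_events(norm))
        assert fp == 0

    def test_flat_trace_has_no_events(self):
        norm = FluorescenceTrace(np.ones(10000), 2000.0, normalized=True)
        assert transients.detect_resting_events(norm) == []

    def test_large_event_labelled_resting_transient(self):
        norm = self._trace([15.0])  # 0.75 dF/F0 > 0.5 default criterion
        events = transients.detect_resting_events(norm)
        assert [e.kind for e in events] == ["resting_transient"]


class TestCtrlNormalization:
    def test_identical_groups_give_unit_ratios(self):
        df = pd.DataFrame({"cycle_length": [250, 250, 500, 500],
                           "value": [1.0, 1.2, 0.9, 1.1]})
        out = transients.normalize_to_ctrl(df, df.copy())
        assert np.allclose(out["ratio"], 1.0)

    def test_known_deficit_recovered(self):
        rng = np.random.default_rng(3)
        ctrl = pd.DataFrame({"cycle_length": np.repeat([250, 500, 1000], 40),
                             "value": rng.normal(1.0, 0.05, 120)})
        trt = pd.DataFrame({"cycle_length": np.repeat([250, 500, 1000], 40),
                            "value": rng.normal(0.8, 0.05, 120)})
        out = transients.normalize_to_ctrl(trt, ctrl)
        assert np.allclose(out["ratio"], 0.8, atol=0.05)

    def test_missing_ctrl_cycle_length_reported(self):
        trt = pd.DataFrame({"cycle_length": [250, 500], "value": [1.0, 1.0]})
        ctrl = pd.DataFrame({"cycle_length": [250], "value": [1.0]})
        with pytest.raises(ValueError, match="500"):
            transients.normalize_to_ctrl(trt, ctrl)
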
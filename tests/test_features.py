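import numpy as np
import pytest

from neonirs.features import (Epoch, baseline_correct, build_feature_table,
                              epoch, mean_amplitude, peak_latency)
from neonirs.signals import HemoSeries
from neonirs.simulate import (GroundTruth, NoiseSpec, hrf_kernel,
                              make_test_schedule, simulate_session)


def _epoch_from(values, valid=None):
    v = np.atleast_2d(np.asarray(values, dtype=float))
    time = np.arange(-20, 201) / 10.0
    assert v.shape[1] == time.size
    return Epoch(v, -0.3 * v, time, 0, "forward",
                 np.ones(v.shape[0], bool) if valid is None else valid)


class TestEpoching:
    def test_full_session_yields_24_epochs_of_221_samples(self, montage8,
                                                          schedule24,
                                                          quiet_truth):
        clean, _ = simulate_session(montage8, schedule24, quiet_truth,
                                    "passive", "T0", 0)
        eps = epoch(clean, schedule24)
        assert len(eps) == 24
        assert all(e.hbo.shape == (8, 221) for e in eps)
        assert eps[0].time[0] == pytest.approx(-2.0)
        assert eps[0].time[-1] == pytest.approx(20.0)

    def test_event_near_recording_end_dropped_and_logged(self, montage8,
                                                         quiet_truth):
        sched = make_test_schedule(2, 0, 6.0, (12.0, 12.0), seed=0)
        clean, _ = simulate_session(montage8, sched, quiet_truth,
                                    "passive", "T0", 0, duration_s=30.0)
        eps = epoch(clean, sched)
        assert len(eps) == 1
        assert any(p["step"] == "epoch_dropped" for p in clean.provenance)

    def test_masked_span_invalidates_only_affected_channels(self, montage8,
                                                            schedule24,
                                                            quiet_truth):
        clean, _ = simulate_session(montage8, schedule24, quiet_truth,
                                    "passive", "T0", 0)
        onset = schedule24.events[3].onset
        i = int(onset * 10)
        clean.mask[2, i + 5:i + 15] = False
        eps = epoch(clean, schedule24)
        assert not eps[3].valid[2]
        assert eps[3].valid[[0, 1, 3, 4, 5, 6, 7]].all()
        assert eps[2].valid.all() or not eps[2].valid[2]  # neighbours only if overlap

    def test_trial_mask_applied_per_event(self, montage8, schedule24,
                                          quiet_truth):
        clean, _ = simulate_session(montage8, schedule24, quiet_truth,
                                    "passive", "T0", 0)
        onsets = np.array([e.onset for e in schedule24.events])
        valid = np.ones((24, 8), bool)
        valid[5, 1] = False
        clean.trial_mask = {"onsets": onsets, "valid": valid}
        eps = epoch(clean, schedule24)
        assert not eps[5].valid[1]
        assert eps[5].valid[0]
        assert eps[4].valid.all()

    def test_inverted_window_rejected(self, montage8, schedule24,
                                      quiet_truth):
        clean, _ = simulate_session(montage8, schedule24, quiet_truth,
                                    "passive", "T0", 0)
        with pytest.raises(ValueError):
            epoch(clean, schedule24, window=(20.0, -2.0))


class TestBaselineCorrection:
    def test_constant_epoch_becomes_zero(self):
        ep = baseline_correct(_epoch_from(np.full(221, 3.7)))
        assert np.allclose(ep.hbo, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        ep1 = baseline_correct(_epoch_from(rng.standard_normal(221)))
        once = ep1.hbo.copy()
        baseline_correct(ep1)
        assert np.allclose(ep1.hbo, once, atol=1e-12)

    def test_ramp_baseline_mean_exactly_zero(self):
        t = np.arange(-20, 201) / 10.0
        ep = baseline_correct(_epoch_from(0.1 * t))
        sel = (ep.time >= -2.0) & (ep.time < 0.0)
        assert ep.hbo[0, sel].mean() == pytest.approx(0.0, abs=1e-12)


class TestMeanAmplitude:
    def test_unit_epoch_gives_unit_amplitude(self):
        assert mean_amplitude(_epoch_from(np.ones(221)))[0] == pytest.approx(1.0)

    def test_matches_brute_force_average_of_kernel(self):
        t = np.arange(-20, 201) / 10.0
        k = hrf_kernel(t, 8.0, 3.0, 1.0)
        ep = _epoch_from(k)
        brute = np.mean([k[i] for i in range(t.size)
                         if 6.0 - 1e-9 <= t[i] <= 16.0 + 1e-9])
        assert mean_amplitude(ep)[0] == pytest.approx(brute, rel=1e-12)

    def test_antisymmetric_signal_about_11s_averages_to_zero(self):
        t = np.arange(-20, 201) / 10.0
        ep = _epoch_from(t - 11.0)
        assert mean_amplitude(ep)[0] == pytest.approx(0.0, abs=1e-12)

    def test_invalid_channel_returns_nan(self):
        ep = _epoch_from(np.vstack([np.ones(221), np.ones(221)]),
                         valid=np.array([True, False]))
        amp = mean_amplitude(ep)
        assert np.isfinite(amp[0]) and np.isnan(amp[1])

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            mean_amplitude(_epoch_from(np.ones(221)), window=(30.0, 40.0))


class TestPeakLatency:
    def test_planted_peak_time_recovered(self):
        t = np.arange(-20, 201) / 10.0
        ep = _epoch_from(hrf_kernel(t, 8.0, 3.0, 1.0))
        assert peak_latency(ep)[0] == pytest.approx(8.0, abs=1e-9)

    def test_tie_breaks_to_earliest_sample(self):
        t = np.arange(-20, 201) / 10.0
        x = np.zeros(221)
        x[np.argmin(np.abs(t - 7.0))] = 1.0
        x[np.argmin(np.abs(t - 9.0))] = 1.0
        assert peak_latency(_epoch_from(x))[0] == pytest.approx(7.0)

    def test_matches_exhaustive_argmax_on_noisy_epochs(self, rng):
        t = np.arange(-20, 201) / 10.0
        sel = (t >= 0.0 - 1e-9) & (t <= 20.0 + 1e-9)
        for _ in range(50):
            x = rng.standard_normal(221)
            ep = _epoch_from(x)
            brute = t[sel][int(np.argmax(x[sel]))]
            assert peak_latency(ep)[0] == pytest.approx(brute)

    def test_invariant_under_positive_rescaling(self, rng):
        x = rng.standard_normal(221)
        a = peak_latency(_epoch_from(x))[0]
        b = peak_latency(_epoch_from(5.0 * x))[0]
        assert a == b

    def test_search_window_can_include_baseline(self):
        x = np.zeros(221)
        x[5] = 1.0                       # t = -1.5 s
        assert peak_latency(_epoch_from(x), (-2.0, 20.0))[0] == pytest.approx(-1.5)
        assert peak_latency(_epoch_from(x), (0.0, 20.0))[0] == pytest.approx(0.0)


class TestFeatureTable:
    def _epochs(self, montage, schedule, truth, n_trials=None):
        clean, _ = simulate_session(montage, schedule, truth,
                                    "passive", "T0", 0)
        eps = [baseline_correct(e) for e in epoch(clean, schedule)]
        return eps

    def test_row_count_is_trials_times_channels(self, montage8, schedule24,
                                                quiet_truth):
        eps = self._epochs(montage8, schedule24, quiet_truth)
        meta = {"subject_id": "s1", "group": "passive", "phase": "T0"}
        tab = build_feature_table([(meta, eps)], montage8.channel_ids)
        assert len(tab) == 24 * 8
        assert list(tab.columns) == [
            "subject_id", "group", "phase", "channel_id", "trial_index",
            "stimulus_type", "mean_amplitude", "peak_latency", "valid"]

    def test_masked_cells_yield_no_rows(self, montage8, schedule24,
                                        quiet_truth):
        eps = self._epochs(montage8, schedule24, quiet_truth)
        for e in eps[:12]:
            e.valid[:] = False
        meta = {"subject_id": "s1", "group": "passive", "phase": "T0"}
        tab = build_feature_table([(meta, eps)], montage8.channel_ids)
        assert len(tab) == 12 * 8

    def test_all_masked_warns_and_returns_empty(self, montage8, schedule24,
                                                quiet_truth):
        eps = self._epochs(montage8, schedule24, quiet_truth)
        for e in eps:
            e.valid[:] = False
        meta = {"subject_id": "s1", "group": "passive", "phase": "T0"}
        with pytest.warns(UserWarning):
            tab = build_feature_table([(meta, eps)], montage8.channel_ids)
        assert tab.empty

    def test_rows_deterministically_ordered(self, montage8, schedule24,
                                            quiet_truth):
        eps = self._epochs(montage8, schedule24, quiet_truth)
        meta = {"subject_id": "s1", "group": "passive", "phase": "T0"}
        tab = build_feature_table([(meta, eps)], montage8.channel_ids)
        key = tab[["subject_id", "phase", "trial_index", "channel_id"]]
        assert key.equals(key.sort_values(
            ["subject_id", "phase", "trial_index", "channel_id"]))
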
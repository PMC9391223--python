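import numpy as np
import pytest

from neonirs.montage import make_montage
from neonirs.preprocess import (PreprocessConfig, bandpass, correct_spikes,
                                intensity_to_od, od_to_hemo,
                                remove_artifact_epochs, run_preprocessing,
                                screen_saturation)
from neonirs.signals import HemoSeries, OpticalDensitySeries, RawRecording
from neonirs.simulate import (GroundTruth, NoiseSpec, forward_mbll,
                              make_test_schedule, simulate_session,
                              simulate_study, StudyConfig)


def _raw(intensity, **kw):
    return RawRecording(np.asarray(intensity, dtype=float), **kw)


class TestSaturationScreen:
    def test_clipped_channel_flagged(self):
        inten = np.ones((2, 2, 100))
        inten[0, 0, 20:40] = 2.0          # at range max for 20 samples
        flags = screen_saturation(_raw(inten), run_length=10)
        assert flags.tolist() == [True, False]

    def test_single_sample_touch_not_flagged(self):
        inten = np.ones((1, 2, 100))
        inten[0, 0, 50] = 2.0
        assert not screen_saturation(_raw(inten), run_length=10).any()

    def test_default_synthetic_data_never_saturates(self):
        """Simulated studies keep intensities inside the device range, so
        the screen flags no channel (as in the study's recordings)."""
        cfg = StudyConfig(group_sizes={"experimental": 1, "active": 1,
                                       "passive": 1}, n_channels=8)
        study = simulate_study(cfg, seed=8)
        for si in range(3):
            raw, _, _ = study.recording(si, 0)
            assert not screen_saturation(raw).any()


class TestArtifactEpochs:
    def test_large_excursion_masks_cell(self):
        inten = np.ones((1, 2, 400))
        inten[0, :, 100:110] += 0.5       # p2p 0.25 x range width (2.0)
        valid, frac = remove_artifact_epochs(_raw(inten), [8.0], fraction=0.2)
        assert not valid[0, 0]
        assert frac == 1.0

    def test_quiet_data_removes_nothing(self):
        valid, frac = remove_artifact_epochs(_raw(np.ones((3, 2, 400))),
                                             [8.0, 20.0], fraction=0.2)
        assert valid.all() and frac == 0.0

    def test_threshold_monotonicity(self, rng):
        """Lowering the artifact fraction never unmasks a cell."""
        inten = 1.0 + 0.2 * rng.standard_normal((4, 2, 600))
        raw = _raw(inten)
        v_tight, _ = remove_artifact_epochs(raw, [10.0, 30.0], fraction=0.1)
        v_loose, _ = remove_artifact_epochs(raw, [10.0, 30.0], fraction=0.3)
        assert np.all(~v_loose <= ~v_tight)   # loose-invalid => tight-invalid

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            remove_artifact_epochs(_raw(np.ones((1, 2, 100))), [])

    def test_generator_defaults_match_study_removal_rate(self):
        """Default noise removes a study-like fraction of epochs."""
        cfg = StudyConfig(group_sizes={"experimental": 2, "active": 2,
                                       "passive": 2}, n_channels=8)
        study = simulate_study(cfg, seed=17)
        fracs = []
        for si in range(6):
            raw, sched, _ = study.recording(si, 1)
            onsets = [e.onset for e in sched.events]
            _, f = remove_artifact_epochs(raw, onsets)
            fracs.append(f)
        assert 0.10 <= np.mean(fracs) <= 0.30


class TestSpikeCorrection:
    def test_clean_sinusoid_unchanged(self):
        t = np.arange(1000) / 10.0
        x = np.sin(2 * np.pi * 0.1 * t)
        y, log = correct_spikes(x)
        assert np.array_equal(y, x)
        assert log == []

    def test_inserted_jump_interpolated(self):
        t = np.arange(1000) / 10.0
        x = 0.1 * np.sin(2 * np.pi * 0.05 * t)
        spiked = x.copy()
        spiked[500:503] += 30 * 0.1        # far beyond 6 robust s.d.
        y, log = correct_spikes(spiked)
        assert len(log) >= 1
        assert np.abs(y[495:510] - x[495:510]).max() < 0.05

    def test_samples_outside_flagged_spans_untouched(self):
        t = np.arange(2000) / 10.0
        x = 0.1 * np.sin(2 * np.pi * 0.05 * t)
        spiked = x.copy()
        spiked[1000:1003] += 5.0
        y, log = correct_spikes(spiked)
        flagged = np.zeros(2000, dtype=bool)
        for entry in log:
            flagged[entry["start"]:entry["stop"]] = True
        assert np.array_equal(y[~flagged], spiked[~flagged])

    def test_infinite_threshold_is_identity(self, rng):
        x = rng.standard_normal(500)
        y, log = correct_spikes(x, sd_threshold=np.inf)
        assert np.array_equal(y, x) and log == []

    def test_idempotent_on_corrected_data(self):
        t = np.arange(1000) / 10.0
        x = 0.1 * np.sin(2 * np.pi * 0.05 * t)
        x[200:202] += 4.0
        once, _ = correct_spikes(x)
        twice, _ = correct_spikes(once)
        assert np.allclose(once, twice)


class TestIntensityToOd:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(_raw(np.full((2, 2, 50), 1.4)))
        assert np.allclose(od.od, 0.0)

    def test_definition_at_single_sample(self):
        inten = np.ones((1, 2, 100))
        # keep the channel mean at exactly 1 so the reference is unchanged
        inten[0, 0, 10] = 10 ** -0.02
        inten[0, 0, 11] = 2 - 10 ** -0.02
        od = intensity_to_od(_raw(inten))
        assert od.od[0, 0, 10] == pytest.approx(0.02, abs=1e-12)

    def test_recovers_forward_model_od_with_known_reference(self, rng):
        h = HemoSeries(rng.normal(0, 1, (3, 200)), rng.normal(0, 0.3, (3, 200)))
        od_true, inten = forward_mbll(h, i0=1.0)
        od = intensity_to_od(_raw(inten), reference="i0", i0=1.0)
        assert np.abs(od.od - od_true).max() < 1e-12

    def test_mean_reference_leaves_only_constant_offset(self, rng):
        h = HemoSeries(rng.normal(0, 0.5, (2, 500)), rng.normal(0, 0.2, (2, 500)))
        od_true, inten = forward_mbll(h)
        od = intensity_to_od(_raw(inten), reference="mean")
        resid = od.od - od_true
        assert np.ptp(resid, axis=2).max() < 1e-12   # constant per channel

    def test_nonpositive_sample_masked(self):
        inten = np.ones((1, 2, 100))
        inten[0, 0, 5] = -1.0
        od = intensity_to_od(_raw(inten))
        assert not od.mask[0, 5]
        assert od.mask_reasons


class TestBandpass:
    def test_passband_amplitude_preserved(self):
        fs, n = 10.0, 60000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, fs)
        assert np.abs(y[2000:-2000]).max() == pytest.approx(1.0, rel=0.05)

    def test_cardiac_band_suppressed_by_20db(self):
        fs, n = 10.0, 60000
        t = np.arange(n) / fs
        y = bandpass(np.sin(2 * np.pi * 2.5 * t), fs)
        assert np.abs(y[2000:-2000]).max() < 0.1

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(5000), 10.0), 0.0)

    def test_zero_phase_keeps_passband_peaks(self):
        fs, n = 10.0, 20000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x, fs)
        i = slice(5000, 15000)
        cc = np.correlate(y[i], x[i], mode="full")
        lag = int(np.argmax(cc)) - (x[i].size - 1)
        assert abs(lag) <= 1

    def test_linearity(self, rng):
        fs = 10.0
        t = np.arange(8000) / fs
        a = np.sin(2 * np.pi * 0.03 * t)
        b = np.sin(2 * np.pi * 0.11 * t + 1.0)
        assert np.allclose(bandpass(a + b, fs),
                           bandpass(a, fs) + bandpass(b, fs), atol=1e-10)

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), sampling_rate=0.3)


class TestOdToHemo:
    def test_zero_od_gives_zero_concentrations(self):
        h = od_to_hemo(np.zeros((2, 2, 30)))
        assert np.all(h.hbo == 0) and np.all(h.hb == 0)

    def test_round_trip_of_constant_concentrations(self):
        h = HemoSeries(np.full((1, 10), 1.0), np.full((1, 10), -0.3))
        od, _ = forward_mbll(h)
        rec = od_to_hemo(od)
        assert np.allclose(rec.hbo, 1.0, atol=1e-12)
        assert np.allclose(rec.hb, -0.3, atol=1e-12)

    def test_linearity_in_od(self, rng):
        od = rng.normal(0, 0.01, (2, 2, 50))
        a = od_to_hemo(od)
        b = od_to_hemo(2 * od)
        assert np.allclose(b.hbo, 2 * a.hbo) and np.allclose(b.hb, 2 * a.hb)


class TestFullChain:
    def _quiet_recording(self, montage, schedule, amplitude=1.0):
        gt = GroundTruth.null(noise=NoiseSpec.quiet(),
                              base_amplitude=amplitude)
        clean, _ = simulate_session(montage, schedule, gt, "passive", "T0", 0)
        od, inten = forward_mbll(clean)
        raw = RawRecording(inten)
        return raw, clean

    def test_provenance_lists_six_ordered_steps(self, montage8, schedule24):
        raw, _ = self._quiet_recording(montage8, schedule24)
        onsets = [e.onset for e in schedule24.events]
        hemo = run_preprocessing(raw, onsets)
        assert [p["step"] for p in hemo.provenance] == [
            "screen_saturation", "remove_artifact_epochs", "correct_spikes",
            "intensity_to_od", "bandpass", "od_to_hemo"]

    def test_noise_free_recovery_within_filter_tolerance(self, montage8,
                                                         schedule24):
        """On noise-free input the chain returns the clean evoked series up
        to filter transients (< 1% of peak away from the edges)."""
        raw, clean = self._quiet_recording(montage8, schedule24)
        onsets = [e.onset for e in schedule24.events]
        hemo = run_preprocessing(raw, onsets)
        peak = np.abs(clean.hbo).max()
        core = slice(300, -300)           # exclude 30 s at both ends
        # the band-pass removes the evoked response's DC component, so
        # compare filtered truth with the pipeline output
        truth = bandpass(clean.hbo, 10.0)
        err = np.abs(hemo.hbo[:, core] - truth[:, core]).max()
        assert err < 0.01 * peak

    def test_round_trip_identity_with_filter_disabled(self, montage8,
                                                      schedule24):
        raw, clean = self._quiet_recording(montage8, schedule24)
        onsets = [e.onset for e in schedule24.events]
        cfg = PreprocessConfig(od_reference="i0")
        hemo = run_preprocessing(raw, onsets, cfg, apply_filter=False)
        assert np.abs(hemo.hbo - clean.hbo).max() < 1e-9
        assert np.abs(hemo.hb - clean.hb).max() < 1e-9

    def test_all_channels_saturated_aborts(self, schedule24):
        inten = np.full((2, 2, 7000), 2.0)
        with pytest.raises(RuntimeError):
            run_preprocessing(RawRecording(inten),
                              [e.onset for e in schedule24.events])
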
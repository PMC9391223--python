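import numpy as np
import pytest

from neonirs.montage import make_montage
from neonirs.preprocess import od_to_hemo
from neonirs.signals import HemoSeries, MbllParams
from neonirs.simulate import (GroundTruth, NoiseSpec, StudyConfig,
                              forward_mbll, hrf_kernel, make_test_schedule,
                              simulate_resting, simulate_session,
                              simulate_study)


class TestHrfKernel:
    def test_peak_position_and_value(self):
        t = np.arange(0, 30, 0.1)
        k = hrf_kernel(t, peak_time=8.0, dispersion=3.0, amplitude=1.0)
        assert t[np.argmax(k)] == pytest.approx(8.0, abs=0.05)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert np.all(k >= 0)

    def test_zero_amplitude_gives_zero_curve(self):
        t = np.arange(0, 30, 0.1)
        assert np.all(hrf_kernel(t, amplitude=0.0) == 0)

    def test_decays_below_one_percent_by_20s(self):
        t = np.arange(0, 40, 0.1)
        k = hrf_kernel(t)
        assert np.all(k[t >= 20.0] < 0.01)

    def test_peak_shift_detected_by_lag_scan(self):
        """Brute-force cross-correlation lag between peak-7 and peak-9
        kernels is exactly 2 s."""
        t = np.arange(0, 40, 0.1)
        k7 = hrf_kernel(t, peak_time=7.0)
        k9 = hrf_kernel(t, peak_time=9.0)
        lags = np.arange(-50, 51)
        cc = [np.dot(np.roll(k7, l), k9) for l in lags]
        assert lags[np.argmax(cc)] * 0.1 == pytest.approx(2.0, abs=0.2)

    @pytest.mark.parametrize("peak,disp", [(-1, 3), (8, 0), (0, 3)])
    def test_nonpositive_parameters_rejected(self, peak, disp):
        with pytest.raises(ValueError):
            hrf_kernel(np.arange(10.0), peak_time=peak, dispersion=disp)


class TestSimulateSession:
    def test_zero_amplitudes_give_zero_clean_series(self, montage8,
                                                    schedule24):
        gt = GroundTruth.null(noise=NoiseSpec.quiet(), base_amplitude=0.0)
        clean, _ = simulate_session(montage8, schedule24, gt,
                                    "experimental", "T0", 0)
        assert np.all(clean.hbo == 0) and np.all(clean.hb == 0)

    def test_single_event_epoch_mean_matches_kernel_average(self, montage8,
                                                            quiet_truth):
        """Mean over the kernel support equals the brute-force average of
        the sampled kernel."""
        sched = make_test_schedule(1, 0, 6.0, (12.0, 12.0), seed=0,
                                   start_offset=0.0)
        clean, _ = simulate_session(montage8, sched, quiet_truth,
                                    "passive", "T0", 0, duration_s=40.0)
        t = np.arange(400) / 10.0
        expected = hrf_kernel(t, 8.0, 3.0, 1.0).mean()
        assert clean.hbo[0].mean() == pytest.approx(expected, rel=1e-9)

    def test_amplitude_linearity(self, montage8, schedule24):
        """Evoked output scales linearly with the planted amplitude."""
        out = []
        for a in (0.5, 1.0, 2.0):
            gt = GroundTruth.null(noise=NoiseSpec.quiet(), base_amplitude=a)
            clean, _ = simulate_session(montage8, schedule24, gt,
                                        "active", "T1", 0)
            out.append(clean.hbo)
        assert np.allclose(out[1], 2 * out[0], rtol=1e-9)
        assert np.allclose(out[2], 2 * out[1], rtol=1e-9)

    def test_hb_is_scaled_delayed_copy(self, montage8, quiet_truth):
        sched = make_test_schedule(1, 0, 6.0, (12.0, 12.0), seed=0,
                                   start_offset=0.0)
        clean, _ = simulate_session(montage8, sched, quiet_truth,
                                    "passive", "T0", 0, duration_s=40.0)
        assert np.allclose(clean.hb[:, 10:], -0.3 * clean.hbo[:, :-10])

    def test_deterministic_under_seed(self, montage8, schedule24):
        gt = GroundTruth.default(montage8)
        a = simulate_session(montage8, schedule24, gt, "experimental", "T2", 9)
        b = simulate_session(montage8, schedule24, gt, "experimental", "T2", 9)
        assert np.array_equal(a[1].hbo, b[1].hbo)

    def test_schedule_beyond_duration_rejected(self, montage8, schedule24,
                                               quiet_truth):
        with pytest.raises(ValueError):
            simulate_session(montage8, schedule24, quiet_truth,
                             "passive", "T0", 0, duration_s=100.0)


class TestSimulateResting:
    def test_duration_in_samples(self, montage8):
        rest = simulate_resting(montage8, 180.0, seed=0)
        assert rest.n_samples == 1800

    def test_independent_channels_have_small_correlations(self, montage8):
        rest = simulate_resting(montage8, 1800.0, seed=1)
        r = np.corrcoef(rest.hbo)
        off = r[~np.eye(8, dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_planted_pair_correlation_recovered_on_average(self, montage8):
        """Mean sample r over seeds approaches the planted 0.6 (Fisher-CI
        scale tolerance at the band-limited effective sample size)."""
        target = np.eye(8)
        target[5, 6] = target[6, 5] = 0.6
        rs = []
        for s in range(40):
            rest = simulate_resting(montage8, 180.0, conn_target=target,
                                    seed=s)
            rs.append(np.corrcoef(rest.hbo[5], rest.hbo[6])[0, 1])
        assert np.mean(rs) == pytest.approx(0.6, abs=0.06)

    def test_population_targeting_is_exact_at_long_duration(self, montage8):
        target = np.full((8, 8), 0.3)
        np.fill_diagonal(target, 1.0)
        rest = simulate_resting(montage8, 3600.0, conn_target=target, seed=2)
        r = np.corrcoef(rest.hbo)
        off = r[~np.eye(8, dtype=bool)]
        assert off.mean() == pytest.approx(0.3, abs=0.05)

    def test_too_short_duration_rejected(self, montage8):
        with pytest.raises(ValueError):
            simulate_resting(montage8, 5.0, seed=0)


class TestForwardMbll:
    def test_zero_concentrations_give_constant_intensity(self):
        h = HemoSeries(np.zeros((2, 50)), np.zeros((2, 50)))
        od, inten = forward_mbll(h, i0=1.3)
        assert np.all(od == 0)
        assert np.allclose(inten, 1.3)

    def test_round_trip_recovers_concentrations(self, rng):
        h = HemoSeries(rng.normal(0, 1, (4, 300)), rng.normal(0, 0.3, (4, 300)))
        od, _ = forward_mbll(h)
        rec = od_to_hemo(od)
        assert np.abs(rec.hbo - h.hbo).max() < 1e-9
        assert np.abs(rec.hb - h.hb).max() < 1e-9

    def test_od_linear_in_distance(self, rng):
        h = HemoSeries(rng.normal(0, 1, (2, 100)), rng.normal(0, 0.3, (2, 100)))
        od1, _ = forward_mbll(h, distance=2.3)
        od2, _ = forward_mbll(h, distance=4.6)
        assert np.allclose(od2, 2 * od1, rtol=1e-12)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError):
            MbllParams(extinction=((1.0, 2.0), (2.0, 4.0)))


class TestSimulateStudy:
    def test_default_design_has_66_subjects_three_phases(self):
        study = simulate_study(seed=0)
        assert len(study.config.subjects) == 66
        sizes = study.config.group_sizes
        assert (sizes["experimental"], sizes["active"], sizes["passive"]) \
            == (22, 23, 21)
        assert study.config.phases == ("T0", "T1", "T2")

    def test_recordings_reproducible_from_seed(self):
        cfg = StudyConfig(group_sizes={"experimental": 1, "active": 1,
                                       "passive": 1}, n_channels=4)
        a = simulate_study(cfg, seed=5).recording(0, 0)
        b = simulate_study(cfg, seed=5).recording(0, 0)
        assert np.array_equal(a[0].intensity, b[0].intensity)
        assert a[1] == b[1]

    def test_other_subjects_unaffected_by_subsetting(self):
        small = StudyConfig(group_sizes={"experimental": 1, "active": 1,
                                         "passive": 1}, n_channels=4)
        big = StudyConfig(group_sizes={"experimental": 2, "active": 2,
                                       "passive": 2}, n_channels=4)
        a = simulate_study(small, seed=5).recording(0, 1)
        b = simulate_study(big, seed=5).recording(0, 1)
        assert np.array_equal(a[0].intensity, b[0].intensity)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(group_sizes={"experimental": 0, "active": 1,
                                     "passive": 1})

    def test_ground_truth_serialisation_round_trip(self, montage8):
        gt = GroundTruth.default(montage8)
        back = GroundTruth.from_dict(gt.to_dict())
        ids = montage8.channel_ids
        for g in ("experimental", "passive"):
            for p in ("T0", "T2"):
                for s in ("forward", "backward"):
                    assert np.allclose(
                        back.amplitude_vector(g, p, s, ids),
                        gt.amplitude_vector(g, p, s, ids))
        assert np.allclose(back.resting_corr("active", "T2", ids),
                           gt.resting_corr("active", "T2", ids))

    def test_missing_ground_truth_cell_rejected(self, montage8, schedule24):
        gt = GroundTruth.null(noise=NoiseSpec.quiet())
        del gt.amp_effects["experimental|T2|forward"]
        with pytest.raises(KeyError):
            simulate_session(montage8, schedule24, gt, "experimental", "T2", 0)
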
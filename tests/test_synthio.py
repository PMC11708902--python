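"""Synthetic stimulus, pattern, and ensemble generators."""

import numpy as np
import pytest

from neurocode import synthio
from neurocode.containers import Ensemble


class TestOptoPatterns:
    @pytest.mark.parametrize("pid,channel,n_pulses,first,on_ms,off_ms", [
        ("15hz_high", "spot", 9, (0.0, 49.8), 49.8, 16.6),
        ("4hz_high", "spot", 3, (0.0, 149.4), 149.4, 99.6),
        ("4hz_low", "spot", 3, (0.0, 16.6), 16.6, 233.2),
    ])
    def test_single_spot_trains(self, pid, channel, n_pulses, first,
                                on_ms, off_ms):
        p = synthio.make_opto_patterns(pid)
        pulses = p.pulses[channel]
        assert len(pulses) == n_pulses
        assert pulses[0] == pytest.approx(first)
        for (a, b), (a2, _) in zip(pulses, pulses[1:]):
            assert b - a == pytest.approx(on_ms)
            assert a2 - b == pytest.approx(off_ms)

    def test_rate_matched_trains_have_equal_on_time(self):
        # 9 x 49.8 == 3 x 149.4: the 15 Hz and 4 Hz high-rate patterns
        # deliver identical total light, so they differ only temporally
        hi = synthio.make_opto_patterns("15hz_high").total_on_ms()
        lo = synthio.make_opto_patterns("4hz_high").total_on_ms()
        assert hi == pytest.approx(448.2)
        assert lo == pytest.approx(448.2)
        assert synthio.make_opto_patterns("4hz_low").total_on_ms() \
            == pytest.approx(49.8)

    def test_ab_ba_are_time_symmetric(self):
        ab = synthio.make_opto_patterns("AB")
        ba = synthio.make_opto_patterns("BA")
        # identical per-channel pulse multisets, only the channel-to-epoch
        # assignment is swapped
        assert sorted(ab.pulses["A"]) == sorted(ba.pulses["B"])
        assert sorted(ab.pulses["B"]) == sorted(ba.pulses["A"])
        assert ab.pulses["A"][0][0] == 0.0
        assert ba.pulses["B"][0][0] == 0.0
        assert ab.pulses["B"][0][0] == pytest.approx(250.0)

    def test_unknown_protocol_lists_valid_ids(self):
        with pytest.raises(ValueError, match="15hz_high"):
            synthio.make_opto_patterns("8hz_mid")

    def test_waveform_matches_on_time(self):
        p = synthio.make_opto_patterns("15hz_high")
        w = p.waveform(dt_ms=0.1)
        assert w.sum() * 0.1 == pytest.approx(448.2, abs=0.5)


class TestSchedule:
    def test_block_protocol_counts_and_duration(self):
        sched, total = synthio.schedule_protocol(140, 15, 32, 15, 120)
        assert len(sched) == 140 * 15 == 2100
        assert (sched.groupby("sound").size() == 15).all()
        assert total / 60 == pytest.approx(94.0)

    def test_single_block(self):
        sched, total = synthio.schedule_protocol(1, 1, 32, 15, 1)
        assert total == 47.0
        assert len(sched) == 1

    def test_overfull_blocks_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            synthio.schedule_protocol(140, 15, 32, 15, 120, max_per_block=10)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            synthio.schedule_protocol(0, 15, 32, 15, 120)


class TestPatternPair:
    def test_identity_manipulation(self):
        pair = synthio.make_pattern_pair(200, 25, 0, 0, 0, seed=3)
        assert np.array_equal(pair.X_go, pair.X_nogo)
        r = pair.meta["realized"]
        assert r["spatial"] == pytest.approx(1.0)
        assert r["spatiotemporal"] == pytest.approx(1.0)
        assert r["gad"] == 0.0

    def test_shuffling_preserves_means_and_spatial_similarity(self):
        pair = synthio.make_pattern_pair(300, 25, frac_shuffled=1.0, seed=5)
        np.testing.assert_allclose(pair.X_go.mean(axis=1),
                                   pair.X_nogo.mean(axis=1), rtol=1e-12)
        r = pair.meta["realized"]
        assert r["spatial"] == pytest.approx(1.0, abs=1e-9)
        assert r["gad"] == pytest.approx(0.0, abs=1e-12)
        assert r["spatiotemporal"] < 0.8

    def test_spatial_similarity_decreases_with_resampling(self):
        means = []
        for frac in (0.0, 0.3, 0.6, 1.0):
            vals = [synthio.make_pattern_pair(
                300, 25, frac_resampled=frac, seed=s
            ).meta["realized"]["spatial"] for s in range(15)]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))
        assert 0.0 < means[1] < 1.0

    def test_offset_moves_only_gad(self):
        # a global additive offset leaves both Pearson similarities
        # exactly unchanged and sets the global activity difference
        base = synthio.make_pattern_pair(200, 25, 0.5, 0.5, 0.0, seed=9)
        shifted = synthio.make_pattern_pair(200, 25, 0.5, 0.5, 0.3, seed=9)
        rb, rs = base.meta["realized"], shifted.meta["realized"]
        assert rs["spatial"] == pytest.approx(rb["spatial"], abs=1e-9)
        assert rs["spatiotemporal"] == pytest.approx(
            rb["spatiotemporal"], abs=1e-9)
        assert rs["gad"] > rb["gad"]

    def test_resampling_leaves_gad_near_zero(self):
        gads = [synthio.make_pattern_pair(
            400, 25, frac_resampled=1.0, seed=s).meta["realized"]["gad"]
            for s in range(30)]
        assert abs(np.mean(gads)) < 0.05

    def test_negative_offset_is_clipped(self):
        pair = synthio.make_pattern_pair(100, 10, 0, 0, -5.0, seed=1)
        assert (pair.X_nogo == 0).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthio.make_pattern_pair(10, 5, frac_shuffled=1.5)

    def test_seed_determinism(self):
        a = synthio.make_pattern_pair(50, 10, 0.5, 0.5, 0.1, seed=42)
        b = synthio.make_pattern_pair(50, 10, 0.5, 0.5, 0.1, seed=42)
        assert np.array_equal(a.X_nogo, b.X_nogo)


class TestNoisyEnsemble:
    @pytest.mark.parametrize("true_corr", [-0.5, 0.0, 0.25, 0.5, 0.9])
    def test_template_correlation_exact(self, true_corr):
        e = synthio.make_noisy_ensemble(
            n_neurons=400, true_corr=true_corr, noise_sd=1.0,
            n_trials=5, seed=1)
        t = e.truth["templates"].reshape(2, -1)
        realized = np.corrcoef(t[0], t[1])[0, 1]
        assert realized == pytest.approx(true_corr, abs=1e-6)

    def test_zero_noise_trials_equal_templates(self):
        e = synthio.make_noisy_ensemble(
            n_neurons=50, n_bins=4, true_corr=0.5, noise_sd=0.0,
            n_trials=3, seed=2)
        for s in e.stimuli:
            for trial in e.trials_for(s):
                np.testing.assert_array_equal(trial, e.truth["templates"][s])

    def test_multi_stimulus_pairwise_correlations(self):
        e = synthio.make_noisy_ensemble(
            n_neurons=300, true_corr=0.3, noise_sd=0.0, n_trials=2,
            n_stimuli=4, seed=3)
        t = e.truth["templates"].reshape(4, -1)
        c = np.corrcoef(t)
        off = c[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 0.3, atol=1e-6)

    def test_session_labels_partition_trials(self):
        e = synthio.make_noisy_ensemble(
            n_neurons=20, n_trials=12, n_sessions=3, seed=4)
        for s in e.stimuli:
            sess = e.session_labels[e.stimulus_labels == s]
            counts = np.bincount(sess)
            assert counts.sum() == 12 and len(counts) == 3

    def test_extreme_correlation_rejected(self):
        with pytest.raises(ValueError):
            synthio.make_noisy_ensemble(true_corr=1.0, seed=0)

    def test_determinism_and_h5_roundtrip(self, tmp_path):
        a = synthio.make_noisy_ensemble(n_neurons=30, n_trials=4, seed=9)
        b = synthio.make_noisy_ensemble(n_neurons=30, n_trials=4, seed=9)
        assert np.array_equal(a.values, b.values)
        path = tmp_path / "ens.h5"
        a.save(path)
        c = Ensemble.load(path)
        np.testing.assert_array_equal(a.values, c.values)
        np.testing.assert_array_equal(a.stimulus_labels, c.stimulus_labels)
        np.testing.assert_array_equal(a.truth["templates"],
                                      c.truth["templates"])
        assert c.seed == 9


class TestFluorescence:
    def test_zero_rate_zero_noise_constant_baseline(self):
        F, F_np = synthio.make_fluorescence(
            np.zeros(100), dt_s=0.05, noise_sd=0.0)
        assert np.allclose(F, F[0])
        assert np.allclose(F_np, F_np[0])

    def test_impulse_decays_with_tau(self):
        dt = 0.05
        rate = np.zeros(200)
        rate[20] = 1.0
        F, _ = synthio.make_fluorescence(rate, dt, tau_decay_s=2.0,
                                         noise_sd=0.0, neuropil_gain=0.0)
        resp = F[20:] - F[-1]
        # amplitude drops by e^-1 after tau
        k_tau = 20 + int(2.0 / dt)
        assert F[k_tau] - F[0] == pytest.approx(
            (F[20] - F[0]) * np.exp(-1), rel=0.05)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            synthio.make_fluorescence(np.zeros(10), 0.1, tau_decay_s=0.0)
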
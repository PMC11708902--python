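"""Noise-corrected correlation estimator, RSA, and session bootstrap."""

import numpy as np
import pytest

from neurocode import popcode, synthio
from neurocode.containers import Ensemble


class TestCorrectedCorrelation:
    def test_noise_free_identical_stimuli_give_one(self):
        rng = np.random.default_rng(0)
        trial = rng.random((1, 30, 5))
        trials = np.repeat(trial, 4, axis=0)
        assert popcode.corrected_correlation(trials, trials) \
            == pytest.approx(1.0)

    @pytest.mark.parametrize("noise_sd", [0.5, 1.0])
    def test_recovers_known_correlation_under_noise(self, noise_sd):
        ests = []
        for s in range(40):
            e = synthio.make_noisy_ensemble(
                n_neurons=800, true_corr=0.5, noise_sd=noise_sd,
                n_trials=10, seed=100 * s + 1)
            ests.append(popcode.corrected_correlation(
                e.trials_for(0), e.trials_for(1)))
        assert np.mean(ests) == pytest.approx(0.5, abs=0.04)

    def test_orthogonal_templates_give_zero(self):
        ests = []
        for s in range(40):
            e = synthio.make_noisy_ensemble(
                n_neurons=800, true_corr=0.0, noise_sd=1.0,
                n_trials=10, seed=7 * s + 3)
            ests.append(popcode.corrected_correlation(
                e.trials_for(0), e.trials_for(1)))
        assert np.mean(ests) == pytest.approx(0.0, abs=0.04)

    def test_raw_correlation_attenuates_monotonically(self):
        raws = []
        for noise_sd in (0.0, 0.5, 1.0, 2.0):
            vals = []
            for s in range(20):
                e = synthio.make_noisy_ensemble(
                    n_neurons=600, true_corr=0.5, noise_sd=noise_sd,
                    n_trials=10, seed=1000 + 17 * s)
                vals.append(popcode.rsa(
                    e, corrected=False, apply_exclusion=False).values[0, 1])
            raws.append(np.mean(vals))
        assert raws[0] == pytest.approx(0.5, abs=1e-9)
        assert all(a > b for a, b in zip(raws, raws[1:]))

    def test_noise_dominated_pair_flagged_nan(self):
        rng = np.random.default_rng(1)
        noise = rng.standard_normal((6, 50, 4))
        sig = np.repeat(rng.random((1, 50, 4)), 6, axis=0)
        assert np.isnan(popcode.corrected_correlation(noise, sig))

    def test_single_trial_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            popcode.corrected_correlation(rng.random((1, 10, 3)),
                                          rng.random((4, 10, 3)))

    def test_global_affine_invariance(self):
        rng = np.random.default_rng(3)
        tmpl = rng.random((2, 1, 40, 6))
        t1 = np.repeat(tmpl[0], 5, axis=0) + 0.2 * rng.standard_normal((5, 40, 6))
        t2 = np.repeat(tmpl[1], 5, axis=0) + 0.2 * rng.standard_normal((5, 40, 6))
        a = popcode.corrected_correlation(t1, t2)
        b = popcode.corrected_correlation(3.0 * t1 + 2.0, 3.0 * t2 + 2.0)
        assert b == pytest.approx(a, abs=1e-12)


class TestExclusion:
    def test_all_noise_stimulus_excluded(self):
        rng = np.random.default_rng(4)
        sig = np.repeat(rng.random((1, 40, 5)), 6, axis=0)
        noise = rng.standard_normal((6, 40, 5))
        values = np.concatenate([sig, noise])
        ens = Ensemble(values, np.repeat([0, 1], 6), np.zeros(12, int))
        keep = popcode.exclude_stimuli(ens)
        assert keep[0] and not keep[1]

    def test_threshold_is_strictly_below(self):
        rng = np.random.default_rng(5)
        values = np.repeat(rng.random((1, 40, 5)), 4, axis=0) \
            + 0.8 * rng.standard_normal((4, 40, 5))
        ens = Ensemble(values, np.zeros(4, int), np.zeros(4, int))
        sc = popcode.self_consistency(ens.trials_for(0))
        # a stimulus sitting exactly at the threshold is kept
        assert popcode.exclude_stimuli(ens, threshold=sc)[0]
        assert not popcode.exclude_stimuli(ens, threshold=sc + 1e-9)[0]


class TestShuffleTrials:
    def test_marginals_and_average_preserved(self, small_ensemble):
        shuffled = popcode.shuffle_trials(small_ensemble, seed=0)
        for s in small_ensemble.stimuli:
            a = small_ensemble.trials_for(s)
            b = shuffled.trials_for(s)
            for n in range(small_ensemble.n_neurons):
                np.testing.assert_array_equal(
                    np.sort(a[:, n, :], axis=0), np.sort(b[:, n, :], axis=0))
        # averaging the permuted rows changes only the summation order
        np.testing.assert_allclose(small_ensemble.trial_average(),
                                   shuffled.trial_average(), atol=1e-12)

    def test_noise_correlations_destroyed(self):
        rng = np.random.default_rng(6)
        common = rng.standard_normal((40, 1, 8))
        values = 5.0 + np.repeat(common, 30, axis=1) \
            + 0.3 * rng.standard_normal((40, 30, 8))
        ens = Ensemble(values, np.zeros(40, int), np.zeros(40, int))

        def mean_noise_corr(e):
            resid = (e.values - e.trial_average()[0]).reshape(40, 30, 8)
            flat = resid.transpose(1, 0, 2).reshape(30, -1)
            c = np.corrcoef(flat)
            return np.abs(c[np.triu_indices(30, 1)]).mean()

        before = mean_noise_corr(ens)
        after = mean_noise_corr(popcode.shuffle_trials(ens, seed=1))
        assert before > 0.5
        assert after < 0.2


class TestRsa:
    def test_symmetry_and_unit_diagonal(self, small_ensemble):
        m = popcode.rsa(small_ensemble, "spatiotemporal")
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(m.values), 1.0)

    def test_constant_in_time_modes_agree(self):
        # constant-in-time responses make spatial and spatiotemporal
        # featurizations equivalent up to feature replication
        rng = np.random.default_rng(7)
        spatial = rng.random((12, 50, 1))
        values = np.repeat(spatial, 6, axis=2) \
            + 0.0  # K identical bins
        labels = np.repeat(np.arange(4), 3)
        ens = Ensemble(values, labels, np.zeros(12, int))
        m_sp = popcode.rsa(ens, "spatial", apply_exclusion=False)
        m_st = popcode.rsa(ens, "spatiotemporal", apply_exclusion=False)
        np.testing.assert_allclose(m_sp.values, m_st.values, atol=1e-10)

    def test_orthogonal_templates_near_zero_offdiagonal(self):
        e = synthio.make_noisy_ensemble(
            n_neurons=800, true_corr=0.0, noise_sd=0.3, n_trials=8,
            n_stimuli=4, seed=8)
        m = popcode.rsa(e, "spatiotemporal")
        assert abs(m.mean_offdiagonal()) < 0.1


class TestRhoDiff:
    def test_equal_inputs_give_zero(self):
        assert popcode.rho_diff(0.3, 0.3) == 0.0

    def test_printed_formula_value(self):
        assert popcode.rho_diff(0.9, 0.4) == pytest.approx(0.5 / 0.75)

    def test_antisymmetry_of_numerator(self):
        assert popcode.rho_diff(0.4, 0.9) == pytest.approx(-0.5 / 1.25)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            popcode.rho_diff(np.nan, 0.2)


class TestMatrixDissimilarity:
    def _matrix(self, values):
        return popcode.RsaMatrix(values=values,
                                 stimuli=np.arange(len(values)),
                                 mode="spatial")

    def test_identical_matrices_give_zero(self):
        rng = np.random.default_rng(9)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        assert popcode.matrix_dissimilarity(self._matrix(v), self._matrix(v)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_triangles_reach_two(self):
        rng = np.random.default_rng(10)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        w = -v
        assert popcode.matrix_dissimilarity(self._matrix(v), self._matrix(w)) \
            == pytest.approx(2.0)

    def test_degenerate_matrix_flagged(self):
        v = np.ones((4, 4))
        assert np.isnan(popcode.matrix_dissimilarity(
            self._matrix(v), self._matrix(v)))

    def test_correction_removes_noise_induced_dissimilarity(self):
        # two "areas" share a heterogeneous latent RSA structure but have
        # very different noise: the corrected dissimilarity between them
        # is far below the raw one
        rng = np.random.default_rng(21)
        latent = rng.standard_normal((3, 100 * 4))
        mix = rng.standard_normal((6, 3))
        tmpl = (mix @ latent
                + 0.7 * rng.standard_normal((6, 100 * 4))).reshape(6, 100, 4)

        def area(noise_sd, seed):
            r = np.random.default_rng(seed)
            vals = np.repeat(tmpl, 8, axis=0) \
                + noise_sd * r.standard_normal((48, 100, 4))
            return Ensemble(vals, np.repeat(np.arange(6), 8),
                            np.zeros(48, int))

        e1, e2 = area(1.0, 1), area(8.0, 2)
        raw1 = popcode.rsa(e1, "spatiotemporal", corrected=False,
                           apply_exclusion=False)
        raw2 = popcode.rsa(e2, "spatiotemporal", corrected=False,
                           apply_exclusion=False)
        raw_d = popcode.matrix_dissimilarity(raw1, raw2)
        corr_d = popcode.corrected_matrix_dissimilarity(
            e1, "spatiotemporal", "spatiotemporal", ensemble2=e2,
            n_splits=8, seed=3)
        assert raw_d > 0.1
        assert corr_d < raw_d / 2
        assert abs(corr_d) < 0.1


class TestBootstrap:
    def test_constant_statistic_has_zero_sd(self, small_ensemble):
        est, sd, p = popcode.bootstrap_sessions(
            small_ensemble, lambda e: 1.0, n_boot=20, seed=0)
        assert est == 1.0 and sd == 0.0

    def test_p_value_floored_at_one_over_nboot(self, small_ensemble):
        est, sd, p = popcode.bootstrap_sessions(
            small_ensemble, lambda e: e.values.mean() + 100.0,
            n_boot=100, seed=1)
        assert p == pytest.approx(0.01)

    def test_single_session_rejected(self):
        e = synthio.make_noisy_ensemble(n_neurons=10, n_trials=4,
                                        n_sessions=1, seed=2)
        with pytest.raises(ValueError):
            popcode.bootstrap_sessions(e, lambda x: 0.0)

    def test_bootstrap_sd_tracks_analytic_se(self):
        # 20 sessions with distinct means; the bootstrap SD of the grand
        # mean should sit within 30% of the analytic SE
        rng = np.random.default_rng(11)
        session_means = rng.standard_normal(20)
        values = np.repeat(session_means, 5)[:, None, None] \
            * np.ones((100, 4, 2))
        ens = Ensemble(values, np.tile(np.arange(5), 20),
                       np.repeat(np.arange(20), 5))
        est, sd, _ = popcode.bootstrap_sessions(
            ens, lambda e: float(np.mean(
                [e.select_sessions([s]).values.mean() for s in e.sessions])),
            n_boot=200, seed=3)
        se = session_means.std() / np.sqrt(20)
        assert sd == pytest.approx(se, rel=0.3)
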
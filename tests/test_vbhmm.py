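"""VB-HMM estimation: recovery, model selection, pruning, determinism."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from emhmm import (Hmm, HyperParams, fit_vbhmm, prune_states, select_num_rois,
                   sequence_loglik)
from emhmm.synthetic import sample_sequence
from emhmm.vbhmm import DegenerateDataError, _m_step


def two_state_truth(sep=300.0, sd=20.0):
    means = np.array([[250.0, 300.0], [250.0 + sep, 300.0]])
    covs = np.array([sd * sd * np.eye(2)] * 2)
    return Hmm.from_arrays([0.5, 0.5], [[0.8, 0.2], [0.3, 0.7]], means, covs)


def draws(hmm, n, T, seed):
    rng = np.random.default_rng(seed)
    return [sample_sequence(hmm, T, seed=rng, trial_id=str(i))
            for i in range(n)]


def match_states(est_means, true_means):
    cost = np.linalg.norm(est_means[:, None] - true_means[None, :], axis=-1)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    return perm  # est state index for each true state


class TestFitVbhmm:
    def test_single_state_recovers_the_gaussian(self):
        truth = Hmm.from_arrays([1.0], [[1.0]], [[200.0, 150.0]],
                                [400.0 * np.eye(2)])
        seqs = draws(truth, 30, 10, seed=0)
        fit = fit_vbhmm(seqs, K=1, restarts=2, seed=1)
        se = 20.0 / np.sqrt(300)
        assert np.all(np.abs(fit.point_hmm.means[0] - [200, 150]) < 3 * se + 1)
        np.testing.assert_allclose(fit.point_hmm.prior, [1.0])
        np.testing.assert_allclose(fit.point_hmm.transition, [[1.0]])

    def test_two_state_parameter_recovery(self):
        truth = two_state_truth()
        seqs = draws(truth, 50, 10, seed=2)
        fit = fit_vbhmm(seqs, K=2, restarts=3, seed=3)
        perm = match_states(fit.point_hmm.means, truth.means)
        est_means = fit.point_hmm.means[perm]
        est_trans = fit.point_hmm.transition[np.ix_(perm, perm)]
        assert np.all(np.linalg.norm(est_means - truth.means, axis=1) < 10)
        assert np.all(np.abs(est_trans - truth.transition) < 0.1)

    def test_identical_points_regularized_by_prior(self):
        from emhmm.io import FixationSequence
        seqs = [FixationSequence("s", "i", str(t), [[100.0, 100.0]] * 5)
                for t in range(4)]
        fit = fit_vbhmm(seqs, K=1, restarts=1, seed=0)
        assert np.isfinite(fit.elbo)
        assert np.all(np.linalg.eigvalsh(fit.point_hmm.covariances[0]) > 0)

    def test_elbo_never_decreases(self):
        seqs = draws(two_state_truth(), 20, 8, seed=4)
        fit = fit_vbhmm(seqs, K=3, restarts=1, seed=5)
        diffs = np.diff(fit.elbo_history)
        assert np.all(diffs >= -1e-8 * np.maximum(1.0,
                                                  np.abs(fit.elbo_history[:-1])))

    def test_same_seed_is_bit_identical(self):
        seqs = draws(two_state_truth(), 15, 8, seed=6)
        f1 = fit_vbhmm(seqs, K=2, restarts=3, seed=7)
        f2 = fit_vbhmm(seqs, K=2, restarts=3, seed=7)
        assert f1.elbo == f2.elbo
        np.testing.assert_array_equal(f1.m, f2.m)
        np.testing.assert_array_equal(f1.epsilon, f2.epsilon)

    def test_too_few_fixations_raises(self):
        seqs = draws(two_state_truth(), 1, 2, seed=8)
        with pytest.raises(DegenerateDataError):
            fit_vbhmm(seqs, K=5)

    def test_zero_responsibility_state_reduces_to_prior(self):
        hyper = HyperParams(m0=np.array([50.0, 50.0]))
        pts = [np.array([[1.0, 2.0], [3.0, 4.0]])]
        gam = np.array([[1.0, 0.0], [1.0, 0.0]])  # state 2 never used
        alpha, epsilon, m, beta, W, nu, Nk = _m_step(
            pts, [gam], [np.array([[1.0, 0.0], [0.0, 0.0]])],
            np.array([[1.0, 0.0]]), hyper, 2)
        assert Nk[1] == 0.0
        assert beta[1] == hyper.beta0 and nu[1] == hyper.nu0
        np.testing.assert_allclose(m[1], hyper.m0)
        np.testing.assert_allclose(np.linalg.inv(W[1]),
                                   np.linalg.inv(hyper.effective_W0()),
                                   rtol=1e-10)


class TestSelectNumRois:
    def test_recovers_three_rois(self):
        means = np.array([[150.0, 150.0], [450.0, 150.0], [300.0, 410.0]])
        covs = np.array([625.0 * np.eye(2)] * 3)
        truth = Hmm.from_arrays([1 / 3] * 3, np.full((3, 3), 1 / 3), means, covs)
        seqs = draws(truth, 40, 10, seed=9)
        fit = select_num_rois(seqs, range(2, 5), restarts=2, seed=10)
        assert fit.n_states == 3

    def test_single_gaussian_data_prunes_to_one_effective_state(self):
        truth = Hmm.from_arrays([1.0], [[1.0]], [[300.0, 300.0]],
                                [400.0 * np.eye(2)])
        seqs = draws(truth, 40, 10, seed=11)
        fit = select_num_rois(seqs, range(2, 5), restarts=2, seed=12)
        # the ELBO prefers the least complex model in the range
        assert fit.n_states == 2
        assert prune_states(fit, min_weight=1.0).n_states <= 2

    def test_singleton_range_is_identity(self):
        seqs = draws(two_state_truth(), 20, 8, seed=13)
        sel = select_num_rois(seqs, [2], restarts=2, seed=14)
        direct = fit_vbhmm(seqs, 2, restarts=2, seed=14)
        assert sel.elbo == direct.elbo


class TestPruneStates:
    def test_removes_unused_state_and_renormalizes(self):
        seqs = draws(two_state_truth(), 50, 10, seed=15)
        fit = fit_vbhmm(seqs, K=3, restarts=3, seed=16)
        if np.all(fit.state_weights >= 1.0):
            pytest.skip("all three states used on this draw")
        pruned = prune_states(fit, min_weight=1.0)
        assert pruned.n_states < 3
        assert abs(pruned.prior.sum() - 1) < 1e-9
        np.testing.assert_allclose(pruned.transition.sum(axis=1), 1.0)

    def test_noop_when_all_states_used(self):
        seqs = draws(two_state_truth(), 50, 10, seed=17)
        fit = fit_vbhmm(seqs, K=2, restarts=2, seed=18)
        pruned = prune_states(fit, min_weight=1.0)
        assert pruned.n_states == 2
        np.testing.assert_allclose(pruned.means, fit.point_hmm.means)

    def test_pruning_unused_state_barely_changes_likelihood(self):
        truth = two_state_truth()
        seqs = draws(truth, 100, 12, seed=19)
        fit = fit_vbhmm(seqs, K=3, restarts=3, seed=20)
        if np.all(fit.state_weights >= 1.0):
            pytest.skip("all three states used on this draw")
        pruned = prune_states(fit, min_weight=1.0)
        full = np.mean([sequence_loglik(fit.point_hmm, s) for s in seqs])
        red = np.mean([sequence_loglik(pruned, s) for s in seqs])
        # the dead state carries only the Dirichlet pseudo-count mass, so
        # removing it perturbs the per-sequence log-likelihood by well under
        # a tenth of a percent
        assert abs(full - red) < 0.05
        assert abs(full - red) / abs(full) < 1e-3

    def test_all_states_pruned_is_an_error(self):
        seqs = draws(two_state_truth(), 10, 5, seed=21)
        fit = fit_vbhmm(seqs, K=2, restarts=1, seed=22)
        with pytest.raises(ValueError, match="min_weight"):
            prune_states(fit, min_weight=1e9)
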
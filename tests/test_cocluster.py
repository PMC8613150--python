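"""HMM co-clustering: the expected-log-likelihood bound, VHEM, VBHEM."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from emhmm import (GaussianRoi, Hmm, batch_sequence_loglik,
                   expected_loglik_bound, group_separation_report,
                   make_group_hmms, make_hmm_grid, median_states,
                   sample_dataset, sample_sequences, vbhem_cocluster,
                   vhem_cluster_hmms, vhem_cocluster)
from emhmm.cocluster import HmmGrid

from conftest import random_hmm


def _single_state(mean=(0.0, 0.0)):
    return Hmm.from_arrays([1.0], [[1.0]], [list(mean)], [np.eye(2)])


class TestExpectedLoglikBound:
    def test_identity_closed_form(self):
        hmm = _single_state()
        val = expected_loglik_bound(hmm, hmm, n_virtual=1, t_virtual=1)
        assert val == pytest.approx(-math.log(2 * math.pi) - 1.0, abs=1e-10)

    def test_scales_linearly_in_virtual_counts(self):
        hmm = _single_state()
        one = expected_loglik_bound(hmm, hmm, 1, 1)
        assert expected_loglik_bound(hmm, hmm, 7, 1) == pytest.approx(7 * one)
        assert expected_loglik_bound(hmm, hmm, 1, 4) == pytest.approx(4 * one)

    def test_lower_bounds_monte_carlo(self):
        rng = np.random.default_rng(20)
        for _ in range(10):
            base = random_hmm(int(rng.integers(1, 4)), rng)
            reduced = random_hmm(int(rng.integers(1, 4)), rng)
            bound = expected_loglik_bound(base, reduced, 1, 5)
            pts = sample_sequences(base, 3000, 5,
                                   seed=int(rng.integers(2**31)))
            lls = batch_sequence_loglik(reduced, pts)
            assert bound <= lls.mean() + 3 * lls.std(ddof=1) / np.sqrt(len(lls))

    def test_self_bound_beats_shifted_copy(self):
        rng = np.random.default_rng(21)
        base = random_hmm(3, rng)
        shifted = Hmm.from_arrays(base.prior, base.transition,
                                  base.means + [200.0, 0.0], base.covariances)
        self_b = expected_loglik_bound(base, base, 1, 5)
        shift_b = expected_loglik_bound(base, shifted, 1, 5)
        assert self_b > shift_b


class TestMedianStates:
    def _grid(self, counts):
        rng = np.random.default_rng(0)
        hmms = {(f"S{i}", "I1"): random_hmm(k, rng)
                for i, k in enumerate(counts)}
        return HmmGrid(hmms=hmms, subjects=[f"S{i}" for i in range(len(counts))],
                       stimuli=["I1"])

    def test_odd_count_median(self):
        assert median_states(self._grid([2, 3, 4]), "I1") == 3

    def test_half_integer_rounds_up(self):
        assert median_states(self._grid([2, 2, 3, 4]), "I1") == 3

    def test_constant_counts(self):
        assert median_states(self._grid([3, 3, 3]), "I1") == 3


class TestVhemCocluster:
    def test_single_group_absorbs_everyone(self, planted_grid):
        model = vhem_cocluster(planted_grid, n_groups=1, restarts=1, seed=0)
        assert model.n_groups == 1
        np.testing.assert_allclose(model.responsibilities, 1.0)
        assert set(model.group_hmms) == {(0, s) for s in planted_grid.stimuli}

    def test_recovers_planted_partition(self, planted_truth, planted_grid):
        model = vhem_cocluster(planted_grid, n_groups=2, restarts=2, seed=1)
        truth = [planted_truth.assignments[s] for s in planted_grid.subjects]
        pred = [model.assignments[s] for s in planted_grid.subjects]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_objective_monotone_and_deterministic(self, planted_grid):
        m1 = vhem_cocluster(planted_grid, n_groups=2, restarts=2, seed=5)
        m2 = vhem_cocluster(planted_grid, n_groups=2, restarts=2, seed=5)
        hist = m1.objective_history
        assert np.all(np.diff(hist) >= -1e-8 * np.maximum(1.0, np.abs(hist[:-1])))
        assert m1.objective == m2.objective
        np.testing.assert_array_equal(m1.responsibilities, m2.responsibilities)

    def test_responsibilities_shared_across_stimuli(self, planted_grid):
        # one responsibility vector per subject, used for every stimulus
        model = vhem_cocluster(planted_grid, n_groups=2, restarts=1, seed=2)
        assert model.responsibilities.shape == (len(planted_grid.subjects), 2)
        assert len(model.group_hmms) == 2 * len(planted_grid.stimuli)

    def test_single_stimulus_equals_plain_clustering(self):
        truth = make_group_hmms(n_groups=2, n_stimuli=1, k_states=2,
                                separation=250.0, n_subjects_per_group=6,
                                seed=30)
        grid = make_hmm_grid(truth, mean_jitter=8.0, seed=31)
        co = vhem_cocluster(grid, n_groups=2, k_per_stimulus="median",
                            n_virtual=1, t_virtual=13, restarts=2, seed=3)
        plain = vhem_cluster_hmms([grid.hmms[(s, "I1")] for s in grid.subjects],
                                  n_groups=2, restarts=2, seed=3)
        a = [co.assignments[s] for s in grid.subjects]
        b = [plain.assignments[s] for s in plain.subjects]
        assert adjusted_rand_score(a, b) == 1.0

    def test_too_many_groups_is_an_error(self, planted_grid):
        with pytest.raises(ValueError):
            vhem_cocluster(planted_grid, n_groups=100)


class TestVbhemCocluster:
    def test_selects_two_planted_groups(self, planted_truth, planted_grid):
        model = vbhem_cocluster(planted_grid, g_range=range(1, 6),
                                restarts=2, seed=4)
        assert model.n_groups == 2
        truth = [planted_truth.assignments[s] for s in planted_grid.subjects]
        pred = [model.assignments[s] for s in planted_grid.subjects]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_null_data_selects_one_group(self):
        truth = make_group_hmms(n_groups=2, n_stimuli=5, k_states=3,
                                separation=0.0, seed=40)
        grid = make_hmm_grid(truth, mean_jitter=10.0, seed=41)
        model = vbhem_cocluster(grid, g_range=range(1, 6), restarts=2, seed=5)
        assert model.n_groups == 1

    def test_agrees_with_vhem_at_fixed_g(self, planted_truth, planted_grid):
        vb = vbhem_cocluster(planted_grid, g_range=[2], restarts=2, seed=6)
        vh = vhem_cocluster(planted_grid, n_groups=2, restarts=2, seed=6)
        a = [vb.assignments[s] for s in planted_grid.subjects]
        b = [vh.assignments[s] for s in planted_grid.subjects]
        assert adjusted_rand_score(a, b) == 1.0

    def test_out_of_range_g_is_an_error(self, planted_grid):
        with pytest.raises(ValueError):
            vbhem_cocluster(planted_grid, g_range=range(1, 100))


class TestGroupSeparationReport:
    def test_planted_groups_fit_their_own_pattern_better(self, planted_truth,
                                                         planted_grid,
                                                         planted_dataset):
        model = vhem_cocluster(planted_grid, n_groups=2, restarts=2, seed=7)
        table, summary = group_separation_report(model, planted_dataset)
        assert set(table.columns) == {"group_0", "group_1"}
        assert summary["all_positive"].all()
        assert (summary["t"] > 0).all()

    def test_identical_group_hmms_give_zero_differences(self, planted_dataset):
        rng = np.random.default_rng(50)
        stimuli = planted_dataset.stimuli
        shared = {s: random_hmm(2, rng, span=600) for s in stimuli}
        subjects = planted_dataset.subjects
        n = len(subjects)
        resp = np.column_stack([np.ones(n) * 0.5 + 1e-9, np.ones(n) * 0.5 - 1e-9])
        resp /= resp.sum(axis=1, keepdims=True)
        from emhmm.cocluster import CoClusterModel
        model = CoClusterModel(
            n_groups=2, subjects=subjects, stimuli=stimuli,
            assignments={s: 0 for s in subjects}, responsibilities=resp,
            group_hmms={(g, s): shared[s] for g in (0, 1) for s in stimuli},
            group_weights=np.array([0.5, 0.5]), objective=0.0)
        table, summary = group_separation_report(model, planted_dataset)
        np.testing.assert_allclose(table["group_0"], table["group_1"])
        assert np.allclose(summary["mean_diff"], 0.0)

    def test_single_group_degenerate_shape(self, planted_grid, planted_dataset):
        model = vhem_cocluster(planted_grid, n_groups=1, restarts=1, seed=8)
        table, summary = group_separation_report(model, planted_dataset)
        assert list(table.columns) == ["group_0"]
        assert summary.empty
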
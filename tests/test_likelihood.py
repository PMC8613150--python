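"""Forward log-likelihoods, KL estimates, SKL and the cluster score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emhmm import (Hmm, cluster_score, estimate_kl, estimate_kl_sampling,
                   sequence_loglik, skl, subject_group_loglik)
from emhmm.io import FixationDataset, FixationSequence
from emhmm.synthetic import sample_sequences

from conftest import enumerate_loglik, random_hmm


def single_state(mean, cov_scale=1.0):
    return Hmm.from_arrays([1.0], [[1.0]], [list(mean)],
                           [cov_scale * np.eye(2)])


class TestSequenceLoglik:
    def test_standard_normal_at_origin(self):
        hmm = single_state((0.0, 0.0))
        ll = sequence_loglik(hmm, np.array([[0.0, 0.0]]))
        assert ll == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            K = int(rng.integers(1, 4))
            T = int(rng.integers(1, 7))
            hmm = random_hmm(K, rng)
            pts = rng.uniform(0, 500, size=(T, 2))
            assert sequence_loglik(hmm, pts) == pytest.approx(
                enumerate_loglik(hmm, pts), abs=1e-8)

    def test_degenerate_prior_reduces_to_state_density(self):
        rng = np.random.default_rng(1)
        base = random_hmm(2, rng)
        hmm = Hmm.from_arrays([1.0, 0.0], base.transition, base.means,
                              base.covariances)
        pt = np.array([[123.0, 45.0]])
        from scipy.stats import multivariate_normal
        expected = multivariate_normal.logpdf(pt[0], hmm.rois[0].mean,
                                              hmm.rois[0].covariance)
        assert sequence_loglik(hmm, pt) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_state_relabeling(self):
        rng = np.random.default_rng(2)
        hmm = random_hmm(3, rng)
        perm = hmm.permute(np.array([2, 0, 1]))
        pts = rng.uniform(0, 500, size=(5, 2))
        assert sequence_loglik(hmm, pts) == pytest.approx(
            sequence_loglik(perm, pts), abs=1e-10)


def _dataset():
    seqs = [
        FixationSequence("S1", "I1", "1", [[0.0, 0.0], [10.0, 0.0]]),
        FixationSequence("S1", "I2", "1", [[5.0, 5.0]]),
    ]
    return FixationDataset(sequences=seqs)


class TestSubjectGroupLoglik:
    def test_single_sequence_equals_sequence_loglik(self):
        ds = FixationDataset(sequences=[
            FixationSequence("S1", "I1", "1", [[1.0, 2.0], [3.0, 4.0]])])
        hmm = single_state((0.0, 0.0), 100.0)
        direct = sequence_loglik(hmm, ds.sequences[0])
        for mode in ("sum", "mean"):
            assert subject_group_loglik(ds, "S1", {"I1": hmm}, mode) == \
                pytest.approx(direct)

    def test_mean_and_sum_combination(self):
        ds = _dataset()
        hmms = {"I1": single_state((0.0, 0.0), 50.0),
                "I2": single_state((5.0, 5.0), 50.0)}
        lls = [sequence_loglik(hmms[s.stimulus_id], s) for s in ds.sequences]
        assert subject_group_loglik(ds, "S1", hmms, "mean") == \
            pytest.approx(np.mean(lls))
        assert subject_group_loglik(ds, "S1", hmms, "sum") == \
            pytest.approx(np.sum(lls))

    def test_missing_representative_hmm_lists_stimuli(self):
        ds = _dataset()
        with pytest.raises(ValueError, match="I2"):
            subject_group_loglik(ds, "S1", {"I1": single_state((0, 0))})


class TestKlEstimates:
    def test_identical_models_give_exactly_zero(self):
        rng = np.random.default_rng(3)
        hmm = random_hmm(2, rng)
        data = [FixationSequence("s", "i", str(t), rng.uniform(0, 500, (4, 2)))
                for t in range(5)]
        assert estimate_kl(hmm, hmm, data) == 0.0

    def test_matches_gaussian_closed_form(self):
        # single-state models, shared covariance: KL = 0.5 * delta' Sigma^-1 delta
        sigma2 = 400.0
        delta = np.array([60.0, 0.0])
        p = single_state((100.0, 100.0), sigma2)
        q = single_state((100.0 + delta[0], 100.0 + delta[1]), sigma2)
        closed = 0.5 * float(delta @ delta) / sigma2
        n = 4000
        pts = sample_sequences(p, n, 1, seed=7)
        data = [FixationSequence("s", "i", str(t), pts[t]) for t in range(n)]
        est = estimate_kl(p, q, data)
        # SE of the estimator for this pair: sqrt(delta' Sigma^-1 delta / n)
        se = math.sqrt(2 * closed / n)
        assert abs(est - closed) < 3 * se

    def test_estimate_can_be_slightly_negative_but_bounded(self):
        p = single_state((100.0, 100.0), 400.0)
        q = single_state((101.0, 100.0), 400.0)  # nearly identical
        n = 500
        pts = sample_sequences(p, n, 1, seed=8)
        data = [FixationSequence("s", "i", str(t), pts[t]) for t in range(n)]
        est = estimate_kl(p, q, data)
        closed = 0.5 * 1.0 / 400.0
        se = math.sqrt(2 * closed / n) + 1e-6
        assert est > -3 * se

    def test_empty_data_is_an_error(self):
        p = single_state((0, 0))
        with pytest.raises(ValueError):
            estimate_kl(p, p, [])


class TestSkl:
    def test_identical_models_zero(self):
        rng = np.random.default_rng(4)
        hmm = random_hmm(2, rng)
        data = [FixationSequence("s", "i", str(t), rng.uniform(0, 500, (3, 2)))
                for t in range(4)]
        assert skl(hmm, hmm, data, data) == 0.0

    def test_symmetric_under_argument_swap(self):
        rng = np.random.default_rng(5)
        h1, h2 = random_hmm(2, rng), random_hmm(3, rng)
        d1 = [FixationSequence("a", "i", str(t), rng.uniform(0, 500, (3, 2)))
              for t in range(4)]
        d2 = [FixationSequence("b", "i", str(t), rng.uniform(0, 500, (3, 2)))
              for t in range(4)]
        assert skl(h1, h2, d1, d2) == skl(h2, h1, d2, d1)

    def test_grows_with_mean_separation(self):
        vals = []
        for delta in (0.0, 50.0, 100.0):
            h1 = single_state((200.0, 200.0), 400.0)
            h2 = single_state((200.0 + delta, 200.0), 400.0)
            vals.append(estimate_kl_sampling(h1, h2, n_sequences=400,
                                             length=1, seed=11))
        assert vals[0] < vals[1] < vals[2]


class TestClusterScore:
    @pytest.mark.parametrize("l1,l2,expected", [
        (-5.0, -5.0, 0.0),
        (-1.0, -3.0, 0.5),
        (-3.0, -1.0, -0.5),
    ])
    def test_worked_values(self, l1, l2, expected):
        assert cluster_score(l1, l2) == pytest.approx(expected, abs=1e-12)

    def test_both_zero_is_undefined(self):
        with pytest.raises(ValueError):
            cluster_score(0.0, 0.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(l1=st.floats(-1e6, 1e6), l2=st.floats(-1e6, 1e6))
    def test_bounded_in_unit_interval(self, l1, l2):
        if l1 == 0.0 and l2 == 0.0:
            return
        assert -1.0 <= cluster_score(l1, l2) <= 1.0
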
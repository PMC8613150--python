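"""Forward-algorithm log-likelihoods and derived comparison quantities.

The marginal log-likelihood of a fixation sequence under an HMM is the basic
currency of the framework: it feeds the per-subject group log-likelihood
tables, the data-based Kullback–Leibler estimates between group patterns (and
their symmetrised form, SKL), and the bounded cluster score that places an
individual between two group patterns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .io import FixationDataset, FixationSequence
from .model import Hmm

__all__ = ["sequence_loglik", "batch_sequence_loglik", "subject_group_loglik",
           "loglik_table", "estimate_kl", "estimate_kl_sampling", "skl",
           "cluster_score"]


def _log_emissions(hmm: Hmm, points: np.ndarray) -> np.ndarray:
    """(T, K) matrix of per-state Gaussian log densities."""
    cols = [multivariate_normal.logpdf(points, mean=r.mean, cov=r.covariance)
            for r in hmm.rois]
    return np.column_stack([np.atleast_1d(c) for c in cols])


def sequence_loglik(hmm: Hmm, seq: FixationSequence | np.ndarray) -> float:
    """Exact marginal log p(sequence | hmm) in nats, by the forward recursion
    in the log domain (log-sum-exp)."""
    points = seq.points if isinstance(seq, FixationSequence) else \
        np.asarray(seq, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError(f"sequence must be (T, 2), got {points.shape}")
    log_b = _log_emissions(hmm, points)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.prior)
        log_a = np.log(hmm.transition)
    log_alpha = log_pi + log_b[0]
    for t in range(1, points.shape[0]):
        log_alpha = log_b[t] + logsumexp(log_alpha[:, None] + log_a, axis=0)
    return float(logsumexp(log_alpha))


def batch_sequence_loglik(hmm: Hmm, points: np.ndarray) -> np.ndarray:
    """Forward log-likelihoods for a batch of equal-length sequences.

    ``points`` is (N, T, 2); returns (N,) log-likelihoods in nats. Identical
    to mapping :func:`sequence_loglik` over the batch, vectorised across N.
    """
    points = np.asarray(points, float)
    if points.ndim != 3 or points.shape[2] != 2:
        raise ValueError(f"points must be (N, T, 2), got {points.shape}")
    N, T, _ = points.shape
    K = hmm.n_states
    flat = points.reshape(N * T, 2)
    log_b = np.stack(
        [np.atleast_1d(multivariate_normal.logpdf(flat, mean=r.mean,
                                                  cov=r.covariance))
         for r in hmm.rois], axis=1).reshape(N, T, K)
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.prior)
        log_a = np.log(hmm.transition)
    log_alpha = log_pi[None, :] + log_b[:, 0, :]
    for t in range(1, T):
        m = log_alpha.max(axis=1, keepdims=True)
        m = np.where(np.isfinite(m), m, 0.0)
        # log-sum-exp over the previous state, vectorised across the batch
        with np.errstate(divide="ignore"):
            acc = m + np.log(np.exp(log_alpha - m) @ np.exp(log_a))
        log_alpha = log_b[:, t, :] + acc
    m = log_alpha.max(axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return (m + np.log(np.sum(np.exp(log_alpha - m), axis=1,
                              keepdims=True))).ravel()


def subject_group_loglik(dataset: FixationDataset, subject: str,
                         group_hmms: dict[str, Hmm],
                         mode: str = "mean",
                         per_fixation: bool = False) -> float:
    """Combine a subject's per-sequence log-likelihoods under one group's
    per-stimulus representative HMMs.

    ``mode='mean'`` averages over sequences (the default unit throughout);
    ``mode='sum'`` totals them. ``per_fixation`` normalises each sequence's
    log-likelihood by its length first, for unequal-length designs.
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    seqs = dataset.subject_sequences(subject)
    if not seqs:
        raise ValueError(f"no data for subject {subject!r}")
    missing = sorted({s.stimulus_id for s in seqs} - set(group_hmms))
    if missing:
        raise ValueError(f"no representative HMM for stimuli: {missing}")
    lls = []
    for s in seqs:
        ll = sequence_loglik(group_hmms[s.stimulus_id], s)
        lls.append(ll / len(s) if per_fixation else ll)
    return float(np.sum(lls) if mode == "sum" else np.mean(lls))


def loglik_table(dataset: FixationDataset,
                 group_hmms_by_group: dict[int, dict[str, Hmm]],
                 mode: str = "mean") -> pd.DataFrame:
    """Subjects × groups table of combined log-likelihoods (nats)."""
    groups = sorted(group_hmms_by_group)
    rows = {
        subj: [subject_group_loglik(dataset, subj, group_hmms_by_group[g], mode)
               for g in groups]
        for subj in dataset.subjects
    }
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"group_{g}" for g in groups])


def estimate_kl(hmm_p: Hmm, hmm_q: Hmm,
                data_p: list[FixationSequence]) -> float:
    """Data-based KL(p || q) estimate in nats per sequence: the mean difference
    between log-likelihood under the pattern's own model and under the other
    model, over sequences attributed to (or sampled from) ``hmm_p``."""
    if not data_p:
        raise ValueError("data_p must be non-empty")
    diffs = [sequence_loglik(hmm_p, s) - sequence_loglik(hmm_q, s)
             for s in data_p]
    return float(np.mean(diffs))


def estimate_kl_sampling(hmm_p: Hmm, hmm_q: Hmm, n_sequences: int = 500,
                         length: int = 13, seed: int = 0) -> float:
    """Model-only KL estimate: sample sequences from ``hmm_p`` and apply the
    same log-likelihood-difference estimator."""
    from .synthetic import sample_sequence
    rng = np.random.default_rng(seed)
    data = [sample_sequence(hmm_p, length,
                            seed=int(rng.integers(0, 2**31 - 1)))
            for _ in range(n_sequences)]
    return estimate_kl(hmm_p, hmm_q, data)


def skl(hmm_1: Hmm, hmm_2: Hmm, data_1: list[FixationSequence],
        data_2: list[FixationSequence]) -> float:
    """Symmetric KL divergence between two patterns: (KL12 + KL21) / 2, each
    direction estimated from that group's own data."""
    return 0.5 * (estimate_kl(hmm_1, hmm_2, data_1)
                  + estimate_kl(hmm_2, hmm_1, data_2))


def cluster_score(l1: float, l2: float) -> float:
    """Bounded similarity of an individual to group 1 vs group 2:
    (L1 − L2) / (|L1| + |L2|), in [−1, 1]; positive means closer to group 1."""
    denom = abs(l1) + abs(l2)
    if denom == 0.0:
        raise ValueError("cluster score undefined for l1 = l2 = 0")
    return (l1 - l2) / denom
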
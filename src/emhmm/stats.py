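"""Individual-difference metrics on top of the co-clustering result.

Per-subject cluster scores between a pair of group patterns (the basis of an
explorative–focused scale when the two patterns differ in how much gaze
switches between ROIs), descriptive eye-movement statistics (fixations per
trial, saccade length), and split-half reliability of the likelihood-based
measures with Spearman–Brown correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .cocluster import CoClusterModel
from .io import FixationDataset, split_dataset
from .likelihood import cluster_score, subject_group_loglik

__all__ = ["compute_subject_scores", "spearman_brown",
           "split_half_reliability", "descriptives"]


def descriptives(dataset: FixationDataset) -> pd.DataFrame:
    """Per-subject mean fixations per trial and mean saccade length (pixels).

    Saccade lengths are Euclidean distances between consecutive fixations
    within a trial; they never span trial boundaries.
    """
    rows = {}
    for subj in dataset.subjects:
        seqs = dataset.subject_sequences(subj)
        if not seqs:
            continue
        n_fix = [len(s) for s in seqs]
        sacc = []
        for s in seqs:
            if len(s) > 1:
                sacc.extend(np.linalg.norm(np.diff(s.points, axis=0), axis=1))
        rows[subj] = dict(mean_fixations_per_trial=float(np.mean(n_fix)),
                          mean_saccade_length=float(np.mean(sacc)) if sacc
                          else np.nan,
                          n_trials=len(seqs))
    return pd.DataFrame.from_dict(rows, orient="index")


def compute_subject_scores(dataset: FixationDataset, model: CoClusterModel,
                           group_pair: tuple[int, int] = (0, 1),
                           mode: str = "mean") -> pd.DataFrame:
    """Per-subject similarity to two group patterns plus descriptives.

    Columns: ``loglik_a``, ``loglik_b`` (combined log-likelihoods under each
    group's representative HMMs), ``cluster_score`` (positive = closer to the
    first group of ``group_pair``), ``mean_fixations_per_trial``,
    ``mean_saccade_length``. Subjects without data are omitted with a warning.
    """
    g_a, g_b = group_pair
    for g in group_pair:
        if not any(k[0] == g for k in model.group_hmms):
            raise ValueError(f"model has no group {g}")
    hmms_a, hmms_b = model.group_hmm_map(g_a), model.group_hmm_map(g_b)
    desc = descriptives(dataset)
    rows = {}
    for subj in dataset.subjects:
        if not dataset.subject_sequences(subj):
            warnings.warn(f"subject {subj} has no data; omitted", stacklevel=2)
            continue
        la = subject_group_loglik(dataset, subj, hmms_a, mode=mode)
        lb = subject_group_loglik(dataset, subj, hmms_b, mode=mode)
        rows[subj] = dict(loglik_a=la, loglik_b=lb,
                          cluster_score=cluster_score(la, lb))
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.join(desc)


def spearman_brown(r: float) -> float:
    """Reliability of the full-length measure predicted from the split-half
    correlation r: 2r / (1 + r)."""
    if r <= -1.0:
        raise ValueError("Spearman–Brown correction undefined for r <= -1")
    if r > 1.0:
        raise ValueError("correlation cannot exceed 1")
    return 2.0 * r / (1.0 + r)


def split_half_reliability(dataset: FixationDataset, model: CoClusterModel,
                           metric: str = "cluster_score",
                           group_pair: tuple[int, int] = (0, 1),
                           scheme: str = "auto", seed: int = 0,
                           mode: str = "mean") -> dict:
    """Split-half reliability (Spearman–Brown corrected) of a likelihood-based
    individual metric.

    The stimulus set is split into two halves; the per-subject metric is
    computed on each half separately (same representative HMMs, restricted to
    that half's stimuli); the Pearson correlation across subjects is corrected
    by the Spearman–Brown formula. ``metric`` is ``cluster_score`` or
    ``loglik_per_group``. With ``scheme='auto'`` the split is random and
    stratified by stimulus label when labels exist, alternating otherwise.

    Returns a dict with ``r``, ``r_sb`` and the per-half subject tables; for
    ``loglik_per_group`` the values are dicts keyed by group.
    """
    if len(dataset.subjects) < 3:
        raise ValueError("reliability undefined with fewer than 3 subjects")
    if scheme == "auto":
        has_labels = bool(dataset.stimulus_label) and \
            all(s in dataset.stimulus_label for s in dataset.stimuli)
        scheme = "random" if has_labels else "alternating"
    half_a, half_b = split_dataset(dataset, scheme=scheme, seed=seed)

    def metric_frame(half: FixationDataset) -> pd.DataFrame:
        scores = compute_subject_scores(half, model, group_pair, mode=mode)
        return scores

    fa, fb = metric_frame(half_a), metric_frame(half_b)
    common = fa.index.intersection(fb.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 subjects present in both halves")
    fa, fb = fa.loc[common], fb.loc[common]
    if metric == "cluster_score":
        r = float(pearsonr(fa["cluster_score"], fb["cluster_score"])[0])
        return dict(metric=metric, r=r, r_sb=spearman_brown(r),
                    half_a=fa, half_b=fb)
    if metric == "loglik_per_group":
        out_r, out_rsb = {}, {}
        for col, g in (("loglik_a", group_pair[0]), ("loglik_b", group_pair[1])):
            r = float(pearsonr(fa[col], fb[col])[0])
            out_r[g] = r
            out_rsb[g] = spearman_brown(r)
        return dict(metric=metric, r=out_r, r_sb=out_rsb, half_a=fa, half_b=fb)
    raise ValueError(f"unknown metric {metric!r}")
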
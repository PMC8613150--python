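"""Ground-truth generators for fixation data with planted group structure.

No public eye-tracking dataset ships with the package, so every other module
is exercised on synthetic data whose generating process mirrors the modelling
assumptions: each participant group has, per stimulus, an HMM with Gaussian
ROIs; subjects inherit their group's HMMs; trials are sampled by drawing a
hidden ROI path from the prior/transition chain and a fixation from each
visited ROI's Gaussian. Group ROIs are planted a controlled pixel distance
apart and transition styles range from explorative (frequent switching among
ROIs) to focused (high self-transition probability), mirroring the kinds of
patterns such analyses discover in scene viewing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FixationDataset, FixationSequence
from .model import GaussianRoi, Hmm

__all__ = ["GroundTruth", "make_group_hmms", "sample_sequence",
           "sample_sequences", "sample_dataset", "make_hmm_grid"]


@dataclass
class GroundTruth:
    """Planted generating process: per-(group, stimulus) HMMs plus the
    subject → group assignment and the generation parameters."""

    group_hmms: dict[tuple[int, str], Hmm]
    assignments: dict[str, int]
    stimulus_size: tuple[float, float]
    n_groups: int
    stimuli: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subj, g in self.assignments.items():
            for stim in self.stimuli:
                if (g, stim) not in self.group_hmms:
                    raise ValueError(f"missing HMM for group {g}, stimulus {stim}")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.assignments)


def _group_offsets(n_groups: int, separation: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Offsets of each group's ROI centres from the shared base positions.

    Groups sit on a circle whose chord between neighbouring groups equals
    ``separation`` (for 2 groups: diametrically opposite, distance exactly
    ``separation``; for 3: an equilateral triangle)."""
    if separation == 0 or n_groups == 1:
        return np.zeros((n_groups, 2))
    radius = separation / (2.0 * np.sin(np.pi / n_groups))
    phase = rng.uniform(0, 2 * np.pi)
    angles = phase + 2 * np.pi * np.arange(n_groups) / n_groups
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def make_group_hmms(n_groups: int = 2, n_stimuli: int = 5, k_states: int = 3,
                    separation: float = 200.0,
                    stimulus_size: tuple[float, float] = (800.0, 600.0),
                    roi_sd: float = 25.0,
                    n_subjects_per_group: int = 10,
                    seed: int = 0) -> GroundTruth:
    """Build a planted-group ground truth.

    Per (group, stimulus): ``k_states`` Gaussian ROIs whose means are shared
    base positions plus a group-specific offset, so corresponding ROIs of
    neighbouring groups are exactly ``separation`` pixels apart. Transition
    matrices are Dirichlet draws blended with a group-specific self-transition
    weight, from explorative (group 0, weight 0.1) to focused (last group,
    weight 0.7). With ``separation=0`` all groups share one HMM per stimulus
    (the null model).
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if k_states < 1 or n_groups < 1:
        raise ValueError("k_states and n_groups must be >= 1")
    w, h = stimulus_size
    rng = np.random.default_rng(seed)
    offsets = _group_offsets(n_groups, separation, rng)
    margin = float(np.max(np.linalg.norm(offsets, axis=1))) + 3 * roi_sd
    if 2 * margin >= min(w, h):
        raise ValueError(
            f"ROIs cannot fit: separation {separation} too large for "
            f"stimulus {stimulus_size}")

    if n_groups == 1:
        sticky = np.array([0.4])
    else:
        sticky = np.linspace(0.1, 0.7, n_groups)

    group_hmms: dict[tuple[int, str], Hmm] = {}
    stimuli = [f"I{j + 1}" for j in range(n_stimuli)]
    for stim in stimuli:
        # base ROI positions, rejected until pairwise separated enough to
        # keep the planted structure identifiable
        for _ in range(200):
            base = np.column_stack([rng.uniform(margin, w - margin, k_states),
                                    rng.uniform(margin, h - margin, k_states)])
            if k_states == 1:
                break
            d = np.linalg.norm(base[:, None] - base[None, :], axis=-1)
            if np.min(d[np.triu_indices(k_states, 1)]) >= 6 * roi_sd:
                break
        null_prior = rng.dirichlet(np.full(k_states, 5.0))
        null_rows = rng.dirichlet(np.full(k_states, 2.0), size=k_states)
        for g in range(n_groups):
            prior = rng.dirichlet(np.full(k_states, 5.0))
            rows = rng.dirichlet(np.full(k_states, 2.0), size=k_states)
            if separation == 0:
                # null model: identical groups, shared transitions
                prior, rows, s = null_prior, null_rows, 0.4
            else:
                s = sticky[g]
            trans = (1 - s) * rows + s * np.eye(k_states)
            trans /= trans.sum(axis=1, keepdims=True)
            rois = tuple(GaussianRoi(base[k] + offsets[g],
                                     (roi_sd ** 2) * np.eye(2))
                         for k in range(k_states))
            group_hmms[(g, stim)] = Hmm(prior=prior, transition=trans, rois=rois)

    assignments = {f"S{g * n_subjects_per_group + i + 1:03d}": g
                   for g in range(n_groups) for i in range(n_subjects_per_group)}
    return GroundTruth(group_hmms=group_hmms, assignments=assignments,
                       stimulus_size=stimulus_size, n_groups=n_groups,
                       stimuli=stimuli,
                       params=dict(k_states=k_states, separation=separation,
                                   roi_sd=roi_sd, seed=seed,
                                   n_subjects_per_group=n_subjects_per_group))


def sample_sequence(hmm: Hmm, length: int, seed: int | np.random.Generator = 0,
                    subject_id: str = "S", stimulus_id: str = "I",
                    trial_id: str = "1") -> FixationSequence:
    """Sample one fixation sequence: hidden ROI path from the prior/transition
    chain, then a Gaussian draw per visited ROI."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    K = hmm.n_states
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(K, p=hmm.prior / hmm.prior.sum())
    for t in range(1, length):
        row = hmm.transition[states[t - 1]]
        states[t] = rng.choice(K, p=row / row.sum())
    points = np.empty((length, 2))
    for t, k in enumerate(states):
        points[t] = rng.multivariate_normal(hmm.rois[k].mean,
                                            hmm.rois[k].covariance)
    return FixationSequence(subject_id, stimulus_id, trial_id, points)


def sample_sequences(hmm: Hmm, n: int, length: int,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample ``n`` equal-length sequences at once; returns (n, length, 2).

    Vectorised across sequences (same generative process as
    :func:`sample_sequence` but not draw-for-draw identical to it).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    K = hmm.n_states
    states = np.empty((n, length), dtype=int)
    u = rng.random((n, length))
    states[:, 0] = np.searchsorted(np.cumsum(hmm.prior), u[:, 0] *
                                   hmm.prior.sum())
    cum_rows = np.cumsum(hmm.transition, axis=1)
    for t in range(1, length):
        rows = cum_rows[states[:, t - 1]]
        states[:, t] = (u[:, t, None] * rows[:, -1:] > rows).sum(axis=1)
    states = np.clip(states, 0, K - 1)
    chols = np.array([np.linalg.cholesky(r.covariance) for r in hmm.rois])
    z = rng.standard_normal((n, length, 2))
    means = hmm.means[states]                       # (n, length, 2)
    points = means + np.einsum("ntij,ntj->nti", chols[states], z)
    return points


def sample_dataset(truth: GroundTruth, trials_per_stimulus: int = 5,
                   length_distribution=(8, 18), seed: int = 0) -> FixationDataset:
    """Sample a full dataset from the planted truth.

    ``length_distribution``: an int for fixed sequence length, or an inclusive
    (low, high) pair for a discrete uniform draw per trial; the default 8–18
    emulates a mean of about 13 fixations per trial of passive scene viewing.
    """
    rng = np.random.default_rng(seed)
    sequences = []
    for subj in truth.subjects:
        g = truth.assignments[subj]
        for stim in truth.stimuli:
            hmm = truth.group_hmms[(g, stim)]
            for trial in range(1, trials_per_stimulus + 1):
                if isinstance(length_distribution, int):
                    T = length_distribution
                else:
                    lo, hi = length_distribution
                    T = int(rng.integers(lo, hi + 1))
                sequences.append(sample_sequence(
                    hmm, T, seed=rng, subject_id=subj, stimulus_id=stim,
                    trial_id=str(trial)))
    return FixationDataset(sequences=sequences, subjects=truth.subjects,
                           stimuli=list(truth.stimuli),
                           stimulus_size={s: truth.stimulus_size
                                          for s in truth.stimuli})


def make_hmm_grid(truth: GroundTruth, mean_jitter: float = 10.0,
                  n_sequences: int = 5, median_length: int = 13,
                  seed: int = 0):
    """Build a subject × stimulus grid of individual HMMs directly from the
    planted truth, perturbing each subject's ROI means by Gaussian jitter.

    This bypasses per-subject fitting and is the fast route for exercising the
    HMM-clustering stage on models with known group structure.
    """
    from .cocluster import HmmGrid
    rng = np.random.default_rng(seed)
    hmms = {}
    n_seq = {}
    med_len = {}
    for subj in truth.subjects:
        g = truth.assignments[subj]
        for stim in truth.stimuli:
            base = truth.group_hmms[(g, stim)]
            rois = tuple(GaussianRoi(r.mean + rng.normal(0, mean_jitter, 2),
                                     r.covariance)
                         for r in base.rois)
            hmms[(subj, stim)] = Hmm(prior=base.prior,
                                     transition=base.transition, rois=rois)
            n_seq[(subj, stim)] = n_sequences
            med_len[(subj, stim)] = float(median_length)
    return HmmGrid(hmms=hmms, subjects=truth.subjects,
                   stimuli=list(truth.stimuli), n_sequences=n_seq,
                   median_length=med_len)
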
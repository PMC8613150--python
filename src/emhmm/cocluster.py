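"""Co-clustering a subject × stimulus grid of HMMs into participant groups.

Each subject contributes one fitted HMM per stimulus. Co-clustering groups the
subjects — with a single group assignment per subject shared across all
stimuli — and produces one representative (reduced) HMM per (group, stimulus).
Two variants are provided:

* ``vhem_cocluster`` — variational hierarchical EM with a fixed number of
  groups: responsibilities are proportional to the group weight times the
  exponentiated sum, over stimuli, of a variational lower bound on the
  expected log-likelihood of virtual samples from the subject's HMM under the
  group's representative HMM; representative HMMs are re-estimated from
  responsibility-weighted aggregation of the base HMMs' statistics. No
  sequences are ever sampled: all expectations are closed-form.
* ``vbhem_cocluster`` — the variational-Bayesian extension with Dirichlet
  priors on group weights, initial-state vectors and transition rows and
  Normal–Wishart priors on the representative Gaussians. Its objective is a
  bound on the expected marginal log-likelihood, so it can be compared across
  different group counts; superfluous groups shrink under the Dirichlet prior
  and the best count is the one with the highest bound.

The per-pair bound follows the variational-HEM construction for hidden Markov
mixtures: expected Gaussian cross log-likelihoods between base and reduced
states, combined through a backward recursion over the virtual-sequence length
with log-sum-exp over reduced states (the optimal variational assignment), and
averaged over the base chain's state distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import ttest_rel
from sklearn.cluster import KMeans

from .io import FixationDataset
from .model import GaussianRoi, Hmm, HyperParams
from .vbhmm import _kl_dirichlet, _kl_normal_wishart, NumericalError

__all__ = ["HmmGrid", "CoClusterModel", "expected_loglik_bound",
           "vhem_cocluster", "vhem_cluster_hmms", "vbhem_cocluster",
           "median_states", "group_separation_report", "fit_hmm_grid"]

_D = 2
_LOG_2PI = float(np.log(2.0 * np.pi))


def _lse(a: np.ndarray, axis: int = -1, keepdims: bool = False) -> np.ndarray:
    """Log-sum-exp specialised for small dense arrays (hot path)."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return out if keepdims else np.squeeze(out, axis=axis)


@dataclass
class HmmGrid:
    """Subject × stimulus matrix of fitted individual HMMs.

    Cells may be missing (subject did not view the stimulus); present cells
    carry the number of training sequences and the median sequence length,
    which weight the subject's HMM inside the clustering bound.
    """

    hmms: dict[tuple[str, str], Hmm]
    subjects: list[str]
    stimuli: list[str]
    n_sequences: dict[tuple[str, str], int] = field(default_factory=dict)
    median_length: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        subj, stim = set(self.subjects), set(self.stimuli)
        for (s, t) in self.hmms:
            if s not in subj or t not in stim:
                raise ValueError(f"cell ({s},{t}) outside the grid indices")
        for key in self.hmms:
            self.n_sequences.setdefault(key, 1)
            self.median_length.setdefault(key, 13.0)

    def cells(self, subject: str):
        return [(t, self.hmms[(subject, t)]) for t in self.stimuli
                if (subject, t) in self.hmms]

    def state_counts(self, stimulus: str) -> list[int]:
        return [self.hmms[(s, stimulus)].n_states for s in self.subjects
                if (s, stimulus) in self.hmms]


@dataclass
class CoClusterModel:
    """Result of co-clustering: group assignments shared across stimuli plus a
    representative HMM per (group, stimulus)."""

    n_groups: int
    subjects: list[str]
    stimuli: list[str]
    assignments: dict[str, int]
    responsibilities: np.ndarray          # (n_subjects, n_groups)
    group_hmms: dict[tuple[int, str], Hmm]
    group_weights: np.ndarray
    objective: float
    objective_history: np.ndarray = field(
        default_factory=lambda: np.zeros(0), compare=False)

    def __post_init__(self) -> None:
        resp = np.asarray(self.responsibilities, float)
        if resp.shape != (len(self.subjects), self.n_groups):
            raise ValueError("responsibilities shape mismatch")
        if np.any(np.abs(resp.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("responsibility rows must sum to 1")
        for i, s in enumerate(self.subjects):
            if self.assignments[s] != int(np.argmax(resp[i])):
                raise ValueError("assignments must be the argmax responsibilities")
        if abs(float(np.sum(self.group_weights)) - 1.0) > 1e-6:
            raise ValueError("group weights must sum to 1")

    def group_hmm_map(self, group: int) -> dict[str, Hmm]:
        """Per-stimulus representative HMMs for one group."""
        return {t: self.group_hmms[(group, t)] for t in self.stimuli
                if (group, t) in self.group_hmms}

    def members(self, group: int) -> list[str]:
        return [s for s in self.subjects if self.assignments[s] == group]


# ---------------------------------------------------------------------------
# The expected log-likelihood lower bound between two HMMs
# ---------------------------------------------------------------------------

def _cross_gaussian_point(base: Hmm, red_means, red_covs) -> np.ndarray:
    """(Kb, Kr) matrix of E_{base state b}[ln N(y; mu_r, Sigma_r)]."""
    Kb, Kr = base.n_states, red_means.shape[0]
    out = np.empty((Kb, Kr))
    b_means, b_covs = base.means, base.covariances
    for r in range(Kr):
        cov = red_covs[r]
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise NumericalError(f"reduced covariance {r} not positive definite")
        prec = np.linalg.inv(cov)
        for b in range(Kb):
            dm = b_means[b] - red_means[r]
            out[b, r] = -0.5 * (_D * _LOG_2PI + logdet
                                + np.trace(prec @ b_covs[b])
                                + float(dm @ prec @ dm))
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))[0]
        raise NumericalError(f"non-finite cross term for state pair {tuple(bad)}")
    return out


def _backward_bound(log_pi_r, log_A_r, l, base_pi, base_A, T):
    """Backward recursion of the variational bound.

    Returns (J, Fs) where J is the per-virtual-sequence bound and Fs[t]
    (t = 2..T+1) are the future-contribution matrices needed for statistics.
    """
    Kb = l.shape[0]
    Kr = l.shape[1]
    Fs = [None] * (T + 2)
    Fs[T + 1] = np.zeros((Kb, Kr))
    for t in range(T, 1, -1):
        inner = _lse(log_A_r[None, :, :] + (l + Fs[t + 1])[:, None, :], axis=2)                      # (Kb_t, Kr_prev)
        Fs[t] = base_A @ inner                         # (Kb_prev, Kr_prev)
    first = _lse(log_pi_r[None, :] + l + Fs[2], axis=1)
    return float(base_pi @ first), Fs


def _pair_statistics(log_pi_r, log_A_r, l, base_pi, base_A, T, Fs):
    """Expected counts under the optimal variational assignment.

    Returns (nu1 (Kr,), xi (Kr, Kr), occ (Kb, Kr)): expected initial reduced-
    state counts, expected reduced-state transition counts, and the expected
    co-occupancy of (base state, reduced state) summed over time.
    """
    log_phi1 = log_pi_r[None, :] + l + Fs[2]
    phi1 = np.exp(log_phi1 - _lse(log_phi1, axis=1, keepdims=True))
    p = base_pi[:, None] * phi1                        # (Kb, Kr)
    nu1 = p.sum(axis=0)
    occ = p.copy()
    Kr = log_pi_r.shape[0]
    xi = np.zeros((Kr, Kr))
    for t in range(2, T + 1):
        log_phi = log_A_r[:, None, :] + (l + Fs[t + 1])[None, :, :]
        phi = np.exp(log_phi - _lse(log_phi, axis=2, keepdims=True))
        arriving = np.einsum("bp,bc->pc", p, base_A)   # (Kr_prev, Kb_t)
        joint = arriving[:, :, None] * phi             # (Kr_prev, Kb_t, Kr_t)
        xi += joint.sum(axis=1)
        p = joint.sum(axis=0)
        occ += p
    return nu1, xi, occ


def expected_loglik_bound(base: Hmm, reduced: Hmm, n_virtual: int = 1,
                          t_virtual: int = 13) -> float:
    """Variational lower bound on ``n_virtual × E_base[log p(y_1..T | reduced)]``
    for virtual sequences of length ``t_virtual`` drawn from ``base``.

    Computed in closed form from pairwise expected Gaussian cross
    log-likelihoods and expected transition terms; no sampling. The bound is
    tight when the two models' states correspond one-to-one and is always a
    lower bound on the true expected log-likelihood.
    """
    if t_virtual < 1 or n_virtual < 1:
        raise ValueError("t_virtual and n_virtual must be >= 1")
    l = _cross_gaussian_point(base, reduced.means, reduced.covariances)
    with np.errstate(divide="ignore"):
        log_pi_r = np.log(np.maximum(reduced.prior, 1e-300))
        log_A_r = np.log(np.maximum(reduced.transition, 1e-300))
    J, _ = _backward_bound(log_pi_r, log_A_r, l, base.prior, base.transition,
                           t_virtual)
    return n_virtual * J


# ---------------------------------------------------------------------------
# Shared E/M machinery
# ---------------------------------------------------------------------------

def median_states(grid: HmmGrid, stimulus: str) -> int:
    """Median state count of the individual HMMs for one stimulus;
    half-integer medians round up (the richer representative model)."""
    counts = grid.state_counts(stimulus)
    if not counts:
        raise ValueError(f"no HMMs for stimulus {stimulus!r}")
    return int(np.ceil(np.median(counts) - 1e-9))


def _resize_hmm(hmm: Hmm, k_target: int, rng: np.random.Generator) -> Hmm:
    """Adapt a seed HMM to the target state count: drop the lowest-prior states
    or split the heaviest ones with jittered means."""
    k = hmm.n_states
    if k == k_target:
        return hmm
    if k > k_target:
        keep = np.argsort(hmm.prior)[::-1][:k_target]
        keep.sort()
        prior = hmm.prior[keep]
        trans = hmm.transition[np.ix_(keep, keep)]
        return Hmm(prior=prior / prior.sum(),
                   transition=trans / trans.sum(axis=1, keepdims=True),
                   rois=tuple(hmm.rois[i] for i in keep))
    prior = list(hmm.prior)
    trans_rows = [list(row) for row in hmm.transition]
    rois = list(hmm.rois)
    while len(rois) < k_target:
        j = int(np.argmax(prior))
        sd = float(np.sqrt(np.trace(rois[j].covariance) / 2.0))
        jitter = rng.normal(0.0, 0.25 * sd, 2)
        rois.append(GaussianRoi(rois[j].mean + jitter, rois[j].covariance))
        prior[j] *= 0.5
        prior.append(prior[j])
        for row in trans_rows:
            row[j] *= 0.5
            row.append(row[j])
        trans_rows.append(list(trans_rows[j]))
    prior = np.array(prior)
    trans = np.array(trans_rows)
    return Hmm(prior=prior / prior.sum(),
               transition=trans / trans.sum(axis=1, keepdims=True),
               rois=tuple(rois))


def _resolve_k(grid: HmmGrid, k_per_stimulus) -> dict[str, int]:
    if k_per_stimulus == "median" or k_per_stimulus is None:
        return {t: median_states(grid, t) for t in grid.stimuli}
    return {t: int(k_per_stimulus[t]) for t in grid.stimuli}


def _cell_weights(grid: HmmGrid, subject: str, stimulus: str,
                  n_virtual, t_virtual) -> tuple[int, int]:
    n = n_virtual if n_virtual is not None else grid.n_sequences[(subject, stimulus)]
    t = t_virtual if t_virtual is not None else \
        int(round(grid.median_length[(subject, stimulus)]))
    return max(int(n), 1), max(int(t), 1)


def _seed_subjects(grid: HmmGrid, n_groups: int, restart: int,
                   rng: np.random.Generator, n_virtual, t_virtual) -> list[str]:
    subjects = grid.subjects
    if restart == 0 and n_groups > 1:
        # cluster subjects on their pairwise expected-log-likelihood bounds
        feats = np.zeros((len(subjects), len(subjects)))
        for a, sa in enumerate(subjects):
            for b, sb in enumerate(subjects):
                tot = 0.0
                for stim, hmm_a in grid.cells(sa):
                    if (sb, stim) not in grid.hmms:
                        continue
                    n, t = _cell_weights(grid, sa, stim, n_virtual, t_virtual)
                    tot += expected_loglik_bound(hmm_a, grid.hmms[(sb, stim)],
                                                 n, t)
                feats[a, b] = tot
        scale = np.std(feats) or 1.0
        km = KMeans(n_clusters=n_groups, n_init=3,
                    random_state=int(rng.integers(0, 2**31 - 1)))
        labels = km.fit_predict(feats / scale)
        seeds = []
        for g in range(n_groups):
            members = np.flatnonzero(labels == g)
            if members.size == 0:
                members = np.arange(len(subjects))
            centre = km.cluster_centers_[g]
            best = members[int(np.argmin(
                np.linalg.norm(feats[members] / scale - centre, axis=1)))]
            seeds.append(subjects[best])
        if len(set(seeds)) == n_groups:
            return seeds
    idx = rng.choice(len(subjects), size=n_groups, replace=False)
    return [subjects[i] for i in idx]


def _init_group_hmms(grid: HmmGrid, seeds: list[str], k_by_stim: dict[str, int],
                     rng: np.random.Generator) -> dict[tuple[int, str], Hmm]:
    out = {}
    for g, subj in enumerate(seeds):
        for stim in grid.stimuli:
            key = (subj, stim)
            if key not in grid.hmms:  # fall back to any subject with this cell
                for s2 in grid.subjects:
                    if (s2, stim) in grid.hmms:
                        key = (s2, stim)
                        break
            out[(g, stim)] = _resize_hmm(grid.hmms[key], k_by_stim[stim], rng)
    return out


def _aggregate_emissions(stats, weights):
    """Responsibility-weighted moments of the virtual emissions for one
    (group, stimulus): returns (N (Kr,), mom1 (Kr,2), mom2 (Kr,2,2))."""
    Kr = stats[0][2].shape[1]
    N = np.zeros(Kr)
    mom1 = np.zeros((Kr, _D))
    mom2 = np.zeros((Kr, _D, _D))
    for (nu1, xi, occ, b_means, b_covs), w in zip(stats, weights):
        wocc = w * occ                                  # (Kb, Kr)
        N += wocc.sum(axis=0)
        mom1 += wocc.T @ b_means
        outer = b_covs + np.einsum("bi,bj->bij", b_means, b_means)
        mom2 += np.einsum("br,bij->rij", wocc, outer)
    return N, mom1, mom2


# ---------------------------------------------------------------------------
# VHEM (fixed number of groups)
# ---------------------------------------------------------------------------

def vhem_cocluster(grid: HmmGrid, n_groups: int,
                   k_per_stimulus="median", n_virtual: int | None = None,
                   t_virtual: int | None = None, restarts: int = 5,
                   seed: int = 0, max_iter: int = 100, tol: float = 1e-6,
                   min_weight: float = 1.0) -> CoClusterModel:
    """Co-cluster the grid into a fixed number of groups by variational
    hierarchical EM.

    One responsibility vector per subject is shared across all stimuli (the
    co-clustering constraint); representative HMMs per (group, stimulus) are
    re-estimated from responsibility-weighted aggregation of the subjects'
    HMM statistics. Returns the best of ``restarts`` seeded initialisations.
    ``n_virtual``/``t_virtual`` default to each cell's training-sequence count
    and median sequence length.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(grid.subjects):
        raise ValueError(f"n_groups={n_groups} exceeds {len(grid.subjects)} subjects")
    if not grid.hmms:
        raise ValueError("empty grid")
    k_by_stim = _resolve_k(grid, k_per_stimulus)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(restarts, 1)):
        model = _run_hem(grid, n_groups, k_by_stim, n_virtual, t_virtual,
                         rng, restart, max_iter, tol, min_weight,
                         variational_bayes=False, hyper=None,
                         omega_concentration=None)
        if best is None or model.objective > best.objective:
            best = model
    return best


def vhem_cluster_hmms(hmms: list[Hmm], n_groups: int, k_states=None,
                      n_virtual: int = 1, t_virtual: int = 13,
                      restarts: int = 5, seed: int = 0,
                      **kwargs) -> CoClusterModel:
    """Plain (non-co-) VHEM clustering of a single set of HMMs.

    Wraps the HMMs into a one-stimulus grid and runs :func:`vhem_cocluster`;
    with a single stimulus the co-clustering constraint is vacuous, so this is
    ordinary hierarchical-EM clustering of HMMs.
    """
    grid = HmmGrid(hmms={(f"S{i:03d}", "I1"): h for i, h in enumerate(hmms)},
                   subjects=[f"S{i:03d}" for i in range(len(hmms))],
                   stimuli=["I1"])
    k = "median" if k_states is None else {"I1": int(k_states)}
    return vhem_cocluster(grid, n_groups, k_per_stimulus=k,
                          n_virtual=n_virtual, t_virtual=t_virtual,
                          restarts=restarts, seed=seed, **kwargs)


def vbhem_cocluster(grid: HmmGrid, g_range=range(1, 6),
                    k_per_stimulus="median", hyper: HyperParams | None = None,
                    n_virtual: int | None = None, t_virtual: int | None = None,
                    restarts: int = 5, seed: int = 0, max_iter: int = 100,
                    tol: float = 1e-6, min_weight: float = 1.0) -> CoClusterModel:
    """Variational-Bayesian co-clustering with automatic group-count selection.

    Runs the VB variant for every group count in ``g_range`` (priors on the
    representative HMMs' parameters and a Dirichlet prior on group weights
    with concentration 1/max(g_range), so superfluous groups shrink), selects
    the model with the highest expected-marginal-log-likelihood bound (ties
    within 1e-6 broken toward fewer groups), and removes groups whose
    posterior weight collapsed before reporting ``n_groups``.
    """
    gs = sorted(set(int(g) for g in g_range))
    if not gs:
        raise ValueError("g_range must be non-empty")
    if gs[0] < 1 or gs[-1] > len(grid.subjects):
        raise ValueError(f"g_range must lie within [1, {len(grid.subjects)}]")
    k_by_stim = _resolve_k(grid, k_per_stimulus)
    if hyper is None:
        all_means = np.concatenate([h.means for h in grid.hmms.values()])
        w = max(float(all_means[:, 0].max()), 1.0)
        h = max(float(all_means[:, 1].max()), 1.0)
        hyper = HyperParams(m0=all_means.mean(axis=0), stimulus_size=(w, h))
    omega_conc = 1.0 / gs[-1]
    best = None
    for G in gs:
        rng = np.random.default_rng(seed + 7919 * G)
        best_g = None
        for restart in range(max(restarts, 1)):
            model = _run_hem(grid, G, k_by_stim, n_virtual, t_virtual, rng,
                             restart, max_iter, tol, min_weight,
                             variational_bayes=True, hyper=hyper,
                             omega_concentration=omega_conc)
            if best_g is None or model.objective > best_g.objective:
                best_g = model
        if best is None or best_g.objective > best.objective + 1e-6:
            best = best_g
    return _drop_collapsed_groups(best)


def _drop_collapsed_groups(model: CoClusterModel,
                           min_members: float = 0.5) -> CoClusterModel:
    counts = model.responsibilities.sum(axis=0)
    keep = np.flatnonzero(counts >= min_members)
    if keep.size == model.n_groups or keep.size == 0:
        return model
    resp = model.responsibilities[:, keep]
    resp = resp / resp.sum(axis=1, keepdims=True)
    weights = model.group_weights[keep]
    weights = weights / weights.sum()
    assignments = {s: int(np.argmax(resp[i]))
                   for i, s in enumerate(model.subjects)}
    group_hmms = {(int(np.where(keep == g)[0][0]), t): hmm
                  for (g, t), hmm in model.group_hmms.items() if g in keep}
    return CoClusterModel(n_groups=keep.size, subjects=model.subjects,
                          stimuli=model.stimuli, assignments=assignments,
                          responsibilities=resp, group_hmms=group_hmms,
                          group_weights=weights, objective=model.objective,
                          objective_history=model.objective_history)


def _group_params(hmm: Hmm):
    """Point-parameter container used during EM for one reduced HMM."""
    return dict(prior=hmm.prior.copy(), transition=hmm.transition.copy(),
                means=hmm.means, covs=hmm.covariances)


def _run_hem(grid: HmmGrid, G: int, k_by_stim, n_virtual, t_virtual, rng,
             restart: int, max_iter: int, tol: float, min_weight: float,
             variational_bayes: bool, hyper: HyperParams | None,
             omega_concentration: float | None) -> CoClusterModel:
    subjects, stimuli = grid.subjects, grid.stimuli
    N = len(subjects)
    seeds = _seed_subjects(grid, G, restart, rng, n_virtual, t_virtual)
    reduced = {k: _group_params(h) for k, h in
               _init_group_hmms(grid, seeds, k_by_stim, rng).items()}
    # VB posterior hyperparameters for the reduced HMMs, refreshed each M-step
    vb_post: dict = {}
    log_omega = np.full(G, -np.log(G))
    alpha_omega = None

    cell_nt = {key: _cell_weights(grid, key[0], key[1], n_virtual, t_virtual)
               for key in grid.hmms}

    history = []
    obj_prev = -np.inf
    resp = np.full((N, G), 1.0 / G)
    reseeded = False
    for _ in range(max_iter):
        # ---- E-step: bounds, responsibilities, pair statistics ----
        scores = np.zeros((N, G))           # sum over stimuli of n * bound
        pair_stats = {}                     # (i, g, stim) -> stats tuple
        for g in range(G):
            for stim in stimuli:
                rp = reduced[(g, stim)]
                if variational_bayes:
                    l_fn, log_pi_r, log_A_r = _vb_expectations(
                        vb_post.get((g, stim)), rp)
                else:
                    with np.errstate(divide="ignore"):
                        log_pi_r = np.log(np.maximum(rp["prior"], 1e-300))
                        log_A_r = np.log(np.maximum(rp["transition"], 1e-300))
                    l_fn = None
                for i, subj in enumerate(subjects):
                    key = (subj, stim)
                    if key not in grid.hmms:
                        continue
                    base = grid.hmms[key]
                    n, t = cell_nt[key]
                    if l_fn is not None:
                        l = l_fn(base)
                    else:
                        l = _cross_gaussian_point(base, rp["means"], rp["covs"])
                    J, Fs = _backward_bound(log_pi_r, log_A_r, l,
                                            base.prior, base.transition, t)
                    scores[i, g] += n * J
                    nu1, xi, occ = _pair_statistics(
                        log_pi_r, log_A_r, l, base.prior, base.transition, t, Fs)
                    pair_stats[(i, g, stim)] = (nu1, xi, occ,
                                                base.means, base.covariances,
                                                n)
        log_r = log_omega[None, :] + scores
        norm = _lse(log_r, axis=1)
        resp = np.exp(log_r - norm[:, None])
        objective = float(norm.sum())
        if variational_bayes:
            objective -= _vb_kl_total(alpha_omega, omega_concentration, G,
                                      vb_post, hyper, stimuli)
        if not np.isfinite(objective):
            raise NumericalError("non-finite co-clustering objective")

        counts = resp.sum(axis=0)
        if not variational_bayes and np.any(counts < 0.5) and G > 1:
            if not reseeded:
                # re-seed each empty cluster from the worst-fitting subject
                reseeded = True
                own = scores[np.arange(N), np.argmax(resp, axis=1)]
                for g in np.flatnonzero(counts < 0.5):
                    worst = int(np.argmin(own))
                    for stim in stimuli:
                        key = (subjects[worst], stim)
                        if key in grid.hmms:
                            reduced[(g, stim)] = _group_params(_resize_hmm(
                                grid.hmms[key], k_by_stim[stim], rng))
                    resp[worst] = np.eye(G)[g]
                    own[worst] = np.inf
                counts = resp.sum(axis=0)
                obj_prev = -np.inf
                history.clear()
            else:
                keep = np.flatnonzero(counts >= 0.5)
                warnings.warn(f"cluster collapsed; continuing with {keep.size} "
                              f"of {G} groups", stacklevel=2)
                sub = _finalize(grid, resp[:, keep] /
                                resp[:, keep].sum(axis=1, keepdims=True),
                                {(int(np.where(keep == g)[0][0]), t): p
                                 for (g, t), p in reduced.items() if g in keep},
                                counts[keep] / counts[keep].sum(),
                                objective, history, vb_post=None,
                                min_weight=min_weight, pair_stats=None)
                return sub

        history.append(objective)
        if objective - obj_prev < tol * max(1.0, abs(objective)) \
                and len(history) > 1:
            break
        obj_prev = objective

        # ---- M-step ----
        if variational_bayes:
            alpha_omega = omega_concentration + counts
            log_omega = digamma(alpha_omega) - digamma(alpha_omega.sum())
        else:
            log_omega = np.log(np.maximum(counts / counts.sum(), 1e-300))
        for g in range(G):
            for stim in stimuli:
                stats, weights = [], []
                nu1_acc = None
                xi_acc = None
                for i, subj in enumerate(subjects):
                    st = pair_stats.get((i, g, stim))
                    if st is None:
                        continue
                    nu1, xi, occ, b_means, b_covs, n = st
                    w = resp[i, g] * n
                    stats.append((nu1, xi, occ, b_means, b_covs))
                    weights.append(w)
                    nu1_acc = w * nu1 if nu1_acc is None else nu1_acc + w * nu1
                    xi_acc = w * xi if xi_acc is None else xi_acc + w * xi
                if nu1_acc is None:
                    continue
                Nk, mom1, mom2 = _aggregate_emissions(stats, weights)
                if variational_bayes:
                    vb_post[(g, stim)] = _vb_mstep(nu1_acc, xi_acc, Nk, mom1,
                                                   mom2, hyper)
                    reduced[(g, stim)] = _vb_point_params(vb_post[(g, stim)])
                else:
                    reduced[(g, stim)] = _ml_mstep(nu1_acc, xi_acc, Nk, mom1,
                                                   mom2, reduced[(g, stim)])

    weights_out = resp.sum(axis=0)
    weights_out = weights_out / weights_out.sum()
    return _finalize(grid, resp, reduced, weights_out, history[-1], history,
                     vb_post if variational_bayes else None, min_weight,
                     pair_stats)


def _vb_expectations(post, reduced_params):
    """Expected-log parameters and a cross-term closure for one VB reduced HMM."""
    if post is None:
        # before the first M-step, fall back to point parameters
        with np.errstate(divide="ignore"):
            log_pi = np.log(np.maximum(reduced_params["prior"], 1e-300))
            log_A = np.log(np.maximum(reduced_params["transition"], 1e-300))
        means, covs = reduced_params["means"], reduced_params["covs"]
        return (lambda base: _cross_gaussian_point(base, means, covs),
                log_pi, log_A)
    log_pi = digamma(post["alpha"]) - digamma(post["alpha"].sum())
    log_A = digamma(post["epsilon"]) \
        - digamma(post["epsilon"].sum(axis=1, keepdims=True))
    m, beta, W, nu = post["m"], post["beta"], post["W"], post["nu"]
    Kr = m.shape[0]
    elogdet = np.empty(Kr)
    for r in range(Kr):
        sign, logdet = np.linalg.slogdet(W[r])
        elogdet[r] = (digamma(nu[r] / 2.0) + digamma((nu[r] - 1.0) / 2.0)
                      + _D * np.log(2.0) + logdet)

    def l_fn(base: Hmm) -> np.ndarray:
        Kb = base.n_states
        out = np.empty((Kb, Kr))
        for r in range(Kr):
            for b in range(Kb):
                dm = base.rois[b].mean - m[r]
                quad = np.trace(W[r] @ base.rois[b].covariance) \
                    + float(dm @ W[r] @ dm)
                out[b, r] = 0.5 * elogdet[r] - 0.5 * _D * _LOG_2PI \
                    - 0.5 * (_D / beta[r] + nu[r] * quad)
        return out

    return l_fn, log_pi, log_A


def _vb_mstep(nu1_acc, xi_acc, Nk, mom1, mom2, hyper: HyperParams) -> dict:
    Kr = Nk.shape[0]
    alpha = hyper.alpha0 + nu1_acc
    epsilon = hyper.epsilon0 + xi_acc
    beta = hyper.beta0 + Nk
    nu = hyper.nu0 + Nk
    m = np.empty((Kr, _D))
    W = np.empty((Kr, _D, _D))
    W0_inv = np.linalg.inv(hyper.effective_W0())
    for r in range(Kr):
        xbar = mom1[r] / Nk[r] if Nk[r] > 1e-12 else hyper.m0
        scatter = mom2[r] - Nk[r] * np.outer(xbar, xbar)
        m[r] = (hyper.beta0 * hyper.m0 + Nk[r] * xbar) / beta[r]
        dm = xbar - hyper.m0
        W_inv = W0_inv + scatter \
            + (hyper.beta0 * Nk[r] / (hyper.beta0 + Nk[r])) * np.outer(dm, dm)
        W[r] = np.linalg.inv(0.5 * (W_inv + W_inv.T))
        W[r] = 0.5 * (W[r] + W[r].T)
    return dict(alpha=alpha, epsilon=epsilon, m=m, beta=beta, W=W, nu=nu,
                Nk=Nk)


def _vb_point_params(post: dict) -> dict:
    prior = post["alpha"] / post["alpha"].sum()
    trans = post["epsilon"] / post["epsilon"].sum(axis=1, keepdims=True)
    Kr = prior.shape[0]
    covs = np.empty((Kr, _D, _D))
    for r in range(Kr):
        denom = post["nu"][r] - _D - 1.0
        cov = np.linalg.inv(post["W"][r]) / denom if denom > 0.5 else \
            np.linalg.inv(post["nu"][r] * post["W"][r])
        covs[r] = 0.5 * (cov + cov.T)
    return dict(prior=prior, transition=trans, means=post["m"].copy(),
                covs=covs)


def _ml_mstep(nu1_acc, xi_acc, Nk, mom1, mom2, previous: dict) -> dict:
    Kr = Nk.shape[0]
    prior = nu1_acc / nu1_acc.sum()
    trans = np.empty((Kr, Kr))
    means = np.empty((Kr, _D))
    covs = np.empty((Kr, _D, _D))
    for r in range(Kr):
        row = xi_acc[r]
        trans[r] = row / row.sum() if row.sum() > 1e-12 \
            else np.full(Kr, 1.0 / Kr)
        if Nk[r] > 1e-9:
            means[r] = mom1[r] / Nk[r]
            cov = mom2[r] / Nk[r] - np.outer(means[r], means[r])
            cov = 0.5 * (cov + cov.T)
            # guard against numerically singular aggregates
            eig = np.linalg.eigvalsh(cov)
            if eig[0] < 1e-6:
                cov += (1e-6 - min(eig[0], 0.0) + 1e-8) * np.eye(_D)
            covs[r] = cov
        else:  # starved state: keep the previous parameters
            means[r] = previous["means"][r]
            covs[r] = previous["covs"][r]
    return dict(prior=prior, transition=trans, means=means, covs=covs)


def _vb_kl_total(alpha_omega, omega_concentration, G, vb_post,
                 hyper: HyperParams, stimuli) -> float:
    total = 0.0
    if alpha_omega is not None:
        total += _kl_dirichlet(alpha_omega, np.full(G, omega_concentration))
    W0 = hyper.effective_W0()
    for post in vb_post.values():
        Kr = post["alpha"].shape[0]
        total += _kl_dirichlet(post["alpha"], np.full(Kr, hyper.alpha0))
        for r in range(Kr):
            total += _kl_dirichlet(post["epsilon"][r],
                                   np.full(Kr, hyper.epsilon0))
            total += _kl_normal_wishart(post["m"][r], post["beta"][r],
                                        post["W"][r], post["nu"][r],
                                        hyper.m0, hyper.beta0, W0, hyper.nu0)
    return total


def _finalize(grid: HmmGrid, resp, reduced, weights, objective, history,
              vb_post, min_weight, pair_stats) -> CoClusterModel:
    subjects, stimuli = grid.subjects, grid.stimuli
    G = resp.shape[1]
    assignments = {s: int(np.argmax(resp[i])) for i, s in enumerate(subjects)}
    group_hmms = {}
    for (g, stim), p in reduced.items():
        hmm = Hmm.from_arrays(p["prior"], p["transition"], p["means"], p["covs"])
        group_hmms[(g, stim)] = _prune_reduced(hmm, resp, pair_stats, g, stim,
                                               subjects, min_weight)
    return CoClusterModel(n_groups=G, subjects=subjects, stimuli=stimuli,
                          assignments=assignments, responsibilities=resp,
                          group_hmms=group_hmms, group_weights=weights,
                          objective=float(objective),
                          objective_history=np.asarray(history, float))


def _prune_reduced(hmm: Hmm, resp, pair_stats, g, stim, subjects,
                   min_weight) -> Hmm:
    """Drop representative states with negligible aggregated virtual weight."""
    if pair_stats is None:
        return hmm
    agg = np.zeros(hmm.n_states)
    found = False
    for i in range(len(subjects)):
        st = pair_stats.get((i, g, stim))
        if st is None:
            continue
        nu1, xi, occ, _, _, n = st
        agg += resp[i, g] * n * occ.sum(axis=0)
        found = True
    if not found:
        return hmm
    keep = np.flatnonzero(agg >= min_weight)
    if keep.size == 0 or keep.size == hmm.n_states:
        return hmm
    prior = hmm.prior[keep]
    trans = hmm.transition[np.ix_(keep, keep)]
    return Hmm(prior=prior / prior.sum(),
               transition=trans / trans.sum(axis=1, keepdims=True),
               rois=tuple(hmm.rois[i] for i in keep))


# ---------------------------------------------------------------------------
# Fitting a grid from data, and the separation report
# ---------------------------------------------------------------------------

def fit_hmm_grid(dataset: FixationDataset, K_range=range(2, 5),
                 hyper: HyperParams | None = None, restarts: int = 10,
                 seed: int = 0, min_weight: float = 1.0, **kwargs) -> HmmGrid:
    """Fit one VB-HMM per (subject, stimulus) with ROI-count selection and
    pruning; returns the grid ready for co-clustering."""
    from .vbhmm import prune_states, select_num_rois
    rng = np.random.default_rng(seed)
    hmms, n_seq, med_len = {}, {}, {}
    for subj in dataset.subjects:
        for stim in dataset.stimuli:
            seqs = dataset.get(subj, stim)
            if not seqs:
                continue
            fit = select_num_rois(seqs, K_range, hyper, restarts,
                                  seed=int(rng.integers(0, 2**31 - 1)),
                                  **kwargs)
            hmms[(subj, stim)] = prune_states(fit, min_weight)
            n_seq[(subj, stim)] = len(seqs)
            med_len[(subj, stim)] = float(np.median([len(s) for s in seqs]))
    return HmmGrid(hmms=hmms, subjects=list(dataset.subjects),
                   stimuli=list(dataset.stimuli), n_sequences=n_seq,
                   median_length=med_len)


def group_separation_report(model: CoClusterModel, dataset: FixationDataset,
                            mode: str = "mean"):
    """Validate that members of each group are better explained by their own
    group's representative HMMs.

    Returns ``(table, summary)``: the subjects × groups log-likelihood table,
    and a per-group paired comparison (own-group minus best other-group mean
    log-likelihood, paired t statistic and Cohen's d). Groups with fewer than
    two members are skipped with a warning.
    """
    from .likelihood import loglik_table
    groups = sorted({g for (g, _) in model.group_hmms})
    table = loglik_table(dataset, {g: model.group_hmm_map(g) for g in groups},
                         mode=mode)
    rows = []
    if len(groups) > 1:
        for g in groups:
            members = [s for s in model.members(g) if s in table.index]
            if len(members) < 2:
                warnings.warn(f"group {g} has {len(members)} member(s); "
                              "comparison skipped", stacklevel=2)
                continue
            own = table.loc[members, f"group_{g}"]
            others = table.loc[members].drop(columns=f"group_{g}")
            best_other = others.max(axis=1)
            diff = own - best_other
            sd = diff.std(ddof=1)
            tstat, pval = ttest_rel(own, best_other)
            rows.append(dict(group=g, n=len(members),
                             mean_diff=float(diff.mean()),
                             t=float(tstat), p=float(pval),
                             cohen_d=float(diff.mean() / sd) if sd > 0 else np.inf,
                             all_positive=bool((diff >= 0).all())))
    summary = pd.DataFrame(rows)
    return table, summary
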
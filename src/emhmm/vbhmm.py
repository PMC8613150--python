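"""Variational-Bayesian estimation of individual eye-movement HMMs.

One HMM is learned per subject per stimulus from that subject's fixation
sequences. Conjugate priors are placed on all parameters — Dirichlet on the
initial-state vector and on each transition row, Normal–Wishart on each ROI's
Gaussian — and a mean-field VBEM algorithm maximises the evidence lower bound
(ELBO), which approximates the marginal log-likelihood. Model complexity (the
number of ROIs) is selected by refitting over a preset range of state counts
and keeping the fit with the highest ELBO; states that receive negligible
responsibility after training are pruned.

The VBEM scheme is the standard conjugate treatment: the E-step runs the
forward–backward recursions with expected-log-parameter surrogates
(digamma-based), and the ELBO decomposes as the sum of per-sequence surrogate
log-normalisers minus the KL divergences of the posterior Dirichlet and
Normal–Wishart factors from their priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

from .io import FixationSequence
from .model import GaussianRoi, Hmm, HyperParams

__all__ = ["VbFit", "fit_vbhmm", "select_num_rois", "prune_states",
           "DegenerateDataError", "NumericalError"]

_D = 2  # fixation coordinates are 2-D
_LOG_2PI = math.log(2.0 * math.pi)


def _lse(a: np.ndarray, axis: int = -1) -> np.ndarray:
    """Log-sum-exp specialised for the small dense arrays in the recursions."""
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return np.squeeze(m + np.log(np.sum(np.exp(a - m), axis=axis,
                                        keepdims=True)), axis=axis)


class DegenerateDataError(ValueError):
    """Too little data to fit the requested number of states."""


class NumericalError(RuntimeError):
    """A non-finite quantity appeared during optimisation."""


@dataclass
class VbFit:
    """Posterior of one variational-Bayesian HMM fit.

    Holds the posterior hyperparameters (per state / per transition row), the
    per-fixation state responsibilities, the final ELBO in nats, its full
    per-iteration history, and the point-estimate :class:`Hmm` built from
    posterior expectations.
    """

    alpha: np.ndarray            # (K,) posterior Dirichlet for the prior vector
    epsilon: np.ndarray          # (K, K) posterior Dirichlet per transition row
    m: np.ndarray                # (K, 2) posterior Gaussian means
    beta: np.ndarray             # (K,) mean-precision scales
    W: np.ndarray                # (K, 2, 2) posterior Wishart scale matrices
    nu: np.ndarray               # (K,) posterior Wishart degrees of freedom
    responsibilities: list[np.ndarray]   # one (T, K) array per sequence
    elbo: float
    elbo_history: np.ndarray
    point_hmm: Hmm
    hyper: HyperParams
    n_observations: int = 0
    state_weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_states(self) -> int:
        return self.alpha.shape[0]


# ---------------------------------------------------------------------------
# KL divergences of the conjugate posterior factors from their priors
# ---------------------------------------------------------------------------

def _kl_dirichlet(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0, b0 = a.sum(), b.sum()
    return float(gammaln(a0) - gammaln(a).sum() - gammaln(b0) + gammaln(b).sum()
                 + np.sum((a - b) * (digamma(a) - digamma(a0))))


def _expected_logdet_precision(W: np.ndarray, nu: float) -> float:
    # E[ln|Lambda|] for Lambda ~ Wishart(W, nu), d = 2
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0:
        raise NumericalError("posterior Wishart scale not positive definite")
    return float(digamma(nu / 2.0) + digamma((nu - 1.0) / 2.0)
                 + _D * math.log(2.0) + logdet)


def _kl_normal_wishart(m_q, beta_q, W_q, nu_q, m_p, beta_p, W_p, nu_p) -> float:
    """KL(NW_q || NW_p) for one state, d = 2."""
    d = _D
    elogdet = _expected_logdet_precision(W_q, nu_q)
    dm = m_q - m_p
    # expected KL of the conditional Gaussian over the mean
    kl_mean = 0.5 * (d * math.log(beta_q / beta_p) - d + d * beta_p / beta_q
                     + beta_p * nu_q * float(dm @ W_q @ dm))
    # KL between the Wishart factors
    W_p_inv = np.linalg.inv(W_p)
    sign_q, logdet_q = np.linalg.slogdet(W_q)
    sign_p, logdet_p = np.linalg.slogdet(W_p)
    if sign_q <= 0 or sign_p <= 0:
        raise NumericalError("Wishart scale not positive definite")
    kl_wishart = (0.5 * (nu_q - nu_p) * elogdet
                  + 0.5 * nu_q * (np.trace(W_p_inv @ W_q) - d)
                  - 0.5 * nu_q * d * math.log(2.0) - 0.5 * nu_q * logdet_q
                  - multigammaln(nu_q / 2.0, d)
                  + 0.5 * nu_p * d * math.log(2.0) + 0.5 * nu_p * logdet_p
                  + multigammaln(nu_p / 2.0, d))
    return kl_mean + kl_wishart


# ---------------------------------------------------------------------------
# E-step pieces
# ---------------------------------------------------------------------------

def _expected_log_emissions(points: np.ndarray, m, beta, W, nu) -> np.ndarray:
    """(T, K) matrix of E_q[ln N(x_t | mu_k, Lambda_k^-1)]."""
    K = m.shape[0]
    out = np.empty((points.shape[0], K))
    for k in range(K):
        elogdet = _expected_logdet_precision(W[k], nu[k])
        diff = points - m[k]
        maha = nu[k] * np.einsum("ti,ij,tj->t", diff, W[k], diff)
        out[:, k] = 0.5 * elogdet - 0.5 * _D * _LOG_2PI \
            - 0.5 * (_D / beta[k] + maha)
    return out


def _forward_backward(log_pi: np.ndarray, log_A: np.ndarray,
                      log_B: np.ndarray):
    """Log-domain forward–backward with surrogate parameters.

    Returns (gamma (T,K), xi_sum (K,K), log-normaliser).
    """
    T, K = log_B.shape
    log_alpha = np.empty((T, K))
    log_alpha[0] = log_pi + log_B[0]
    for t in range(1, T):
        log_alpha[t] = log_B[t] + _lse(log_alpha[t - 1][:, None] + log_A,
                                       axis=0)
    log_z = float(_lse(log_alpha[-1], axis=0))
    log_beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        log_beta[t] = _lse(log_A + (log_B[t + 1] + log_beta[t + 1])[None, :],
                           axis=1)
    gamma = np.exp(log_alpha + log_beta - log_z)
    xi_sum = np.zeros((K, K))
    for t in range(1, T):
        log_xi = (log_alpha[t - 1][:, None] + log_A
                  + (log_B[t] + log_beta[t])[None, :] - log_z)
        xi_sum += np.exp(log_xi)
    return gamma, xi_sum, log_z


# ---------------------------------------------------------------------------
# VBEM
# ---------------------------------------------------------------------------

def _m_step(seq_points, gammas, xi_sums, first_gammas, hyper: HyperParams, K):
    alpha0 = hyper.alpha0
    eps0 = hyper.epsilon0
    m0, beta0, nu0 = hyper.m0, hyper.beta0, hyper.nu0
    W0_inv = np.linalg.inv(hyper.effective_W0())

    alpha = alpha0 + first_gammas.sum(axis=0)
    epsilon = eps0 + sum(xi_sums)

    all_points = np.concatenate(seq_points, axis=0)
    all_gamma = np.concatenate(gammas, axis=0)
    Nk = all_gamma.sum(axis=0)  # (K,)
    beta = beta0 + Nk
    nu = nu0 + Nk
    m = np.empty((K, _D))
    W = np.empty((K, _D, _D))
    for k in range(K):
        if Nk[k] > 1e-12:
            xbar = (all_gamma[:, k] @ all_points) / Nk[k]
        else:
            xbar = m0.copy()
        diff = all_points - xbar
        Sk = (all_gamma[:, k, None, None]
              * np.einsum("ti,tj->tij", diff, diff)).sum(axis=0)
        m[k] = (beta0 * m0 + Nk[k] * xbar) / beta[k]
        dm = xbar - m0
        W_inv = W0_inv + Sk + (beta0 * Nk[k] / (beta0 + Nk[k])) * np.outer(dm, dm)
        W[k] = np.linalg.inv(W_inv)
        W[k] = 0.5 * (W[k] + W[k].T)
    return alpha, epsilon, m, beta, W, nu, Nk


def _point_hmm(alpha, epsilon, m, beta, W, nu) -> Hmm:
    prior = alpha / alpha.sum()
    transition = epsilon / epsilon.sum(axis=1, keepdims=True)
    rois = []
    for k in range(alpha.shape[0]):
        # posterior expected covariance; nu > d + 1 is guaranteed by nu0 > 3
        denom = nu[k] - _D - 1.0
        cov = np.linalg.inv(W[k]) / denom if denom > 0.5 \
            else np.linalg.inv(nu[k] * W[k])
        rois.append(GaussianRoi(m[k], 0.5 * (cov + cov.T)))
    return Hmm(prior=prior, transition=transition, rois=tuple(rois))


def _run_vbem(seq_points, K, hyper, init_labels, max_iter, tol):
    n_seq = len(seq_points)
    # initial responsibilities: one-hot from the k-means partition for the
    # emissions; uniform pseudo-counts for prior/transition
    gammas = []
    offset = 0
    for pts in seq_points:
        T = pts.shape[0]
        g = np.zeros((T, K))
        g[np.arange(T), init_labels[offset:offset + T]] = 1.0
        gammas.append(g)
        offset += T
    n_trans = sum(max(p.shape[0] - 1, 0) for p in seq_points)
    xi_sums = [np.full((K, K), n_trans / max(n_seq, 1) / (K * K))
               for _ in range(n_seq)]
    first_gammas = np.full((n_seq, K), 1.0 / K)

    elbo_history = []
    elbo_prev = -np.inf
    W0 = hyper.effective_W0()
    alpha, epsilon, m, beta, W, nu, Nk = _m_step(
        seq_points, gammas, xi_sums, first_gammas, hyper, K)
    for _ in range(max_iter):
        # E-step with the current posterior's expected-log surrogates
        log_pi = digamma(alpha) - digamma(alpha.sum())
        log_A = digamma(epsilon) - digamma(epsilon.sum(axis=1, keepdims=True))
        gammas, xi_sums, logzs = [], [], []
        first_gammas = np.empty((n_seq, K))
        for i, pts in enumerate(seq_points):
            log_B = _expected_log_emissions(pts, m, beta, W, nu)
            gamma, xi_sum, log_z = _forward_backward(log_pi, log_A, log_B)
            gammas.append(gamma)
            xi_sums.append(xi_sum)
            logzs.append(log_z)
            first_gammas[i] = gamma[0]
        # the bound pairs the surrogate log-normalisers with the KL of the
        # same posterior that produced them
        kl = _kl_dirichlet(alpha, np.full(K, hyper.alpha0))
        for j in range(K):
            kl += _kl_dirichlet(epsilon[j], np.full(K, hyper.epsilon0))
        for k in range(K):
            kl += _kl_normal_wishart(m[k], beta[k], W[k], nu[k],
                                     hyper.m0, hyper.beta0, W0, hyper.nu0)
        elbo = float(sum(logzs)) - kl
        if not np.isfinite(elbo):
            raise NumericalError(f"non-finite ELBO at K={K}")
        elbo_history.append(elbo)
        converged = elbo - elbo_prev < tol * max(1.0, abs(elbo)) \
            and len(elbo_history) > 1
        elbo_prev = elbo
        # M-step: refresh the posterior from the new responsibilities so the
        # returned fit is consistent with them
        alpha, epsilon, m, beta, W, nu, Nk = _m_step(
            seq_points, gammas, xi_sums, first_gammas, hyper, K)
        if converged:
            break
    return VbFit(alpha=alpha, epsilon=epsilon, m=m, beta=beta, W=W, nu=nu,
                 responsibilities=gammas, elbo=elbo_history[-1],
                 elbo_history=np.array(elbo_history),
                 point_hmm=_point_hmm(alpha, epsilon, m, beta, W, nu),
                 hyper=hyper,
                 n_observations=sum(p.shape[0] for p in seq_points),
                 state_weights=Nk)


def fit_vbhmm(sequences: list[FixationSequence], K: int,
              hyper: HyperParams | None = None, restarts: int = 10,
              seed: int = 0, max_iter: int = 200, tol: float = 1e-5) -> VbFit:
    """Fit a K-state VB-HMM to one subject's fixation sequences for one stimulus.

    Runs ``restarts`` VBEM optimisations from k-means-seeded initial partitions
    of the pooled fixation points and returns the fit with the highest ELBO.
    Deterministic given ``seed``.
    """
    if not sequences:
        raise ValueError("sequences must be non-empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    seq_points = [np.asarray(s.points, float) for s in sequences]
    all_points = np.concatenate(seq_points, axis=0)
    if all_points.shape[0] < K:
        raise DegenerateDataError(
            f"{all_points.shape[0]} fixations cannot support K={K} states")
    if hyper is None:
        # scale-aware defaults inferred from the data's bounding box
        w = max(float(all_points[:, 0].max()), 1.0)
        h = max(float(all_points[:, 1].max()), 1.0)
        hyper = HyperParams(m0=all_points.mean(axis=0), stimulus_size=(w, h))

    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=max(restarts, 1))
    best: VbFit | None = None
    for rs in restart_seeds:
        if K == 1 or np.unique(all_points, axis=0).shape[0] < K:
            labels = np.zeros(all_points.shape[0], dtype=int) if K == 1 else \
                np.random.default_rng(int(rs)).integers(0, K, all_points.shape[0])
        else:
            km = KMeans(n_clusters=K, n_init=1, random_state=int(rs % (2**31)))
            labels = km.fit_predict(all_points)
        fit = _run_vbem(seq_points, K, hyper, labels, max_iter, tol)
        if best is None or fit.elbo > best.elbo:
            best = fit
    return best


def select_num_rois(sequences: list[FixationSequence],
                    K_range=range(2, 5), hyper: HyperParams | None = None,
                    restarts: int = 10, seed: int = 0, **kwargs) -> VbFit:
    """Fit every K in ``K_range`` and return the highest-ELBO fit.

    ELBO ties within 1e-6 are broken toward the smaller state count
    (parsimony). The default range of 2–4 states is the preset used for
    individual eye-movement models.
    """
    ks = sorted(set(int(k) for k in K_range))
    if not ks:
        raise ValueError("K_range must be non-empty")
    fits = [fit_vbhmm(sequences, k, hyper, restarts, seed, **kwargs) for k in ks]
    best = fits[0]
    for fit in fits[1:]:
        if fit.elbo > best.elbo + 1e-6:
            best = fit
    return best


def prune_states(fit: VbFit, min_weight: float = 1.0) -> Hmm:
    """Drop states with total expected responsibility below ``min_weight``
    expected fixations; renormalise the prior and transition over survivors.
    """
    keep = np.flatnonzero(fit.state_weights >= min_weight)
    if keep.size == 0:
        raise ValueError(
            f"all states pruned at min_weight={min_weight}; "
            f"state weights are {fit.state_weights}")
    hmm = fit.point_hmm
    prior = hmm.prior[keep]
    prior = prior / prior.sum()
    trans = hmm.transition[np.ix_(keep, keep)]
    trans = trans / trans.sum(axis=1, keepdims=True)
    rois = tuple(hmm.rois[i] for i in keep)
    return Hmm(prior=prior, transition=trans, rois=rois)
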
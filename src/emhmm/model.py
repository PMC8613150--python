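"""Core model containers: Gaussian regions of interest and hidden Markov models.

An eye-movement pattern for one subject viewing one stimulus is summarised by a
hidden Markov model whose hidden states are regions of interest (ROIs) with 2-D
Gaussian emission densities over fixation locations (pixels), a prior vector over
the starting ROI, and a row-stochastic transition matrix describing how gaze moves
between ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianRoi", "Hmm", "HyperParams"]

_PROB_TOL = 1e-8


@dataclass(frozen=True)
class GaussianRoi:
    """A region of interest: a 2-D Gaussian over fixation locations.

    Parameters
    ----------
    mean : (2,) array
        ROI centre in pixels (x, y).
    covariance : (2, 2) array
        Symmetric positive-definite covariance in pixels².
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(2)
        cov = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("ROI covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if np.any(eigvals <= 0):
            raise ValueError(f"ROI covariance must be positive definite, eigvals={eigvals}")
        if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(cov))):
            raise ValueError("ROI parameters must be finite")


@dataclass(frozen=True)
class Hmm:
    """A point-estimate eye-movement model.

    Attributes
    ----------
    prior : (K,) array
        Probability that a fixation sequence starts in each ROI.
    transition : (K, K) array
        Row-stochastic transition probabilities among ROIs.
    rois : tuple of GaussianRoi
        One Gaussian emission per hidden state.
    """

    prior: np.ndarray
    transition: np.ndarray
    rois: tuple[GaussianRoi, ...]

    def __post_init__(self) -> None:
        prior = np.asarray(self.prior, dtype=float).reshape(-1)
        trans = np.asarray(self.transition, dtype=float)
        rois = tuple(self.rois)
        k = prior.shape[0]
        if k < 1:
            raise ValueError("HMM needs at least one state")
        if trans.shape != (k, k):
            raise ValueError(f"transition must be ({k},{k}), got {trans.shape}")
        if len(rois) != k:
            raise ValueError(f"expected {k} ROIs, got {len(rois)}")
        if np.any(prior < -_PROB_TOL) or np.any(trans < -_PROB_TOL):
            raise ValueError("probabilities must be non-negative")
        if abs(prior.sum() - 1.0) > 1e-6:
            raise ValueError(f"prior must sum to 1, sums to {prior.sum()}")
        rowsums = trans.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            raise ValueError(f"transition rows must sum to 1, sums are {rowsums}")
        object.__setattr__(self, "prior", np.clip(prior, 0.0, None))
        object.__setattr__(self, "transition", np.clip(trans, 0.0, None))
        object.__setattr__(self, "rois", rois)

    @property
    def n_states(self) -> int:
        return self.prior.shape[0]

    @property
    def means(self) -> np.ndarray:
        """(K, 2) matrix of ROI means."""
        return np.array([r.mean for r in self.rois])

    @property
    def covariances(self) -> np.ndarray:
        """(K, 2, 2) stack of ROI covariances."""
        return np.array([r.covariance for r in self.rois])

    @classmethod
    def from_arrays(cls, prior: np.ndarray, transition: np.ndarray,
                    means: np.ndarray, covariances: np.ndarray) -> "Hmm":
        rois = tuple(GaussianRoi(m, c) for m, c in zip(means, covariances))
        return cls(prior=np.asarray(prior, float),
                   transition=np.asarray(transition, float), rois=rois)

    def permute(self, order: np.ndarray) -> "Hmm":
        """Relabel states by `order` (new state i is old state order[i])."""
        order = np.asarray(order)
        return Hmm(prior=self.prior[order],
                   transition=self.transition[np.ix_(order, order)],
                   rois=tuple(self.rois[i] for i in order))


@dataclass(frozen=True)
class HyperParams:
    """Conjugate prior hyperparameters for variational-Bayesian HMM estimation.

    Dirichlet priors on the initial-state vector (``alpha0``) and on each
    transition row (``epsilon0``); a Normal–Wishart prior on each ROI's Gaussian:
    mean ``m0`` with precision scale ``beta0``, and Wishart(``W0``, ``nu0``) on
    the precision matrix. ``W0`` should be scale-aware: its default is chosen so
    that the prior expected ROI standard deviation is about 1/16 of the stimulus
    diagonal.
    """

    alpha0: float = 1.0
    epsilon0: float = 1.0
    m0: np.ndarray = field(default_factory=lambda: np.array([400.0, 300.0]))
    beta0: float = 1.0
    W0: np.ndarray | None = None
    nu0: float = 5.0
    stimulus_size: tuple[float, float] = (800.0, 600.0)

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.epsilon0 <= 0 or self.beta0 <= 0:
            raise ValueError("concentrations and beta0 must be positive")
        if self.nu0 <= 1:
            raise ValueError("nu0 must exceed 1")
        object.__setattr__(self, "m0", np.asarray(self.m0, float).reshape(2))
        if self.W0 is not None:
            w0 = np.asarray(self.W0, float).reshape(2, 2)
            if np.any(np.linalg.eigvalsh(w0) <= 0):
                raise ValueError("W0 must be positive definite")
            object.__setattr__(self, "W0", w0)

    @classmethod
    def for_stimulus(cls, width: float, height: float, **kwargs) -> "HyperParams":
        """Scale-aware defaults: prior ROI mean at the stimulus centre, prior ROI
        spread ~ diagonal/16."""
        kwargs.setdefault("m0", np.array([width / 2.0, height / 2.0]))
        kwargs.setdefault("stimulus_size", (width, height))
        return cls(**kwargs)

    def effective_W0(self) -> np.ndarray:
        """W0, defaulting to ((D/16)² nu0)⁻¹ I so E[Λ] = nu0·W0 has prior
        standard deviation D/16 (D = stimulus diagonal)."""
        if self.W0 is not None:
            return self.W0
        w, h = self.stimulus_size
        diag = float(np.hypot(w, h))
        sd = diag / 16.0
        return np.eye(2) / (sd * sd * self.nu0)
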
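"""Shared fixtures: random model factories and small planted datasets."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from emhmm import Hmm


def random_hmm(K: int, rng: np.random.Generator, span: float = 500.0) -> Hmm:
    """A valid random HMM with anisotropic, correlated ROI covariances."""
    prior = rng.dirichlet(np.ones(K))
    trans = rng.dirichlet(np.ones(K), size=K)
    means = rng.uniform(0.0, span, size=(K, 2))
    covs = []
    for _ in range(K):
        sx, sy = rng.uniform(10.0, 50.0, size=2)
        rho = rng.uniform(-0.5, 0.5)
        covs.append(np.array([[sx * sx, rho * sx * sy],
                              [rho * sx * sy, sy * sy]]))
    return Hmm.from_arrays(prior, trans, means, np.array(covs))


def enumerate_loglik(hmm: Hmm, points: np.ndarray) -> float:
    """Brute-force marginal log-likelihood by summing over all state paths."""
    T = points.shape[0]
    K = hmm.n_states
    dens = np.array([[multivariate_normal.logpdf(points[t], hmm.rois[k].mean,
                                                 hmm.rois[k].covariance)
                      for k in range(K)] for t in range(T)])
    with np.errstate(divide="ignore"):
        log_pi = np.log(hmm.prior)
        log_a = np.log(hmm.transition)
    total = -np.inf
    for path in product(range(K), repeat=T):
        lp = log_pi[path[0]] + dens[0, path[0]]
        for t in range(1, T):
            lp += log_a[path[t - 1], path[t]] + dens[t, path[t]]
        total = np.logaddexp(total, lp)
    return float(total)


@pytest.fixture(scope="session")
def planted_truth():
    from emhmm import make_group_hmms
    return make_group_hmms(n_groups=2, n_stimuli=5, k_states=3,
                           separation=200.0, n_subjects_per_group=10, seed=11)


@pytest.fixture(scope="session")
def planted_grid(planted_truth):
    from emhmm import make_hmm_grid
    return make_hmm_grid(planted_truth, mean_jitter=10.0, seed=12)


@pytest.fixture(scope="session")
def planted_dataset(planted_truth):
    from emhmm import sample_dataset
    return sample_dataset(planted_truth, trials_per_stimulus=3,
                          length_distribution=13, seed=13)
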
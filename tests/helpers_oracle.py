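"""Independent oracles used by the test suite.

The joint-Gaussian oracle assembles the full 3T x 3T multivariate normal
implied by a linear-Gaussian Markov chain and evaluates its density with
scipy, independently of the chain-factorized likelihood it checks.
"""

import numpy as np
from scipy.stats import multivariate_normal


def joint_gaussian_loglik(model, values: np.ndarray) -> float:
    """Log-density of one cycle under the chain's implied joint Gaussian."""
    T = model.n_steps
    mean = np.zeros((T, 3))
    cov = np.zeros((T, 3, T, 3))
    mean[0] = model.mu1
    cov[0, :, 0, :] = model.S1
    for t in range(1, T):
        A = model.A[t - 1]
        mean[t] = A @ mean[t - 1] + model.b[t - 1]
        for s in range(t):
            cov[t, :, s, :] = A @ cov[t - 1, :, s, :]
            cov[s, :, t, :] = cov[t, :, s, :].T
        cov[t, :, t, :] = A @ cov[t - 1, :, t - 1, :] @ A.T + model.Q[t - 1]
    mvn = multivariate_normal(mean.reshape(-1), cov.reshape(3 * T, 3 * T))
    return float(mvn.logpdf(np.asarray(values, float).reshape(-1)))


def brute_force_kernel_smooth(t, v, sigma, query):
    """O(n*m) untruncated Nadaraya-Watson weighted sum."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    out = np.empty(len(query))
    for i, q in enumerate(np.asarray(query, float)):
        w = np.exp(-((t - q) ** 2) / (2.0 * sigma**2))
        out[i] = (w * v).sum() / w.sum()
    return out
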
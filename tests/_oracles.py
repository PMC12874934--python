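"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own sampling machinery: the
posterior mean of the intercept on a small two-level instance is obtained
by deterministic quadrature (Gauss-Hermite over each cluster effect, a
dense grid over the intercept), and the stationary acceptance rate of a
random-walk Metropolis kernel is obtained by numerical double integration.
"""

import numpy as np
from numpy.polynomial.hermite_e import hermegauss


def beta0_posterior_mean_grid(n_j, k_j, sigma2, lo=-6.0, hi=8.0, m=1401, gh_order=80):
    """Posterior mean of the intercept in a one-level random-intercept
    logistic model with known cluster variance and a flat intercept prior.

    Marginalises each cluster effect by Gauss-Hermite quadrature and
    integrates the intercept over a dense grid.
    """
    x, w = hermegauss(gh_order)  # integrates f(x) exp(-x^2/2) dx
    grid = np.linspace(lo, hi, m)
    logw = np.log(w / np.sqrt(2.0 * np.pi))
    logpost = np.zeros(m)
    for n, k in zip(n_j, k_j):
        eta = grid[:, None] + np.sqrt(sigma2) * x[None, :]
        ll = k * eta - n * np.logaddexp(0.0, eta)
        logpost += np.logaddexp.reduce(logw[None, :] + ll, axis=1)
    logpost -= logpost.max()
    dens = np.exp(logpost)
    return float(np.trapezoid(dens * grid, grid) / np.trapezoid(dens, grid))


def rw_metropolis_acceptance_normal(proposal_sd, span=8.0, m=801):
    """Stationary acceptance rate of random-walk Metropolis targeting
    N(0, 1), by brute-force double integration on a grid."""
    xs = np.linspace(-span, span, m)
    target = np.exp(-(xs**2) / 2.0) / np.sqrt(2.0 * np.pi)
    acc = np.empty(m)
    for i, x in enumerate(xs):
        q = np.exp(-((xs - x) ** 2) / (2.0 * proposal_sd**2)) / (
            proposal_sd * np.sqrt(2.0 * np.pi)
        )
        a = np.minimum(1.0, np.exp(-(xs**2 - x**2) / 2.0))
        acc[i] = np.trapezoid(q * a, xs)
    return float(np.trapezoid(target * acc, xs))
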
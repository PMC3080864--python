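"""Independent oracles used by the test suite.

The Bayes-factor oracle integrates the Gaussian likelihood ratio over the
effect size on a dense grid, using only generic multivariate-normal
densities — no code shared with the closed form it checks.
"""

import numpy as np
from scipy import stats


def numeric_log10_bf(y, z, sigma, tau, n_grid=40001, width=10.0):
    """Brute-force BF: trapezoid integration of N(y; b z, Sigma) N(b; 0, tau^2)
    over b on a +/- width*tau grid, divided by the null density."""
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    grid = np.linspace(-width * tau, width * tau, n_grid)
    inv = np.linalg.inv(sigma)
    sign, logdet = np.linalg.slogdet(sigma)
    assert sign > 0

    r = y[None, :] - grid[:, None] * z[None, :]          # (G, L) residuals
    quad = np.einsum("gi,ij,gj->g", r, inv, r)
    ll = -0.5 * quad - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi)
    ll0 = -0.5 * (y @ inv @ y) - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi)
    integrand = np.exp(ll) * stats.norm.pdf(grid, 0.0, tau)
    bf = np.trapezoid(integrand, grid) / np.exp(ll0)
    return np.log10(bf)


def random_bf_instance(rng, max_l=10):
    """A random small (L <= max_l) scan instance: y, z, PSD sigma, tau."""
    L = int(rng.integers(3, max_l + 1))
    a = rng.standard_normal((L, L))
    omega = a @ a.T / L + 0.5 * np.eye(L)
    d = rng.uniform(0.005, 0.1, L)
    sigma = omega + np.diag(d)
    y = rng.standard_normal(L)
    z = rng.standard_normal(L)
    z = (z - z.mean()) / z.std()
    tau = float(rng.uniform(0.2, 2.0))
    return y, z, omega, d, sigma, tau
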
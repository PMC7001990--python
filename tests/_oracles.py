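"""Independent brute-force oracles used to check package computations.

These deliberately avoid the code paths they verify: grid integration over
the simplex for mixing posteriors, double-loop sums of squares for the
variance decomposition, normal equations for OLS.
"""

from __future__ import annotations

import numpy as np

from nichemix.mixing_model import corrected_source_arrays


def _loglik(p: np.ndarray, mu: np.ndarray, var: np.ndarray,
            obs: np.ndarray, sigma: float) -> float:
    mean = p @ mu
    tot = (p**2) @ var + sigma**2
    out = 0.0
    for j in range(2):
        out += (
            -0.5 * obs.shape[0] * np.log(2 * np.pi * tot[j])
            - 0.5 * ((obs[:, j] - mean[j]) ** 2).sum() / tot[j]
        )
    return out


def grid_posterior_mean_k2(sources, tdf, obs, sigma, alpha, n_grid=2001):
    """Posterior mean of (p1, p2) by dense 1-D quadrature over the simplex."""
    _, mu, var = corrected_source_arrays(sources, tdf)
    p1 = np.linspace(1e-6, 1 - 1e-6, n_grid)
    lp = np.array(
        [
            (alpha[0] - 1) * np.log(q)
            + (alpha[1] - 1) * np.log(1 - q)
            + _loglik(np.array([q, 1 - q]), mu, var, obs, sigma)
            for q in p1
        ]
    )
    w = np.exp(lp - lp.max())
    w /= w.sum()
    return np.array([(w * p1).sum(), (w * (1 - p1)).sum()])


def grid_posterior_mean_k3(sources, tdf, obs, sigma, alpha, step=0.01):
    """Posterior mean over a triangular grid on the 3-simplex."""
    _, mu, var = corrected_source_arrays(sources, tdf)
    pts = []
    for a in np.arange(step / 2, 1, step):
        for b in np.arange(step / 2, 1 - a, step):
            c = 1 - a - b
            if c > 0:
                pts.append((a, b, c))
    grid = np.array(pts)
    log_prior = ((alpha - 1) * np.log(grid)).sum(axis=1)
    mean = grid @ mu  # (M, 2)
    tot = (grid**2) @ var + sigma**2
    n = obs.shape[0]
    ll = np.zeros(len(grid))
    for j in range(2):
        ss = ((obs[:, j] ** 2).sum()
              - 2 * mean[:, j] * obs[:, j].sum()
              + n * mean[:, j] ** 2)
        ll += -0.5 * n * np.log(2 * np.pi * tot[:, j]) - 0.5 * ss / tot[:, j]
    w = np.exp(log_prior + ll - (log_prior + ll).max())
    w /= w.sum()
    return (w[:, None] * grid).sum(axis=0)


def sum_of_squares_oracle(series_list):
    """WIC/BIC/TNW by explicit double loops over individuals and subsamples."""
    all_values = [x for v in series_list for x in v]
    grand = sum(all_values) / len(all_values)
    tnw = sum((x - grand) ** 2 for x in all_values)
    wic = 0.0
    bic = 0.0
    for v in series_list:
        m = sum(v) / len(v)
        for x in v:
            wic += (x - m) ** 2
        bic += len(v) * (m - grand) ** 2
    return wic, bic, tnw


def ols_oracle(x_matrix: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Regression coefficients by the normal equations."""
    xtx = x_matrix.T @ x_matrix
    return np.linalg.solve(xtx, x_matrix.T @ y)
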
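"""Independent oracles the test suite checks the package against.

Everything here is deliberately written from first principles — brute
force, quadrature, or a separately coded Gibbs sampler — and shares no code
with the implementation it validates.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite_e import hermegauss


def brute_force_hpdi(draws, prob):
    """Shortest window over sorted draws by exhaustive enumeration."""
    s = sorted(float(v) for v in draws)
    n = len(s)
    m = math.ceil(prob * n)
    best = None
    for i in range(n - m + 1):
        width = s[i + m - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + m - 1])
    return best[1], best[2]


def poisson_grid_posterior(
    y, levels, n_levels, ig_shape, ig_rate,
    beta_var=1e8, b0_grid=None, ls2_grid=None, n_quad=81,
):
    """Grid-integration posterior for the intercept + one-random-term
    Poisson log-link model.

    The per-level random effect is integrated out with Gauss-Hermite
    quadrature; the (beta0, log sigma2) plane is then summed over a dense
    grid. Returns posterior mean and SD of beta0 and sigma2.
    """
    y = np.asarray(y, dtype=float)
    levels = np.asarray(levels)
    if b0_grid is None:
        b0_grid = np.linspace(-2.0, 6.0, 201)
    if ls2_grid is None:
        ls2_grid = np.linspace(-8.0, 6.0, 241)
    Sy = np.array([y[levels == l].sum() for l in range(n_levels)])
    Nl = np.array([(levels == l).sum() for l in range(n_levels)])
    x, w = hermegauss(n_quad)
    B0, LS2 = np.meshgrid(b0_grid, ls2_grid, indexing="ij")
    S2 = np.exp(LS2)
    loglik = np.zeros_like(B0)
    for l in range(n_levels):
        u = np.sqrt(S2)[..., None] * x
        f = Sy[l] * (B0[..., None] + u) - Nl[l] * np.exp(
            np.clip(B0[..., None] + u, -700, 700)
        )
        fmax = f.max(axis=-1, keepdims=True)
        loglik += np.log((w * np.exp(f - fmax)).sum(axis=-1) / w.sum()) + fmax[..., 0]
    logw = (
        loglik
        - (ig_shape + 1.0) * np.log(S2)
        - ig_rate / S2
        - B0 ** 2 / (2.0 * beta_var)
        + LS2  # jacobian of the log-sigma2 grid
    )
    logw -= logw.max()
    W = np.exp(logw)
    W /= W.sum()
    mb0 = float((W * B0).sum())
    sb0 = float(np.sqrt((W * (B0 - mb0) ** 2).sum()))
    ms2 = float((W * S2).sum())
    ss2 = float(np.sqrt((W * (S2 - ms2) ** 2).sum()))
    # guard: negligible mass on the grid boundary, else moments are truncated
    edge = W[0, :].sum() + W[-1, :].sum() + W[:, 0].sum() + W[:, -1].sum()
    assert edge < 1e-3, f"oracle grid truncates posterior mass ({edge:.2e})"
    return {"beta0_mean": mb0, "beta0_sd": sb0, "sigma2_mean": ms2, "sigma2_sd": ss2}


def oneway_gaussian_gibbs(
    y, groups, n_groups, n_iter=30_000, burn=2_000, seed=77,
    nu=0.002, V=1.0, mu_var=1e8,
):
    """Conjugate Gibbs sampler for y_ij = mu + a_i + e_ij, coded
    independently of the package's engine. Returns variance draws."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups)
    n = y.size
    ng = np.bincount(g, minlength=n_groups).astype(float)
    mu = float(y.mean())
    a = np.zeros(n_groups)
    s2a = s2e = 1.0
    out_a, out_e = [], []
    for it in range(n_iter):
        r = y - a[g]
        prec = n / s2e + 1.0 / mu_var
        mu = rng.normal(r.sum() / s2e / prec, 1.0 / np.sqrt(prec))
        r = y - mu
        prec_a = ng / s2e + 1.0 / s2a
        mean_a = np.bincount(g, weights=r, minlength=n_groups) / s2e / prec_a
        a = rng.normal(mean_a, 1.0 / np.sqrt(prec_a))
        s2a = (nu * V / 2 + 0.5 * float(a @ a)) / rng.gamma(nu / 2 + n_groups / 2)
        e = y - mu - a[g]
        s2e = (nu * V / 2 + 0.5 * float(e @ e)) / rng.gamma(nu / 2 + n / 2)
        if it >= burn:
            out_a.append(s2a)
            out_e.append(s2e)
    return np.array(out_a), np.array(out_e)


def ar1_ess(n, rho):
    """Analytic effective sample size of an AR(1) chain."""
    return n * (1.0 - rho) / (1.0 + rho)


def batch_mcse(draws, n_batches=25):
    """Batch-means Monte Carlo standard error of the mean."""
    x = np.asarray(draws, dtype=float).ravel()
    b = len(x) // n_batches
    means = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
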
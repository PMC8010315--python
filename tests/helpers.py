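"""Independent oracles used by the test suite.

Everything here is deliberately written as a *separate* route from the package
implementation: dense grid quadrature for the robust-regression posterior,
closed-form normal-linear marginalization for the large-nu limit, explicit
loops for VIP and split-R-hat, and exhaustive partition search for K-means.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats
from scipy.special import gammaln


def grid_posterior_pooled(
    y: np.ndarray,
    x: np.ndarray,
    prior_beta_var: float = 10.0,
    nu_upper: float = 100.0,
    prec_shape: float = 1.0,
    prec_rate: float = 1.0,
    n_beta: int = 71,
    n_sigma: int = 45,
    n_nu: int = 40,
) -> dict[str, tuple[float, float]]:
    """Dense quadrature over (beta0, beta1, sigma^2, nu) of the robust model
    with the latent scale weights integrated out analytically (Student-t
    likelihood).  Returns posterior (mean, sd) per parameter."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    res_var = float(np.sum((y - X @ ols) ** 2) / max(n - 2, 1))
    XtX = X.T @ X
    se = np.sqrt(res_var * np.diag(np.linalg.inv(XtX)))

    b0g = np.linspace(ols[0] - 25 * se[0], ols[0] + 25 * se[0], n_beta)
    b1g = np.linspace(ols[1] - 25 * se[1], ols[1] + 25 * se[1], n_beta)
    s2g = np.geomspace(res_var / 60.0, res_var * 60.0, n_sigma)
    nug = np.geomspace(0.3, nu_upper, n_nu)

    def widths(g):
        w = np.empty_like(g)
        w[1:-1] = 0.5 * (g[2:] - g[:-2])
        w[0] = g[1] - g[0]
        w[-1] = g[-1] - g[-2]
        return w

    wb0, wb1, ws2, wnu = widths(b0g), widths(b1g), widths(s2g), widths(nug)

    B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
    M = B0[..., None] + B1[..., None] * x[None, None, :]  # (nb, nb, n)

    # accumulate weighted moments over the (sigma2, nu) outer loop
    tot = 0.0
    sums = {k: 0.0 for k in ("b0", "b1", "b0sq", "b1sq", "s2", "nu")}
    log_prior_beta = (
        stats.norm.logpdf(B0, 0.0, np.sqrt(prior_beta_var))
        + stats.norm.logpdf(B1, 0.0, np.sqrt(prior_beta_var))
    )
    chunks = []
    for i2, s2 in enumerate(s2g):
        sig = np.sqrt(s2)
        # inverse-gamma prior on sigma^2 from Gamma(shape, rate) on precision
        lp_s2 = (prec_shape * np.log(prec_rate) - gammaln(prec_shape)
                 - (prec_shape + 1) * np.log(s2) - prec_rate / s2)
        for i3, nu in enumerate(nug):
            ll = stats.t.logpdf((y[None, None, :] - M) / sig, df=nu).sum(axis=-1) \
                - n * np.log(sig)
            logw = ll + log_prior_beta + lp_s2
            chunks.append((i2, i3, logw))
    max_log = max(c[2].max() for c in chunks)
    for i2, i3, logw in chunks:
        w = np.exp(logw - max_log) * wb0[:, None] * wb1[None, :] * ws2[i2] * wnu[i3]
        s = w.sum()
        tot += s
        sums["b0"] += (w * B0).sum()
        sums["b1"] += (w * B1).sum()
        sums["b0sq"] += (w * B0**2).sum()
        sums["b1sq"] += (w * B1**2).sum()
        sums["s2"] += s * s2g[i2]
        sums["nu"] += s * nug[i3]
    m0, m1 = sums["b0"] / tot, sums["b1"] / tot
    return {
        "beta0": (m0, float(np.sqrt(sums["b0sq"] / tot - m0**2))),
        "beta_ssc": (m1, float(np.sqrt(sums["b1sq"] / tot - m1**2))),
        "sigma_sq": (sums["s2"] / tot, np.nan),
        "nu": (sums["nu"] / tot, np.nan),
    }


def normal_limit_posterior(
    y: np.ndarray,
    x: np.ndarray,
    prior_beta_var: float = 10.0,
    prec_shape: float = 1.0,
    prec_rate: float = 1.0,
    n_sigma: int = 4000,
) -> dict[str, float]:
    """Closed-form conjugate normal-linear posterior for (beta0, beta1),
    marginalized over sigma^2 by 1-D quadrature of the exact marginal
    likelihood N(y | 0, sigma^2 I + V0 X X')."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    X = np.column_stack([np.ones(n), x])
    V0 = prior_beta_var * np.eye(2)
    res_var = float(np.var(y - X @ np.linalg.lstsq(X, y, rcond=None)[0]))
    s2g = np.geomspace(max(res_var, 1e-8) / 200.0, res_var * 200.0, n_sigma)

    logws = np.empty(n_sigma)
    means = np.empty((n_sigma, 2))
    covs = np.empty((n_sigma, 2, 2))
    for i, s2 in enumerate(s2g):
        cov_y = s2 * np.eye(n) + X @ V0 @ X.T
        logws[i] = stats.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov_y)
        logws[i] += (prec_shape * np.log(prec_rate) - gammaln(prec_shape)
                     - (prec_shape + 1) * np.log(s2) - prec_rate / s2)
        A = X.T @ X / s2 + np.linalg.inv(V0)
        C = np.linalg.inv(A)
        means[i] = C @ (X.T @ y / s2)
        covs[i] = C
    # log-trapezoid weights over the sigma^2 grid
    dg = np.empty_like(s2g)
    dg[1:-1] = 0.5 * (s2g[2:] - s2g[:-2])
    dg[0], dg[-1] = s2g[1] - s2g[0], s2g[-1] - s2g[-2]
    w = np.exp(logws - logws.max()) * dg
    w /= w.sum()
    mean = (w[:, None] * means).sum(axis=0)
    second = (w[:, None, None] * (covs + np.einsum("ij,ik->ijk", means, means))).sum(axis=0)
    cov = second - np.outer(mean, mean)
    return {"beta0_mean": mean[0], "beta_ssc_mean": mean[1],
            "beta0_sd": float(np.sqrt(cov[0, 0])),
            "beta_ssc_sd": float(np.sqrt(cov[1, 1]))}


def vip_reference(weights, x_scores, y_loadings) -> np.ndarray:
    """VIP by an explicit loop over components (independent of the package)."""
    W = np.asarray(weights, float)
    T = np.asarray(x_scores, float)
    q = np.asarray(y_loadings, float)
    p, A = W.shape
    ssy = np.array([q[a] ** 2 * T[:, a] @ T[:, a] for a in range(A)])
    out = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for a in range(A):
            wnorm = np.linalg.norm(W[:, a])
            acc += ssy[a] * (W[j, a] / wnorm) ** 2
        out[j] = np.sqrt(p * acc / ssy.sum())
    return out


def split_rhat_reference(draws: np.ndarray) -> float:
    """Split-R-hat by direct evaluation of the variance formula."""
    c, d = draws.shape
    L = d // 2
    halves = [draws[i, :L] for i in range(c)] + [draws[i, L:2 * L] for i in range(c)]
    means = np.array([h.mean() for h in halves])
    W = float(np.mean([h.var(ddof=1) for h in halves]))
    B = L * float(np.var(means, ddof=1))
    var_plus = (L - 1) / L * W + B / L
    return float(np.sqrt(var_plus / W))


def brute_force_kmeans(points: np.ndarray, k: int = 2) -> float:
    """Minimal within-cluster sum of squares over all k-partitions (k=2 only,
    exhaustive over 2^(n-1) assignments)."""
    assert k == 2
    pts = np.asarray(points, float)
    n = pts.shape[0]
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        lab = np.array((0,) + bits)
        if lab.min() == lab.max():
            continue
        wcss = 0.0
        for c in (0, 1):
            sub = pts[lab == c]
            wcss += ((sub - sub.mean(axis=0)) ** 2).sum()
        best = min(best, wcss)
    return float(best)


def mc_se(draws_2d: np.ndarray) -> float:
    """Monte-Carlo standard error of a posterior mean via arviz ESS."""
    import arviz as az

    ess = float(az.ess(np.asarray(draws_2d)))
    return float(draws_2d.std(ddof=1) / np.sqrt(max(ess, 1.0)))
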
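"""Gibbs samplers for the robust soluble-solids -> sweetness regression.

Two models are implemented, and only these two.

Pooled robust regression (Student-t errors as a scale mixture of normals)::

    y_i ~ Normal(beta0 + beta_ssc * x_i,  sigma^2 / tau_i)
    tau_i ~ Gamma(nu/2, rate=nu/2)
    beta0, beta_ssc ~ Normal(0, variance=10)
    nu ~ Uniform(0, 100)
    1/sigma^2 ~ Gamma(1, rate=1)

Marginalizing tau_i yields Student-t(nu) residuals; observations with large
residuals receive posterior weights tau_i < 1 and are automatically
down-weighted, which is what makes the slope estimate robust to the handful
of aberrant panel/refractometer samples every season produces.

Hierarchical extension: the slope varies by harvest month j,

    y_ij ~ Normal(beta0 + beta_j * x_ij, sigma^2 / tau_ij)
    beta_j ~ Normal(mu, sigma1^2),   mu ~ Normal(0, 10),
    1/sigma1^2 ~ Gamma(1, rate=1)

with beta0, sigma^2 and nu shared across months.  Partial pooling shrinks
poorly observed months toward the population slope mu.

All conditionals are conjugate except nu, which is updated by slice sampling
(step-out + shrink) of

    log p(nu | tau) = n * [ (nu/2) log(nu/2) - logGamma(nu/2) ]
                      + (nu/2) * sum_i (log tau_i - tau_i)      on (0, upper)

with an evaluated-grid inverse-CDF fallback behind ``ModelSpec.nu_sampler``.
Fixed seed => bit-identical draws.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RegressionData:
    """Response (sweetness), predictor (SSC %), and optional month index."""

    y: np.ndarray
    x: np.ndarray
    month: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.month is not None:
            self.month = np.asarray(self.month, dtype=int)
        if self.y.shape != self.x.shape or self.y.ndim != 1:
            raise ValidationError("y and x must be 1-D vectors of equal length")
        if np.isnan(self.y).any() or np.isnan(self.x).any():
            raise ValidationError("y and x must not contain missing values")
        if self.n < 3:
            raise ValidationError("need at least 3 observations")
        if self.month is not None and self.month.shape != self.y.shape:
            raise ValidationError("month must align with y")

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class ModelSpec:
    """Sampler configuration; priors default to the weakly informative set
    N(0, 10) on location parameters, Uniform(0, 100) on nu, Gamma(1, 1) on
    precisions."""

    kind: str = "pooled"  # pooled | hierarchical
    prior_beta_variance: float = 10.0
    prior_nu_upper: float = 100.0
    prior_precision_shape: float = 1.0
    prior_precision_rate: float = 1.0
    n_chains: int = 3
    n_iterations: int = 20_000  # total per chain, including burn-in
    n_burnin: int = 5_000
    seed: int = 0
    fix_nu: float | None = None  # fix nu instead of sampling (normal limit checks)
    nu_sampler: str = "slice"  # slice | grid

    def validate(self) -> None:
        if self.kind not in ("pooled", "hierarchical"):
            raise ConfigError(f"unknown model kind {self.kind!r}")
        for name in ("prior_beta_variance", "prior_nu_upper",
                     "prior_precision_shape", "prior_precision_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ConfigError("need n_iterations > n_burnin >= 0")
        if self.n_chains < 1:
            raise ConfigError("n_chains must be >= 1")
        if self.nu_sampler not in ("slice", "grid"):
            raise ConfigError(f"unknown nu_sampler {self.nu_sampler!r}")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (n_chains, n_draws[, ...])."""

    kind: str
    beta0: np.ndarray
    sigma_sq: np.ndarray
    nu: np.ndarray
    tau: np.ndarray  # (chains, draws, n_obs)
    beta_ssc: np.ndarray | None = None  # pooled
    beta_month: np.ndarray | None = None  # (chains, draws, J) hierarchical
    mu: np.ndarray | None = None
    sigma1_sq: np.ndarray | None = None
    months: np.ndarray | None = None  # month value per slope column
    spec: ModelSpec | None = None

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta0.shape[1]

    def scalar_params(self) -> dict[str, np.ndarray]:
        """Named scalar draws, (chains, draws) each; slopes expanded per month."""
        out = {"beta0": self.beta0, "sigma_sq": self.sigma_sq, "nu": self.nu}
        if self.kind == "pooled":
            out["beta_ssc"] = self.beta_ssc
        else:
            for j, m in enumerate(self.months):
                out[f"beta_month[{int(m)}]"] = self.beta_month[:, :, j]
            out["mu"] = self.mu
            out["sigma1_sq"] = self.sigma1_sq
        return out

    def slope_draws(self, x_month: np.ndarray | None = None) -> np.ndarray:
        """Flattened slope draws; for hierarchical fits, per-observation slopes
        require the month vector ``x_month``."""
        if self.kind == "pooled":
            return self.beta_ssc.reshape(-1)
        if x_month is None:
            raise ValidationError("hierarchical slope draws need the month vector")
        idx = np.searchsorted(self.months, x_month)
        return self.beta_month.reshape(-1, self.beta_month.shape[-1])[:, idx]

    def to_long_frame(self) -> pd.DataFrame:
        """Scalar draws in long format (chain, iteration, parameter, value).

        Per-observation tau draws are deliberately not included (their
        posterior means are exported via :func:`summarize`)."""
        frames = []
        for name, arr in self.scalar_params().items():
            c, d = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]),
                               indexing="ij")
            frames.append(pd.DataFrame({
                "chain": c.ravel(), "iteration": d.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "PosteriorDraws":
        """Rebuild (scalar-only) draws from the long-format export; tau is
        restored as ones since it is not persisted."""
        names = df["parameter"].unique().tolist()
        arrays = {}
        for name in names:
            sub = df[df["parameter"] == name]
            piv = sub.pivot(index="chain", columns="iteration", values="value")
            arrays[name] = piv.to_numpy()
        kind = "pooled" if "beta_ssc" in arrays else "hierarchical"
        shape = arrays["beta0"].shape
        tau = np.ones(shape + (1,))
        if kind == "pooled":
            return cls(kind=kind, beta0=arrays["beta0"], sigma_sq=arrays["sigma_sq"],
                       nu=arrays["nu"], tau=tau, beta_ssc=arrays["beta_ssc"])
        months = sorted(int(n.split("[")[1].rstrip("]"))
                        for n in names if n.startswith("beta_month["))
        bm = np.stack([arrays[f"beta_month[{m}]"] for m in months], axis=-1)
        return cls(kind=kind, beta0=arrays["beta0"], sigma_sq=arrays["sigma_sq"],
                   nu=arrays["nu"], tau=tau, beta_month=bm, mu=arrays["mu"],
                   sigma1_sq=arrays["sigma1_sq"], months=np.array(months))


# -- nu update -------------------------------------------------------------


def _nu_logpost(nu, n, s):
    """log p(nu | tau) up to a constant; s = sum(log tau - tau)."""
    h = 0.5 * nu
    return n * (h * np.log(h) - gammaln(h)) + h * s


_NU_LO = 1e-2


def _slice_sample_nu(rng, nu, n, s, upper, width=2.0, max_step=50):
    logp0 = _nu_logpost(nu, n, s)
    level = logp0 + np.log(rng.random())
    lo = max(nu - width * rng.random(), _NU_LO)
    hi = min(lo + width, upper)
    for _ in range(max_step):  # step out
        if lo <= _NU_LO or _nu_logpost(lo, n, s) < level:
            break
        lo = max(lo - width, _NU_LO)
    for _ in range(max_step):
        if hi >= upper or _nu_logpost(hi, n, s) < level:
            break
        hi = min(hi + width, upper)
    for _ in range(100):  # shrink
        prop = lo + (hi - lo) * rng.random()
        if _nu_logpost(prop, n, s) >= level:
            return prop
        if prop < nu:
            lo = prop
        else:
            hi = prop
    return nu  # pathological slice; keep current value


def _grid_sample_nu(rng, n, s, upper, n_grid=2000):
    grid = np.geomspace(0.1, upper, n_grid)
    logp = _nu_logpost(grid, n, s)
    logp -= logp.max()
    w = np.exp(logp)
    # trapezoid cell masses on the log-spaced grid
    dg = np.diff(grid)
    cell = 0.5 * (w[1:] + w[:-1]) * dg
    cdf = np.cumsum(cell)
    cdf /= cdf[-1]
    u = rng.random()
    k = int(np.searchsorted(cdf, u))
    left = cdf[k - 1] if k > 0 else 0.0
    frac = (u - left) / max(cdf[k] - left, 1e-300)
    return grid[k] + frac * dg[k]


# -- samplers --------------------------------------------------------------


def _chain_seed(seed: int, chain: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), chain])


def fit_pooled(data: RegressionData, spec: ModelSpec) -> PosteriorDraws:
    """Sample the pooled robust-regression posterior by Gibbs."""
    spec.validate()
    if spec.kind != "pooled":
        raise ConfigError("spec.kind must be 'pooled'")
    x, y, n = data.x, data.y, data.n
    if np.ptp(x) == 0:
        raise ValidationError("x is constant: SSC slope is unidentifiable")

    v0 = spec.prior_beta_variance
    a0, b0 = spec.prior_precision_shape, spec.prior_precision_rate
    n_keep = spec.n_iterations - spec.n_burnin
    C = spec.n_chains

    beta0_d = np.empty((C, n_keep))
    beta1_d = np.empty((C, n_keep))
    sig2_d = np.empty((C, n_keep))
    nu_d = np.empty((C, n_keep))
    tau_d = np.empty((C, n_keep, n))

    X = np.column_stack([np.ones(n), x])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]

    for c in range(C):
        rng = _chain_seed(spec.seed, c)
        b0c, b1c = ols + 0.1 * rng.standard_normal(2)
        resid = y - (b0c + b1c * x)
        sig2 = max(float(np.var(resid)), 1e-6)
        nu = spec.fix_nu if spec.fix_nu is not None else 10.0
        tau = np.ones(n)

        for it in range(spec.n_iterations):
            # tau_i | . ~ Gamma((nu+1)/2, rate=(nu + r_i^2/sigma^2)/2)
            resid = y - (b0c + b1c * x)
            rate = 0.5 * (nu + resid**2 / sig2)
            tau = rng.gamma(0.5 * (nu + 1.0), 1.0 / rate)

            # (beta0, beta_ssc) | . : conjugate bivariate normal
            w = tau / sig2
            sw, swx, swxx = w.sum(), (w * x).sum(), (w * x * x).sum()
            A = np.array([[sw + 1.0 / v0, swx], [swx, swxx + 1.0 / v0]])
            b = np.array([(w * y).sum(), (w * x * y).sum()])
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError as exc:
                raise ArithmeticError(
                    f"non-positive-definite slope update at iteration {it}"
                ) from exc
            mean = np.linalg.solve(A, b)
            z = rng.standard_normal(2)
            b0c, b1c = mean + np.linalg.solve(L.T, z)

            # 1/sigma^2 | .
            resid = y - (b0c + b1c * x)
            prec = rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * (tau * resid**2).sum()))
            sig2 = 1.0 / prec

            # nu | tau
            if spec.fix_nu is None:
                s = float(np.log(tau).sum() - tau.sum())
                if spec.nu_sampler == "slice":
                    nu = _slice_sample_nu(rng, nu, n, s, spec.prior_nu_upper)
                else:
                    nu = _grid_sample_nu(rng, n, s, spec.prior_nu_upper)

            if it >= spec.n_burnin:
                k = it - spec.n_burnin
                beta0_d[c, k] = b0c
                beta1_d[c, k] = b1c
                sig2_d[c, k] = sig2
                nu_d[c, k] = nu
                tau_d[c, k] = tau

    return PosteriorDraws(kind="pooled", beta0=beta0_d, beta_ssc=beta1_d,
                          sigma_sq=sig2_d, nu=nu_d, tau=tau_d, spec=spec)


def fit_hierarchical(data: RegressionData, spec: ModelSpec) -> PosteriorDraws:
    """Sample the varying-slope (per-month) posterior by Gibbs."""
    spec.validate()
    if spec.kind != "hierarchical":
        raise ConfigError("spec.kind must be 'hierarchical'")
    if data.month is None:
        raise ValidationError("hierarchical fit requires per-observation months")
    months, codes = np.unique(data.month, return_inverse=True)
    J = months.size
    if J < 2:
        raise ValidationError("need >= 2 distinct months for a hierarchical fit")
    counts = np.bincount(codes, minlength=J)
    for m, cnt in zip(months, counts):
        if cnt < 3:
            raise ValidationError(f"month {int(m)} has only {int(cnt)} observations (< 3)")

    x, y, n = data.x, data.y, data.n
    v0 = spec.prior_beta_variance
    a0, b0 = spec.prior_precision_shape, spec.prior_precision_rate
    n_keep = spec.n_iterations - spec.n_burnin
    C = spec.n_chains

    beta0_d = np.empty((C, n_keep))
    betaj_d = np.empty((C, n_keep, J))
    mu_d = np.empty((C, n_keep))
    sig2_d = np.empty((C, n_keep))
    sig1_d = np.empty((C, n_keep))
    nu_d = np.empty((C, n_keep))
    tau_d = np.empty((C, n_keep, n))

    X = np.column_stack([np.ones(n), x])
    ols = np.linalg.lstsq(X, y, rcond=None)[0]

    for c in range(C):
        rng = _chain_seed(spec.seed, c)
        b0c = ols[0] + 0.1 * rng.standard_normal()
        bj = np.full(J, ols[1]) + 0.05 * rng.standard_normal(J)
        mu = float(ols[1])
        sig2 = max(float(np.var(y - X @ ols)), 1e-6)
        sig1 = 0.01
        nu = spec.fix_nu if spec.fix_nu is not None else 10.0

        for it in range(spec.n_iterations):
            resid = y - (b0c + bj[codes] * x)
            rate = 0.5 * (nu + resid**2 / sig2)
            tau = rng.gamma(0.5 * (nu + 1.0), 1.0 / rate)
            w = tau / sig2

            # beta0 | .
            prec0 = w.sum() + 1.0 / v0
            m0 = (w * (y - bj[codes] * x)).sum() / prec0
            b0c = m0 + rng.standard_normal() / np.sqrt(prec0)

            # beta_j | . (independent across months given the rest)
            r0 = y - b0c
            sxx = np.bincount(codes, weights=w * x * x, minlength=J)
            sxy = np.bincount(codes, weights=w * x * r0, minlength=J)
            prec_j = sxx + 1.0 / sig1
            mean_j = (sxy + mu / sig1) / prec_j
            bj = mean_j + rng.standard_normal(J) / np.sqrt(prec_j)

            # mu | beta_j
            prec_mu = J / sig1 + 1.0 / v0
            mu = bj.sum() / sig1 / prec_mu + rng.standard_normal() / np.sqrt(prec_mu)

            # 1/sigma1^2 | beta_j, mu
            sig1 = 1.0 / rng.gamma(a0 + 0.5 * J,
                                   1.0 / (b0 + 0.5 * ((bj - mu) ** 2).sum()))

            # 1/sigma^2 | .
            resid = y - (b0c + bj[codes] * x)
            sig2 = 1.0 / rng.gamma(a0 + 0.5 * n,
                                   1.0 / (b0 + 0.5 * (tau * resid**2).sum()))

            if spec.fix_nu is None:
                s = float(np.log(tau).sum() - tau.sum())
                if spec.nu_sampler == "slice":
                    nu = _slice_sample_nu(rng, nu, n, s, spec.prior_nu_upper)
                else:
                    nu = _grid_sample_nu(rng, n, s, spec.prior_nu_upper)

            if it >= spec.n_burnin:
                k = it - spec.n_burnin
                beta0_d[c, k] = b0c
                betaj_d[c, k] = bj
                mu_d[c, k] = mu
                sig2_d[c, k] = sig2
                sig1_d[c, k] = sig1
                nu_d[c, k] = nu
                tau_d[c, k] = tau

    return PosteriorDraws(kind="hierarchical", beta0=beta0_d, beta_month=betaj_d,
                          mu=mu_d, sigma_sq=sig2_d, sigma1_sq=sig1_d, nu=nu_d,
                          tau=tau_d, months=months, spec=spec)


# -- diagnostics & summaries ------------------------------------------------


def split_rhat(draws: np.ndarray) -> float:
    """Split potential-scale-reduction factor for one scalar parameter.

    Each chain is split in half; with m half-sequences of length L,
    within-variance W = mean of half variances, between-variance
    B = L * var(half means), and

        R-hat = sqrt( ((L-1)/L * W + B/L) / W ).
    """
    c, d = draws.shape
    L = d // 2
    halves = draws[:, :2 * L].reshape(c * 2, L)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean()
    B = L * means.var(ddof=1)
    if W <= 0:
        return 1.0  # degenerate constant chains
    var_plus = (L - 1) / L * W + B / L
    return float(np.sqrt(var_plus / W))


@dataclass
class FitSummary:
    """Posterior summaries, convergence diagnostics and per-observation
    predictive checks."""

    params: pd.DataFrame  # parameter, mean, sd, q2.5, q97.5, rhat
    avg_rhat: float | None
    predictive: pd.DataFrame  # lower, upper, observed, covered, tau_mean
    n_covered: int
    n_outliers: int  # posterior-mean tau < 1

    @property
    def coverage(self) -> float:
        return self.n_covered / len(self.predictive)


def summarize(draws: PosteriorDraws, data: RegressionData,
              seed: int = 0, interval: float = 0.95) -> FitSummary:
    """Posterior means/SDs/95% intervals, split-R-hat, 95% posterior-predictive
    intervals per observation (one predictive replicate per retained draw),
    coverage count and tau-outlier count."""
    rng = np.random.default_rng(int(seed) % (2**31) + 7)
    scalars = draws.scalar_params()
    single_chain = draws.n_chains < 2
    if single_chain:
        warnings.warn("R-hat requires >= 2 chains; reporting R-hat as absent",
                      stacklevel=2)

    rows = []
    for name, arr in scalars.items():
        flat = arr.reshape(-1)
        rows.append({
            "parameter": name,
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)),
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
            "rhat": np.nan if single_chain else split_rhat(arr),
        })
    params = pd.DataFrame(rows)
    avg_rhat = None if single_chain else float(params["rhat"].mean())

    # posterior-predictive replicates: y*_i = m_i + sqrt(sig2/tau*) z per draw
    beta0 = draws.beta0.reshape(-1)
    sig2 = draws.sigma_sq.reshape(-1)
    nu = draws.nu.reshape(-1)
    D = beta0.size
    if draws.kind == "pooled":
        slope = draws.beta_ssc.reshape(-1)[:, None]  # (D, 1)
    else:
        slope = draws.slope_draws(data.month)  # (D, n)
    m = beta0[:, None] + slope * data.x[None, :]  # (D, n)
    tau_star = rng.gamma(nu / 2.0, 2.0 / nu)[:, None]
    yrep = m + np.sqrt(sig2[:, None] / tau_star) * rng.standard_normal(m.shape)
    alpha = (1.0 - interval) / 2.0
    lower = np.quantile(yrep, alpha, axis=0)
    upper = np.quantile(yrep, 1.0 - alpha, axis=0)
    covered = (data.y >= lower) & (data.y <= upper)

    tau_mean = draws.tau.reshape(-1, draws.tau.shape[-1]).mean(axis=0)
    if tau_mean.size != data.n:  # draws restored from disk lack tau
        tau_mean = np.full(data.n, np.nan)
    predictive = pd.DataFrame({
        "lower": lower, "upper": upper, "observed": data.y,
        "covered": covered, "tau_mean": tau_mean,
    })
    n_outliers = int(np.nansum(tau_mean < 1.0)) if np.isfinite(tau_mean).any() else 0
    logger.info("coverage %d/%d, %d tau-outliers", int(covered.sum()), data.n, n_outliers)
    return FitSummary(params=params, avg_rhat=avg_rhat, predictive=predictive,
                      n_covered=int(covered.sum()), n_outliers=n_outliers)
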
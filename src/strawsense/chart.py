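"""Probabilistic SSC -> sweetness chart from pooled posterior draws.

For each SSC value on a grid, the chart reports the posterior-predictive
probability that a new sample's panel-mean sweetness exceeds three cutoffs
derived from the observed sweetness distribution: its mean ("above average")
and its 80th/90th percentiles ("top 20%" / "top 10%").  Per retained draw the
predictive is Student-t: marginalizing the latent weight tau* ~ Gamma(nu/2,
nu/2) out of Normal(beta0 + beta_ssc*x, sigma^2/tau*) gives a t(nu) density
with location beta0 + beta_ssc*x and scale sigma, so the exceedance mass is a
closed-form t tail probability, averaged over draws.  A deterministic
least-squares line is carried alongside for comparison: its crossing of the
"above average" cutoff is the classical single-threshold rule the
probabilistic chart replaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import PosteriorDraws
from .errors import ConfigError, ValidationError

THRESHOLD_ORDER = ("above_average", "top20", "top10")


@dataclass
class ProbabilityChart:
    ssc_grid: np.ndarray
    thresholds: dict[str, float]  # name -> sweetness cutoff
    threshold_provenance: dict[str, str]
    probabilities: pd.DataFrame  # columns = threshold names, index = grid
    ols_crossings: dict[str, float]
    ols_coef: tuple[float, float] = (np.nan, np.nan)  # (intercept, slope)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        P = self.probabilities[list(THRESHOLD_ORDER)].to_numpy()
        if ((P < -atol) | (P > 1 + atol)).any():
            raise ValidationError("probabilities must lie in [0, 1]")
        if (np.diff(P, axis=0) < -atol).any():
            raise ValidationError("probabilities must be non-decreasing in SSC")
        cuts = [self.thresholds[t] for t in THRESHOLD_ORDER]
        if cuts == sorted(cuts):  # ordered cutoffs => ordered tail masses
            if ((P[:, 0] + atol < P[:, 1]) | (P[:, 1] + atol < P[:, 2])).any():
                raise ValidationError("threshold ordering violated")

    def to_frame(self) -> pd.DataFrame:
        df = self.probabilities.copy()
        df.insert(0, "ssc", self.ssc_grid)
        return df.reset_index(drop=True)


def make_chart(
    draws: PosteriorDraws,
    observed_sweetness: np.ndarray,
    observed_ssc: np.ndarray,
    grid: np.ndarray | None = None,
) -> ProbabilityChart:
    """Build the probability chart from pooled-model draws.

    ``grid`` defaults to 6.0-12.0 % SSC in steps of 0.5.  A grid extending
    beyond the observed SSC range triggers an extrapolation warning, not an
    error."""
    if draws.kind != "pooled":
        raise ConfigError("chart requires pooled-model draws")
    obs = np.asarray(observed_sweetness, dtype=float)
    if obs.size == 0:
        raise ValidationError("observed sweetness must be non-empty")
    xs = np.asarray(observed_ssc, dtype=float)
    grid = np.arange(6.0, 12.0 + 1e-9, 0.5) if grid is None else np.asarray(grid, float)
    if grid[0] < xs.min() - 1e-9 or grid[-1] > xs.max() + 1e-9:
        warnings.warn(
            f"SSC grid [{grid[0]:g}, {grid[-1]:g}] extends beyond the data support "
            f"[{xs.min():.2f}, {xs.max():.2f}]; chart tails are extrapolations",
            stacklevel=2,
        )

    thresholds = {
        "above_average": float(obs.mean()),
        "top20": float(np.quantile(obs, 0.80)),
        "top10": float(np.quantile(obs, 0.90)),
    }
    provenance = {
        "above_average": "empirical mean of observed sweetness",
        "top20": "80th percentile of observed sweetness",
        "top10": "90th percentile of observed sweetness",
    }

    b0 = draws.beta0.reshape(-1)
    b1 = draws.beta_ssc.reshape(-1)
    sig = np.sqrt(draws.sigma_sq.reshape(-1))
    nu = draws.nu.reshape(-1)

    cols = {}
    for name in THRESHOLD_ORDER:
        c = thresholds[name]
        # closed-form t tail mass per draw, averaged over the posterior
        p = np.empty(grid.size)
        for i, x in enumerate(grid):
            m = b0 + b1 * x
            p[i] = stats.t.sf((c - m) / sig, df=nu).mean()
        cols[name] = p
    probabilities = pd.DataFrame(cols)

    slope, intercept = np.polyfit(xs, obs, 1)
    ols_crossings = {
        name: float((thresholds[name] - intercept) / slope) if slope != 0 else np.nan
        for name in THRESHOLD_ORDER
    }
    return ProbabilityChart(
        ssc_grid=grid, thresholds=thresholds, threshold_provenance=provenance,
        probabilities=probabilities, ols_crossings=ols_crossings,
        ols_coef=(float(intercept), float(slope)),
    )


def exceedance_by_simulation(
    draws: PosteriorDraws, cutoff: float, x: float,
    n_rep_per_draw: int = 1, seed: int = 0,
) -> float:
    """Monte-Carlo exceedance probability via per-draw tau* simulation.

    Kept as the independent route against the closed-form t tail used by
    :func:`make_chart` (one replicate per draw by default)."""
    rng = np.random.default_rng(int(seed) % (2**31))
    b0 = draws.beta0.reshape(-1)
    b1 = draws.beta_ssc.reshape(-1)
    sig2 = draws.sigma_sq.reshape(-1)
    nu = draws.nu.reshape(-1)
    total = 0
    count = 0
    for _ in range(n_rep_per_draw):
        tau = rng.gamma(nu / 2.0, 2.0 / nu)
        y = b0 + b1 * x + np.sqrt(sig2 / tau) * rng.standard_normal(b0.size)
        total += int((y > cutoff).sum())
        count += b0.size
    return total / count


def threshold_ssc(chart: ProbabilityChart, threshold: str, confidence: float) -> float:
    """Smallest SSC (linear interpolation between grid points) whose exceedance
    probability reaches ``confidence`` for the named threshold.

    Returns NaN (with a warning stating the maximum attained probability) when
    the confidence is unreachable on the grid."""
    if not 0.0 <= confidence < 1.0:
        raise ConfigError("confidence must be in [0, 1)")
    if threshold not in chart.thresholds:
        raise ConfigError(
            f"unknown threshold {threshold!r}; valid: {list(chart.thresholds)}")
    p = chart.probabilities[threshold].to_numpy()
    grid = chart.ssc_grid
    if confidence <= p[0]:
        return float(grid[0])
    idx = np.nonzero(p >= confidence)[0]
    if idx.size == 0:
        warnings.warn(
            f"confidence {confidence:g} unreachable on grid; maximum attained "
            f"probability is {p.max():.3f} at SSC {grid[-1]:g}",
            stacklevel=2,
        )
        return float("nan")
    k = int(idx[0])
    # interpolate between (k-1, k); p is non-decreasing and p[k-1] < confidence
    frac = (confidence - p[k - 1]) / (p[k] - p[k - 1])
    return float(grid[k - 1] + frac * (grid[k] - grid[k - 1]))
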
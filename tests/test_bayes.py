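"""Gibbs-sampler behavior: determinism, exchangeability, outlier weighting,
diagnostics, and the hierarchical pooling limits."""

import numpy as np
import pandas as pd
import pytest

import strawsense as ss
from strawsense.errors import ConfigError, ValidationError
from tests.helpers import split_rhat_reference


def _tiny_data(tiny):
    ds, _ = tiny
    rf = ds.regression_frame()
    return ss.RegressionData(y=rf["y"].to_numpy(), x=rf["x"].to_numpy())


SMALL = dict(n_chains=2, n_iterations=2500, n_burnin=800)


def test_chain_level_determinism(tiny):
    data = _tiny_data(tiny)
    spec = ss.ModelSpec(kind="pooled", seed=9, **SMALL)
    a = ss.fit_pooled(data, spec)
    b = ss.fit_pooled(data, ss.ModelSpec(kind="pooled", seed=9, **SMALL))
    np.testing.assert_array_equal(a.beta_ssc, b.beta_ssc)
    np.testing.assert_array_equal(a.tau, b.tau)
    c = ss.fit_pooled(data, ss.ModelSpec(kind="pooled", seed=10, **SMALL))
    assert not np.array_equal(a.beta_ssc, c.beta_ssc)


def test_exchangeability_under_permutation(tiny):
    """Permuting observations leaves parameter posteriors unchanged up to
    Monte-Carlo error, and tau posterior means permute accordingly."""
    data = _tiny_data(tiny)
    perm = np.array([3, 0, 5, 1, 4, 2])
    pdata = ss.RegressionData(y=data.y[perm], x=data.x[perm])
    spec = dict(kind="pooled", n_chains=2, n_iterations=4000, n_burnin=1000)
    a = ss.fit_pooled(data, ss.ModelSpec(seed=1, **spec))
    b = ss.fit_pooled(pdata, ss.ModelSpec(seed=2, **spec))
    assert a.beta_ssc.mean() == pytest.approx(b.beta_ssc.mean(), abs=0.02)
    assert a.beta0.mean() == pytest.approx(b.beta0.mean(), abs=0.15)
    tau_a = a.tau.reshape(-1, 6).mean(axis=0)
    tau_b = b.tau.reshape(-1, 6).mean(axis=0)
    np.testing.assert_allclose(tau_a[perm], tau_b, atol=0.05)


def test_contaminated_points_get_downweighted():
    """Injected outliers receive posterior-mean tau strictly below the median
    tau of clean points."""
    cfg = ss.GeneratorConfig(
        n_genotypes=60, years=[2019], genotypes_per_year=60, months_per_year=[2],
        min_harvests=1, max_harvests=1, n_volatiles=3, n_active_volatiles=0,
        n_negative_active=0, beta0=2.0, sigma=0.3, nu=30.0, outlier_fraction=0.1,
        n_panelists=2, n_replicates=1, seed=17,
    )
    ds, truth = ss.generate_dataset(cfg)
    rf = ds.regression_frame()
    data = ss.RegressionData(y=rf["y"].to_numpy(), x=rf["x"].to_numpy())
    flags = np.array([truth.outlier_flags[s] for s in rf["sample_id"]])
    assert flags.any()
    draws = ss.fit_pooled(data, ss.ModelSpec(kind="pooled", seed=3, **SMALL))
    tau_mean = draws.tau.reshape(-1, data.n).mean(axis=0)
    assert tau_mean[flags].max() < np.median(tau_mean[~flags])
    summary = ss.summarize(draws, data, seed=0)
    assert summary.n_outliers >= flags.sum()


def test_constant_x_rejected():
    with pytest.raises(ValidationError, match="constant"):
        ss.fit_pooled(
            ss.RegressionData(y=np.array([1.0, 2.0, 3.0]), x=np.full(3, 7.0)),
            ss.ModelSpec(kind="pooled", **SMALL),
        )


def test_kind_mismatch_and_bad_spec(tiny):
    data = _tiny_data(tiny)
    with pytest.raises(ConfigError):
        ss.fit_pooled(data, ss.ModelSpec(kind="hierarchical", **SMALL))
    with pytest.raises(ConfigError):
        ss.ModelSpec(kind="pooled", n_iterations=100, n_burnin=200).validate()


def test_sparse_month_rejected():
    rng = np.random.default_rng(0)
    x = rng.uniform(6, 10, 20)
    y = 1 + 0.5 * x + 0.1 * rng.standard_normal(20)
    month = np.array([1] * 18 + [2] * 2)
    with pytest.raises(ValidationError, match="month 2"):
        ss.fit_hierarchical(
            ss.RegressionData(y=y, x=x, month=month),
            ss.ModelSpec(kind="hierarchical", **SMALL),
        )


def test_single_chain_reports_rhat_absent(tiny):
    data = _tiny_data(tiny)
    draws = ss.fit_pooled(
        data, ss.ModelSpec(kind="pooled", n_chains=1, n_iterations=1500,
                           n_burnin=500, seed=4))
    with pytest.warns(UserWarning, match="R-hat"):
        summary = ss.summarize(draws, data)
    assert summary.avg_rhat is None
    assert summary.params["rhat"].isna().all()


def test_split_rhat_formula_and_limits():
    rng = np.random.default_rng(8)
    base = rng.standard_normal(400)
    identical = np.vstack([base, base])
    # identical chains: R-hat equals its stationary floor sqrt((L-1)/L) ~ 1
    assert ss.split_rhat(identical) == pytest.approx(1.0, abs=0.01)
    shifted = np.vstack([base, base + 3.0])
    r = ss.split_rhat(shifted)
    assert r > 1.5
    assert r == pytest.approx(split_rhat_reference(shifted), abs=1e-12)
    mixed = rng.standard_normal((4, 250))
    assert ss.split_rhat(mixed) == pytest.approx(split_rhat_reference(mixed), abs=1e-12)


def test_prior_reading_insensitivity_at_study_scale(pooled_demo_fit):
    """Reading the stated location priors as variance 10 vs precision 10
    (variance 0.1) moves the slope posterior by far less than one posterior SD
    at n ~ 200."""
    ds, truth, data, draws = pooled_demo_fit
    alt_spec = ss.ModelSpec(kind="pooled", prior_beta_variance=0.1, seed=42,
                            n_chains=2, n_iterations=2500, n_burnin=800)
    alt = ss.fit_pooled(data, alt_spec)
    sd = draws.beta_ssc.std(ddof=1)
    assert abs(alt.beta_ssc.mean() - draws.beta_ssc.mean()) < sd


def test_hierarchical_exchangeable_limit():
    """When all months share one true slope, the per-month posteriors overlap
    and mu covers the common slope."""
    cfg = ss.GeneratorConfig(
        n_genotypes=40, years=[2019], genotypes_per_year=40,
        months_per_year=[1, 2, 3], min_harvests=3, max_harvests=3,
        n_volatiles=3, n_active_volatiles=0, n_negative_active=0,
        month_slopes={1: 0.45, 2: 0.45, 3: 0.45}, sigma=0.25, nu=10.0,
        outlier_fraction=0.0, n_panelists=2, n_replicates=1, seed=23,
    )
    ds, _ = ss.generate_dataset(cfg)
    rf = ds.regression_frame()
    data = ss.RegressionData(y=rf["y"].to_numpy(), x=rf["x"].to_numpy(),
                             month=rf["month"].to_numpy())
    draws = ss.fit_hierarchical(
        data, ss.ModelSpec(kind="hierarchical", seed=6, n_chains=2,
                           n_iterations=4000, n_burnin=1500))
    summary = ss.summarize(draws, data)
    slopes = summary.params[summary.params["parameter"].str.startswith("beta_month")]
    for _, row in slopes.iterrows():
        assert row["q2.5"] <= 0.45 <= row["q97.5"]
    lo = slopes["q2.5"].to_numpy()
    hi = slopes["q97.5"].to_numpy()
    assert (lo.max() < hi.min())  # mutually overlapping intervals
    mu_row = summary.params.set_index("parameter").loc["mu"]
    assert mu_row["q2.5"] <= 0.45 <= mu_row["q97.5"]


def test_draws_long_format_round_trip(tiny):
    data = _tiny_data(tiny)
    draws = ss.fit_pooled(data, ss.ModelSpec(kind="pooled", seed=2, n_chains=2,
                                             n_iterations=1200, n_burnin=400))
    back = ss.PosteriorDraws.from_long_frame(draws.to_long_frame())
    np.testing.assert_allclose(back.beta_ssc, draws.beta_ssc)
    np.testing.assert_allclose(back.nu, draws.nu)


def test_grid_nu_sampler_agrees_with_slice(tiny):
    data = _tiny_data(tiny)
    a = ss.fit_pooled(data, ss.ModelSpec(kind="pooled", seed=5, nu_sampler="slice",
                                         n_chains=2, n_iterations=4000, n_burnin=1000))
    b = ss.fit_pooled(data, ss.ModelSpec(kind="pooled", seed=5, nu_sampler="grid",
                                         n_chains=2, n_iterations=4000, n_burnin=1000))
    assert a.nu.mean() == pytest.approx(b.nu.mean(), rel=0.1)
    assert a.beta_ssc.mean() == pytest.approx(b.beta_ssc.mean(), abs=0.01)
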
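"""PLS1/NIPALS, VIP and the cross-year importance index."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

import strawsense as ss
from strawsense.errors import ValidationError
from strawsense.pls import aggregate_importance
from tests.helpers import vip_reference


def _random_xy(seed, n=30, p=6):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + 0.3 * rng.standard_normal(n)
    return X, y


def test_single_active_predictor_recovers_proportionality():
    rng = np.random.default_rng(2)
    # zero-mean orthogonal predictors: the single-component solution is exact
    Q, _ = np.linalg.qr(np.column_stack([np.ones(25), rng.standard_normal((25, 4))]))
    X = Q[:, 1:]
    y = 2.5 * X[:, 1]
    m = ss.fit_pls(X, y, n_components=1)
    assert m.coefficients[1] == pytest.approx(2.5, abs=1e-8)
    np.testing.assert_allclose(np.delete(m.coefficients, 1), 0, atol=1e-8)


def test_full_rank_pls_equals_ols_fit():
    X, y = _random_xy(5, n=30, p=4)
    m = ss.fit_pls(X, y, n_components=4)
    Xc = np.column_stack([np.ones(len(y)), X])
    ols_fit = Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    np.testing.assert_allclose(m.predict(X), ols_fit, atol=1e-6)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fitted_values_match_sklearn_pls(seed):
    """The in-package NIPALS route agrees with an independent implementation."""
    X, y = _random_xy(seed, n=30, p=6)
    m = ss.fit_pls(X, y, n_components=3)
    ref = PLSRegression(n_components=3, scale=False).fit(X, y[:, None])
    np.testing.assert_allclose(m.predict(X), ref.predict(X).ravel(), atol=1e-6)


def test_prediction_through_scores_equals_coefficients():
    X, y = _random_xy(9, n=25, p=5)
    m = ss.fit_pls(X, y, n_components=3)
    via_scores = float(y.mean()) + m.x_scores @ m.y_loadings
    np.testing.assert_allclose(m.predict(X), via_scores, atol=1e-6)


@pytest.mark.parametrize("seed", [0, 3, 7, 11])
def test_vip_normalization_and_formula_oracle(seed):
    """sum VIP^2 = p on every fit, and VIP equals the explicit loop formula."""
    X, y = _random_xy(seed, n=24, p=5)
    m = ss.fit_pls(X, y, n_components=3)
    vip = ss.compute_vip(m)
    assert (vip >= 0).all()
    assert np.sum(vip**2) == pytest.approx(5.0, abs=1e-6)
    np.testing.assert_allclose(
        vip, vip_reference(m.weights, m.x_scores, m.y_loadings), atol=1e-10)


def test_single_predictor_vip_is_one():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((15, 1))
    y = 1.5 * X[:, 0] + 0.1 * rng.standard_normal(15)
    vip = ss.compute_vip(ss.fit_pls(X, y, n_components=1))
    assert vip[0] == pytest.approx(1.0, abs=1e-12)


def test_zero_variance_predictor_dropped_with_metadata():
    X, y = _random_xy(6, n=20, p=4)
    X[:, 2] = 3.0
    m = ss.fit_pls(X, y, n_components=2, predictor_names=list("abcd"))
    assert m.dropped_predictors == ["c"]
    assert m.coefficients[2] == 0.0


def test_constant_response_rejected():
    X, _ = _random_xy(8, n=10, p=3)
    with pytest.raises(ValidationError):
        ss.fit_pls(X, np.full(10, 2.0), n_components=2)


def test_importance_index_arithmetic():
    """3 positive-hit years, 1 negative-hit year, VIP < 1 elsewhere => index 2;
    a 7-for-7 positive compound sits at the +7 anchor."""
    years = list(range(2013, 2020))
    vip = pd.DataFrame(0.5, index=["a", "b"], columns=years)
    sign = pd.DataFrame(1, index=["a", "b"], columns=years)
    vip.loc["a", years[:3]] = 1.4
    vip.loc["a", years[3]] = 1.2
    sign.loc["a", years[3]] = -1
    vip.loc["b"] = 1.8
    table = aggregate_importance(vip, sign, "sweetness")
    assert table.importance_index["a"] == 2
    assert table.importance_index["b"] == 7
    assert table.influential.all()
    assert table.importance_index.abs().max() <= len(years)


def _screen_config(**kw):
    base = dict(
        n_genotypes=24, years=[2015, 2016, 2017, 2018], genotypes_per_year=18,
        min_harvests=3, max_harvests=3, n_panelists=2, n_replicates=1,
        n_volatiles=15, n_active_volatiles=5, n_negative_active=1,
        n_absent_volatiles=0, gamma_scale=0.35, sigma=0.2, outlier_fraction=0.0,
        seed=31,
    )
    base.update(kw)
    return ss.GeneratorConfig(**base)


def test_screen_recovers_active_volatiles_and_ssc_tops_sweetness():
    ds, truth = ss.generate_dataset(_screen_config())
    table = ss.screen_attribute(ds, "sweetness")
    idx = table.importance_index
    # SSC attains the maximal positive index
    assert idx["SSC"] == idx.max() == len(table.years)
    actives = truth.active_volatile_coefs
    inert = [c for c in ds.compound_names if c not in actives]
    positives = [c for c, g in actives.items() if g > 0]
    negatives = [c for c, g in actives.items() if g < 0]
    # sweetness-enhancing actives sit at the top of the volatile table ...
    assert all(idx[c] >= 1 for c in positives)
    assert np.mean([idx[c] for c in positives]) > np.mean([idx[c] for c in inert]) + 1
    # ... and the sweetness-reducing compound at the bottom
    for c in negatives:
        assert idx[c] == idx.min() < 0
    assert abs(np.mean([idx[c] for c in inert])) < 1.0


def test_screen_null_volatiles_stay_below_threshold():
    ds, _ = ss.generate_dataset(_screen_config(
        n_active_volatiles=0, n_negative_active=0, seed=5))
    table = ss.screen_attribute(ds, "sweetness")
    vol_idx = table.importance_index.drop(["SSC", "TA", "firmness"])
    assert vol_idx.abs().max() <= 2  # threshold-crossing noise only
    assert abs(vol_idx.mean()) < 0.5


def test_index_antisymmetry_under_response_negation():
    ds, _ = ss.generate_dataset(_screen_config())
    flipped = ss.generate_dataset(_screen_config())[0]
    for r in flipped.records:
        r.sensory["sweetness"] = 10.0 - r.sensory["sweetness"]
    t1 = ss.screen_attribute(ds, "sweetness")
    t2 = ss.screen_attribute(flipped, "sweetness")
    pd.testing.assert_series_equal(t1.importance_index, -t2.importance_index)


def test_permutation_null_centers_index_at_zero():
    ds, _ = ss.generate_dataset(_screen_config(seed=13))
    rng = np.random.default_rng(0)
    by_year = {}
    for r in ds.records:
        by_year.setdefault(r.year, []).append(r)
    for recs in by_year.values():
        vals = [r.sensory["sweetness"] for r in recs]
        for r, v in zip(recs, rng.permutation(vals)):
            r.sensory["sweetness"] = float(v)
    table = ss.screen_attribute(ds, "sweetness")
    vol_idx = table.importance_index.drop(["SSC", "TA", "firmness"])
    assert abs(vol_idx.mean()) < 1.0
    assert abs(table.importance_index["SSC"]) <= 2


def test_firmness_response_excludes_firmness_predictor():
    ds, _ = ss.generate_dataset(_screen_config())
    table = ss.screen_attribute(ds, "firmness")
    assert "firmness" not in table.importance_index.index
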
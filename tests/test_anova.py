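"""Two-way fixed-effects decomposition against closed-form sums of squares."""

import numpy as np
import pandas as pd
import pytest

import strawsense as ss
from strawsense.core_data import PanelDataset, SampleRecord
from strawsense.errors import ConfigError, ValidationError


def _balanced_2x2(cell_values, reps=3, noise=None):
    """Dataset with 2 genotypes x 2 months and hand-set panelist ratings."""
    records, rows = [], []
    rng = np.random.default_rng(0)
    for gi, g in enumerate(["G1", "G2"]):
        for mi, m in enumerate([1, 2]):
            sid = f"{g}-M{m}"
            base = cell_values[gi][mi]
            vals = [base + (noise[gi][mi][r] if noise is not None else 0.1 * r)
                    for r in range(reps)]
            records.append(SampleRecord(
                sample_id=sid, genotype=g, year=2019, month=m,
                sensory={"sweetness": float(np.mean(vals))},
                ssc=7.0, ta=0.8, ph=3.5, volatiles={}))
            rows += [(sid, f"P{r}", "sweetness", v) for r, v in enumerate(vals)]
    pan = pd.DataFrame(rows, columns=["sample_id", "panelist_id", "attribute", "rating"])
    return PanelDataset(records=records, attribute_names=["sweetness"],
                        compound_names=[], panelist_ratings=pan)


def _hand_anova_2x2(values):
    """Type-I sums of squares for a balanced 2x2 design, by direct formula.

    ``values[g][m]`` is the list of replicate observations in cell (g, m)."""
    arr = np.array(values, float)  # (2, 2, r)
    r = arr.shape[2]
    grand = arr.mean()
    g_means = arr.mean(axis=(1, 2))
    m_means = arr.mean(axis=(0, 2))
    cell = arr.mean(axis=2)
    ss_g = 2 * r * ((g_means - grand) ** 2).sum()
    ss_m = 2 * r * ((m_means - grand) ** 2).sum()
    ss_int = r * ((cell - g_means[:, None] - m_means[None, :] + grand) ** 2).sum()
    ss_res = ((arr - cell[:, :, None]) ** 2).sum()
    df_res = 4 * (r - 1)
    return {
        "genotype": (ss_g / 1) / (ss_res / df_res),
        "month": (ss_m / 1) / (ss_res / df_res),
        "interaction": (ss_int / 1) / (ss_res / df_res),
    }


def test_2x2_f_statistics_match_hand_computation():
    rng = np.random.default_rng(5)
    noise = rng.standard_normal((2, 2, 4)) * 0.5
    cells = [[4.0, 5.0], [4.5, 6.5]]
    values = [[[cells[g][m] + noise[g][m][r] for r in range(4)] for m in range(2)]
              for g in range(2)]
    ds = _balanced_2x2(cells, reps=4, noise=noise)
    res = ss.fit_effects(ds, "sweetness", 2019, level="panelist")
    expected = _hand_anova_2x2(values)
    for _, row in res.iterrows():
        assert row["F"] == pytest.approx(expected[row["effect"]], rel=1e-10)


def test_balanced_design_type1_equals_type2():
    ds = _balanced_2x2([[4.0, 5.0], [4.5, 6.5]], reps=3)
    t1 = ss.fit_effects(ds, "sweetness", 2019, ss_type=1)
    t2 = ss.fit_effects(ds, "sweetness", 2019, ss_type=2)
    np.testing.assert_allclose(
        t1.sort_values("effect")["p"].to_numpy(),
        t2.sort_values("effect")["p"].to_numpy(), atol=1e-12)


def test_bonferroni_rules():
    assert ss.bonferroni(0.03, 1) == 0.03  # family of one: unchanged
    assert ss.bonferroni(0.001, 10) == pytest.approx(0.01)
    assert -np.log10(ss.bonferroni(0.001, 10)) == pytest.approx(2.0)
    assert ss.bonferroni(0.5, 10) == 1.0  # capped
    with pytest.raises(ConfigError):
        ss.bonferroni(0.1, 0)


def test_untestable_interaction_flagged_not_numbered():
    ds = _balanced_2x2([[4.0, 5.0], [4.5, 6.5]], reps=3)
    res = ss.fit_effects(ds, "sweetness", 2019, level="sample_mean")
    assert (~res["testable"]).all()
    assert res["p"].isna().all()


def test_genotype_driven_attribute_detected_and_month_not():
    """An attribute with purely genotypic structure shows a significant
    genotype effect and a null month effect."""
    cfg = ss.GeneratorConfig(
        n_genotypes=10, years=[2019], genotypes_per_year=10,
        months_per_year=[1, 2, 3], min_harvests=3, max_harvests=3,
        n_volatiles=3, n_active_volatiles=0, n_negative_active=0,
        attr_genotype_sd=1.0, attr_month_sd=0.0, attr_interaction_sd=0.0,
        n_panelists=8, n_replicates=2, panelist_bias_sd=0.0, seed=19,
    )
    ds, _ = ss.generate_dataset(cfg)
    res = ss.effects_table(ds, attributes=["green"], alpha=0.01)
    tab = res.table.set_index("effect")
    assert tab.loc["genotype", "significant"]
    assert tab.loc["month", "p"] > 0.01


def test_permuting_genotype_labels_destroys_significance():
    cfg = ss.GeneratorConfig(
        n_genotypes=8, years=[2019], genotypes_per_year=8,
        months_per_year=[1, 2], min_harvests=2, max_harvests=2,
        n_volatiles=3, n_active_volatiles=0, n_negative_active=0,
        attr_genotype_sd=1.2, attr_month_sd=0.0, attr_interaction_sd=0.0,
        n_panelists=6, n_replicates=2, panelist_bias_sd=0.0, seed=29,
    )
    ds, _ = ss.generate_dataset(cfg)
    orig = ss.fit_effects(ds, "green", 2019).set_index("effect")
    rng = np.random.default_rng(1)
    ratings = ds.panelist_ratings.copy()
    sid_geno = {r.sample_id: r.genotype for r in ds.records}
    # permute genotype labels among samples (breaks the genotype-value link)
    sids = list(sid_geno)
    permuted = dict(zip(sids, rng.permutation([sid_geno[s] for s in sids])))
    for rec in ds.records:
        rec.genotype = permuted[rec.sample_id] + "-" + rec.sample_id  # keep keys unique
    perm = ss.fit_effects(ds, "green", 2019).set_index("effect")
    assert orig.loc["genotype", "p"] < 1e-6
    assert perm.loc["genotype", "p"] > orig.loc["genotype", "p"]


def test_requires_two_levels():
    ds = _balanced_2x2([[4.0, 5.0], [4.5, 6.5]], reps=3)
    with pytest.raises(ValidationError, match="no samples"):
        ss.fit_effects(ds, "sweetness", 2020)
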
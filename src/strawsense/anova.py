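"""Per-year, per-attribute fixed-effects decomposition Y ~ G + M + G:M.

Each season and attribute gets its own two-way fixed-effects linear model with
genotype, harvest-month and interaction terms, fitted by least squares on the
finest observation level available: panelist-level ratings for sensory
attributes, field-replicate values for chemistry (SSC/TA/pH), sample means as
the fallback.  Tests use sequential (Type I) sums of squares in the order
G, M, GxM against the residual mean square — the classical base-R `aov`
convention — with a Type II option for unbalanced designs.  P-values are
Bonferroni-corrected within the year's family of tests and reported as
-log10(p) with a significance flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core_data import PanelDataset
from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

CHEM_MEASURES = ("ssc", "ta", "ph")
EFFECTS = ("genotype", "month", "interaction")
_TERMS = {"genotype": "C(genotype)", "month": "C(month)",
          "interaction": "C(genotype):C(month)"}


@dataclass
class EffectsResult:
    """Long-format effects table: one row per (year, attribute, effect)."""

    table: pd.DataFrame
    # columns: year, attribute, effect, level, df, F, p, p_corrected,
    #          neg_log10_p, significant, testable

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _observation_frame(
    ds: PanelDataset, attribute: str, year: int, level: str
) -> tuple[pd.DataFrame, str]:
    """Assemble (value, genotype, month) rows for one attribute and year at the
    requested observation level ('panelist', 'replicate', 'sample_mean',
    'auto')."""
    meta = pd.DataFrame(
        {"sample_id": [r.sample_id for r in ds.records],
         "genotype": [r.genotype for r in ds.records],
         "year": [r.year for r in ds.records],
         "month": [r.month for r in ds.records]}
    )
    meta = meta[meta["year"] == year]
    if meta.empty:
        raise ValidationError(f"no samples for year {year}")
    is_chem = attribute in CHEM_MEASURES

    if level == "auto":
        if is_chem and ds.replicate_chem is not None:
            level = "replicate"
        elif not is_chem and ds.panelist_ratings is not None:
            level = "panelist"
        else:
            level = "sample_mean"

    if level == "panelist":
        if ds.panelist_ratings is None:
            raise ValidationError("panelist-level ratings not available")
        obs = ds.panelist_ratings.query("attribute == @attribute")
        df = obs.merge(meta, on="sample_id").rename(columns={"rating": "value"})
    elif level == "replicate":
        if ds.replicate_chem is None:
            raise ValidationError("replicate-level chemistry not available")
        obs = ds.replicate_chem.query("measure == @attribute")
        df = obs.merge(meta, on="sample_id")
    elif level == "sample_mean":
        if is_chem:
            vals = {r.sample_id: getattr(r, attribute) for r in ds.records}
        else:
            vals = {r.sample_id: r.sensory.get(attribute, np.nan) for r in ds.records}
        df = meta.assign(value=meta["sample_id"].map(vals))
    else:
        raise ConfigError(f"unknown observation level {level!r}")
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValidationError(f"attribute {attribute!r} not observed in {year}")
    return df[["value", "genotype", "month"]], level


def fit_effects(
    ds: PanelDataset, attribute: str, year: int,
    level: str = "auto", ss_type: int = 1,
) -> pd.DataFrame:
    """Fit Y ~ G + M + G:M for one (attribute, year) cell; returns rows with
    raw p-values per effect.  Effects without residual replication are flagged
    untestable rather than given a number."""
    df, used_level = _observation_frame(ds, attribute, year, level)
    if df["genotype"].nunique() < 2 or df["month"].nunique() < 2:
        raise ValidationError(
            f"{attribute}/{year}: need >= 2 genotypes and >= 2 months "
            f"(got {df['genotype'].nunique()} x {df['month'].nunique()})"
        )
    model = smf.ols("value ~ C(genotype) + C(month) + C(genotype):C(month)",
                    data=df).fit()
    testable = model.df_resid > 0
    rows = []
    if testable:
        aov = sm.stats.anova_lm(model, typ=ss_type)
        for effect in EFFECTS:
            term = _TERMS[effect]
            rows.append({
                "year": year, "attribute": attribute, "effect": effect,
                "level": used_level, "df": float(aov.loc[term, "df"]),
                "F": float(aov.loc[term, "F"]), "p": float(aov.loc[term, "PR(>F)"]),
                "testable": np.isfinite(aov.loc[term, "F"]),
            })
    else:
        logger.warning("%s/%s: no residual degrees of freedom; effects untestable",
                       attribute, year)
        for effect in EFFECTS:
            rows.append({"year": year, "attribute": attribute, "effect": effect,
                         "level": used_level, "df": np.nan, "F": np.nan,
                         "p": np.nan, "testable": False})
    return pd.DataFrame(rows)


def bonferroni(p: float | np.ndarray, family_size: int) -> float | np.ndarray:
    """Bonferroni-corrected p-value, capped at 1 (family of 1 => unchanged)."""
    if family_size < 1:
        raise ConfigError("family_size must be >= 1")
    return np.minimum(np.asarray(p, float) * family_size, 1.0)[()]


def effects_table(
    ds: PanelDataset,
    attributes: list[str] | None = None,
    alpha: float = 0.01,
    level: str = "auto",
    ss_type: int = 1,
) -> EffectsResult:
    """Full per-year effects decomposition with Bonferroni correction.

    The correction family is all testable effects within a year (attributes x
    3 by default); corrected p is capped at 1 and reported as -log10.
    """
    attributes = attributes or (list(ds.attribute_names) + list(CHEM_MEASURES))
    years = sorted({r.year for r in ds.records})
    pieces = []
    for yr in years:
        for attr in attributes:
            try:
                pieces.append(fit_effects(ds, attr, yr, level=level, ss_type=ss_type))
            except ValidationError as exc:
                logger.info("skipping %s/%s: %s", attr, yr, exc)
    if not pieces:
        raise ValidationError("no testable (attribute, year) cells")
    table = pd.concat(pieces, ignore_index=True)

    table["p_corrected"] = np.nan
    for yr, idx in table.groupby("year").groups.items():
        sub = table.loc[idx]
        m = int(sub["testable"].sum())
        corr = np.minimum(sub["p"] * max(m, 1), 1.0)
        table.loc[idx, "p_corrected"] = corr
    table["neg_log10_p"] = -np.log10(table["p_corrected"])
    table["significant"] = table["p_corrected"] <= alpha
    table.loc[~table["testable"], ["neg_log10_p", "significant"]] = [np.nan, False]
    return EffectsResult(table=table)
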
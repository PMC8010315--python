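"""Per-year PLS models of sensory attributes on chemistry + volatiles, VIP
scores, and the cross-year importance index.

For each season an independent PLS1 model (5 components, or the rank limit on
small seasons) regresses one sensory attribute on SSC, TA, the volatile panel
and sensory firmness (pH is excluded because of its strong correlation with
TA; firmness stands in for unmeasured instrumental texture).  Per-year
importance is scored by the variable importance in projection,

    VIP_j = sqrt( p * sum_a SSY_a * (w_ja / ||w_a||)^2 / sum_a SSY_a ),

with SSY_a = q_a^2 * t_a' t_a the response variance captured by component a;
mean squared VIP over predictors is 1, so VIP > 1 flags above-average
contributors.  The effect sign is taken from the final regression coefficient.
Seasons are then aggregated into the importance index

    index = (#years with VIP > 1 and positive effect)
          - (#years with VIP > 1 and negative effect),

bounded by +/- the number of seasons analyzed; a compound is called
influential only when it clears the VIP threshold in at least 2 years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import PanelDataset
from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 5
VIP_THRESHOLD = 1.0
MIN_YEARS_INFLUENTIAL = 2


@dataclass
class PlsModel:
    """A fitted PLS1 decomposition (NIPALS), one response, one season."""

    n_components: int
    weights: np.ndarray  # (p, A), unit-norm columns w_a
    x_loadings: np.ndarray  # (p, A)
    x_scores: np.ndarray  # (n, A) t_a
    y_loadings: np.ndarray  # (A,) q_a
    coefficients: np.ndarray  # (p,) final regression coefficients
    intercept: float
    predictor_names: list[str]
    response_name: str
    year: int | None = None
    dropped_predictors: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coefficients


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    predictor_names: list[str] | None = None,
    response_name: str = "y",
    year: int | None = None,
) -> PlsModel:
    """PLS1 via NIPALS with per-component deflation of X.

    Zero-variance predictors are dropped with a warning and recorded in the
    model metadata (their coefficients are reported as 0).  Deterministic for
    fixed input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValidationError("X must be (n, p) and y (n,) with matching n")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValidationError("fit_pls requires complete data (impute first)")
    n, p_full = X.shape
    names = list(predictor_names) if predictor_names is not None else [
        f"x{j}" for j in range(p_full)]
    if len(names) != p_full:
        raise ValidationError("predictor_names length mismatch")

    variances = X.var(axis=0)
    keep = variances > 0
    dropped = [names[j] for j in range(p_full) if not keep[j]]
    if dropped:
        logger.warning("dropping zero-variance predictors: %s", dropped)
    Xk = X[:, keep]
    kept_names = [nm for nm, k in zip(names, keep) if k]
    p = Xk.shape[1]
    if p == 0:
        raise ValidationError("no predictors with variance remain")
    A = int(n_components)
    if A < 1:
        raise ConfigError("n_components must be >= 1")
    A = min(A, p, n - 1) if n > 1 else 1

    x_mean = Xk.mean(axis=0)
    y_mean = float(y.mean())
    E = Xk - x_mean
    f = y - y_mean

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    a_eff = 0
    for a in range(A):
        wv = E.T @ f
        norm = np.linalg.norm(wv)
        if norm < 1e-12:  # residual response exhausted
            break
        wv /= norm
        t = E @ wv
        tt = float(t @ t)
        if tt < 1e-12:
            break
        qa = float(t @ f) / tt
        pv = (E.T @ t) / tt
        W[:, a], P[:, a], T[:, a], q[a] = wv, pv, t, qa
        E = E - np.outer(t, pv)
        f = f - qa * t
        a_eff = a + 1
    if a_eff == 0:
        raise ValidationError("response is constant; PLS undefined")
    W, P, T, q = W[:, :a_eff], P[:, :a_eff], T[:, :a_eff], q[:a_eff]

    # B = W (P'W)^-1 q ; transforms scores-space regression to predictor space
    coef_kept = W @ np.linalg.solve(P.T @ W, q)
    coefficients = np.zeros(p_full)
    coefficients[keep] = coef_kept
    intercept = y_mean - float(x_mean @ coef_kept)

    return PlsModel(
        n_components=a_eff, weights=W, x_loadings=P, x_scores=T, y_loadings=q,
        coefficients=coefficients, intercept=intercept,
        predictor_names=names, response_name=response_name, year=year,
        dropped_predictors=dropped,
    )


def compute_vip(m: PlsModel) -> np.ndarray:
    """Per-predictor VIP vector (dropped predictors score 0).

    Satisfies sum_j VIP_j^2 = p over the retained predictors.
    """
    ssy = m.y_loadings**2 * (m.x_scores**2).sum(axis=0)  # (A,)
    total = ssy.sum()
    if total <= 0:
        raise ValidationError("response variance captured is zero; VIP undefined")
    wnorm = np.linalg.norm(m.weights, axis=0)
    wnorm[wnorm == 0] = 1.0
    frac = (m.weights / wnorm) ** 2  # (p, A)
    p = m.weights.shape[0]
    vip_kept = np.sqrt(p * (frac @ ssy) / total)
    kept = [nm for nm in m.predictor_names if nm not in m.dropped_predictors]
    out = np.zeros(len(m.predictor_names))
    pos = {nm: j for j, nm in enumerate(kept)}
    for j, nm in enumerate(m.predictor_names):
        if nm in pos:
            out[j] = vip_kept[pos[nm]]
    return out


@dataclass
class ImportanceTable:
    """VIP-by-year matrix, effect signs, and the aggregated importance index
    for one response attribute."""

    response_name: str
    years: list[int]
    vip_by_year: pd.DataFrame  # predictors x years
    sign_by_year: pd.DataFrame  # predictors x years, values in {+1, -1, 0(absent)}
    importance_index: pd.Series  # predictor -> integer index
    influential: pd.Series  # predictor -> bool (|VIP>1 years| >= 2)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for pred in self.vip_by_year.index:
            for yr in self.years:
                rows.append({
                    "predictor": pred, "attribute": self.response_name, "year": yr,
                    "vip": self.vip_by_year.loc[pred, yr],
                    "sign": int(self.sign_by_year.loc[pred, yr]),
                    "importance_index": int(self.importance_index[pred]),
                    "influential": bool(self.influential[pred]),
                })
        return pd.DataFrame(rows)

    def ranked(self) -> pd.Series:
        return self.importance_index.sort_values(ascending=False)


def importance_index(
    models: dict[int, PlsModel], vip_threshold: float = VIP_THRESHOLD
) -> ImportanceTable:
    """Aggregate per-year models into the cross-year importance index.

    Predictors absent from a year's model simply contribute nothing that year.
    All models must share one response name.
    """
    if not models:
        raise ValidationError("need at least one yearly model")
    responses = {m.response_name for m in models.values()}
    if len(responses) != 1:
        raise ValidationError(f"inconsistent response names across years: {responses}")
    response = responses.pop()
    years = sorted(models)
    predictors: list[str] = []
    for m in models.values():
        for nm in m.predictor_names:
            if nm not in predictors:
                predictors.append(nm)

    vip_df = pd.DataFrame(0.0, index=predictors, columns=years)
    sign_df = pd.DataFrame(0, index=predictors, columns=years, dtype=int)
    for yr in years:
        m = models[yr]
        vips = compute_vip(m)
        for nm, v, c in zip(m.predictor_names, vips, m.coefficients):
            vip_df.loc[nm, yr] = v
            sign_df.loc[nm, yr] = int(np.sign(c)) if v > 0 else 0

    return aggregate_importance(vip_df, sign_df, response, vip_threshold)


def aggregate_importance(
    vip_by_year: pd.DataFrame,
    sign_by_year: pd.DataFrame,
    response_name: str,
    vip_threshold: float = VIP_THRESHOLD,
) -> ImportanceTable:
    """Turn VIP-by-year and sign-by-year tables into the importance index:
    (#years with VIP > threshold and + sign) - (#years with VIP > threshold
    and - sign), bounded by +/- the number of years."""
    years = list(vip_by_year.columns)
    hit = vip_by_year > vip_threshold
    pos = (hit & (sign_by_year > 0)).sum(axis=1)
    neg = (hit & (sign_by_year < 0)).sum(axis=1)
    index = (pos - neg).astype(int)
    influential = hit.sum(axis=1) >= MIN_YEARS_INFLUENTIAL
    assert index.abs().max() <= len(years)
    return ImportanceTable(
        response_name=response_name, years=years, vip_by_year=vip_by_year,
        sign_by_year=sign_by_year, importance_index=index, influential=influential,
    )


def _standardize(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (M - mu) / sd_safe


def screen_attribute(
    ds: PanelDataset,
    attribute: str,
    n_components: int = DEFAULT_N_COMPONENTS,
    vip_threshold: float = VIP_THRESHOLD,
    zero_fill_missing_volatiles: bool = True,
    min_samples_per_year: int = 2,
) -> ImportanceTable:
    """Per-year PLS screen of ``attribute`` against SSC, TA, volatiles and
    sensory firmness; predictors and response standardized within year; pH
    excluded (collinear with TA)."""
    if attribute not in ds.attribute_names:
        raise ValidationError(f"attribute {attribute!r} not in dataset")
    df = ds.to_frame(zero_fill_volatiles=zero_fill_missing_volatiles)
    ycol = "sens_" + attribute
    predictor_cols = ["chem_ssc", "chem_ta"]
    pretty = {"chem_ssc": "SSC", "chem_ta": "TA", "sens_firmness": "firmness"}
    if attribute != "firmness" and "firmness" in ds.attribute_names:
        predictor_cols.append("sens_firmness")
    vol_cols = ["vol_" + c for c in ds.compound_names]
    predictor_cols += vol_cols
    names = [pretty.get(c, c.removeprefix("vol_")) for c in predictor_cols]

    models: dict[int, PlsModel] = {}
    for yr, sub in df.groupby("year"):
        sub = sub.dropna(subset=[ycol, "chem_ssc", "chem_ta"])
        if len(sub) < min_samples_per_year:
            logger.warning("year %s skipped: only %d usable samples", yr, len(sub))
            continue
        X = _standardize(sub[predictor_cols].to_numpy(float))
        yv = sub[ycol].to_numpy(float)
        ysd = yv.std()
        if ysd == 0:
            logger.warning("year %s skipped: constant response", yr)
            continue
        yz = (yv - yv.mean()) / ysd
        models[int(yr)] = fit_pls(X, yz, n_components, predictor_names=names,
                                  response_name=attribute, year=int(yr))
    if not models:
        raise ValidationError(f"no year had enough data to screen {attribute!r}")
    return importance_index(models, vip_threshold=vip_threshold)
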
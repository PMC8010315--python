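"""PCA of sensory + chemistry variables and K-means (k=3) sample grouping.

Variables are standardized to unit variance by default before both analyses:
the table mixes 0-10 panel ratings with SSC percentages and pH units, and an
unstandardized analysis would be dominated by scale.  Component signs are
fixed by forcing the largest-magnitude loading of each component positive.
K-means labels are arbitrary, so clusters are renumbered deterministically by
descending mean sweetness of their members — "the sweet cluster" is then
stable across seeds and restarts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core_data import PanelDataset
from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PROFILE_VARIABLES = [
    "sens_sweetness", "sens_sourness", "sens_strawberry", "sens_green",
    "sens_overripe", "sens_woody", "sens_astringent", "sens_firmness",
    "chem_ssc", "chem_ta", "chem_ph",
]


@dataclass
class PcaResult:
    variables: list[str]
    loadings: pd.DataFrame  # variables x components, orthonormal columns
    scores: pd.DataFrame  # samples x components, indexed by sample_id
    explained_fraction: np.ndarray

    def __post_init__(self) -> None:
        ef = self.explained_fraction
        if ((ef < -1e-12) | (ef > 1 + 1e-12)).any() or (np.diff(ef) > 1e-10).any():
            raise ValidationError("explained fractions must be non-increasing in [0,1]")
        L = self.loadings.to_numpy()
        gram = L.T @ L
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValidationError("loading columns must be orthonormal")


@dataclass
class ClusterAssignment:
    labels: pd.Series  # sample_id -> cluster label in 1..k
    centroids: pd.DataFrame  # clusters x variables (standardized space)
    k: int
    inertia: float  # within-cluster sum of squares of the reported solution


def _profile_matrix(
    ds: PanelDataset, variables: list[str], standardize: bool
) -> tuple[pd.DataFrame, np.ndarray]:
    df = ds.to_frame().set_index("sample_id")
    missing_cols = [v for v in variables if v not in df.columns]
    if missing_cols:
        raise ValidationError(f"variables not in dataset: {missing_cols}")
    sub = df[variables]
    keep = sub.notna().all(axis=1)
    if (~keep).any():
        logger.info("dropping %d samples with missing profile variables", int((~keep).sum()))
        sub = sub[keep]
    M = sub.to_numpy(float)
    if M.shape[0] < 2:
        raise ValidationError("need at least 2 complete samples")
    M = M - M.mean(axis=0)
    if standardize:
        sd = M.std(axis=0, ddof=0)
        zero = [v for v, s in zip(variables, sd) if s == 0]
        if zero:
            raise ValidationError(
                f"constant variable(s) cannot be standardized: {zero}")
        M = M / sd
    return sub, M


def run_pca(
    ds: PanelDataset,
    variables: list[str] | None = None,
    standardize: bool = True,
    n_components: int | None = None,
) -> PcaResult:
    """Principal components of the sample profile; all components by default
    so explained fractions sum to 1."""
    variables = variables or DEFAULT_PROFILE_VARIABLES
    sub, M = _profile_matrix(ds, variables, standardize)
    n, p = M.shape
    k = min(n - 1 if n > 1 else 1, p) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(M)
    loadings = pca.components_.T  # (p, k), orthonormal columns

    # deterministic sign: largest-magnitude loading of each component positive
    for a in range(loadings.shape[1]):
        col = loadings[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, a] = -col
            scores[:, a] = -scores[:, a]

    comp_names = [f"PC{a + 1}" for a in range(loadings.shape[1])]
    return PcaResult(
        variables=list(variables),
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=sub.index, columns=comp_names),
        explained_fraction=pca.explained_variance_ratio_.copy(),
    )


def run_kmeans(
    ds: PanelDataset,
    variables: list[str] | None = None,
    k: int = 3,
    n_restarts: int = 25,
    seed: int = 0,
    standardize: bool = True,
) -> ClusterAssignment:
    """K-means over the (standardized) profile, best of ``n_restarts`` runs,
    clusters renumbered 1..k by descending mean sweetness of members."""
    if k < 1:
        raise ConfigError("k must be >= 1")
    variables = variables or DEFAULT_PROFILE_VARIABLES
    sub, M = _profile_matrix(ds, variables, standardize)
    if k > M.shape[0]:
        raise ConfigError(f"k={k} exceeds the {M.shape[0]} available samples")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed) % (2**31))
    raw = km.fit_predict(M)

    # rank clusters by mean sweetness of their members (fallback: first variable)
    sweet_col = "sens_sweetness" if "sens_sweetness" in sub.columns else sub.columns[0]
    sweet = sub[sweet_col].to_numpy(float)
    order_stat = [
        (-sweet[raw == c].mean(), -np.sum(raw == c), c) for c in range(k)
    ]
    ranked = [c for *_, c in sorted(order_stat)]
    relabel = {c: i + 1 for i, c in enumerate(ranked)}
    labels = pd.Series([relabel[c] for c in raw], index=sub.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_[ranked], columns=variables,
        index=[i + 1 for i in range(k)],
    )
    return ClusterAssignment(labels=labels, centroids=centroids, k=k,
                             inertia=float(km.inertia_))
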
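"""Unsupervised cohort structure: PCA, correlation clustering, site clusters.

PCA drops the lowest-variance fraction of sites first (removeVar-style
filtering, default 0.1), centers (optionally scales) and decomposes by SVD
with a fixed sign convention so results are reproducible. Sample-level
structure uses Spearman correlation with complete-linkage hierarchical
clustering; site-level structure clusters the top variable sites on
Euclidean distance of their level vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MethylPCA",
    "pca",
    "pc_age_correlation",
    "sample_correlation_cluster",
    "top_variable_sites",
    "site_cluster",
]


class MethylPCA(TransformerMixin, BaseEstimator):
    """PCA of a samples x sites methylation matrix with low-variance filtering.

    Parameters
    ----------
    remove_var_fraction : float, default 0.1
        Fraction of lowest-variance sites dropped before the decomposition
        (zero-variance sites are always dropped).
    center, scale : bool
        Column centering (default on) and unit-variance scaling (default
        off), matching the conventions of the R PCA tooling this mirrors.

    Attributes
    ----------
    scores_ : samples x components array.
    loadings_ : kept-sites x components array.
    variance_explained_ : fraction of variance per component, non-increasing.
    kept_sites_ : integer indices of sites surviving the variance filter.
    """

    def __init__(self, remove_var_fraction: float = 0.1,
                 center: bool = True, scale: bool = False):
        self.remove_var_fraction = remove_var_fraction
        self.center = center
        self.scale = scale

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if n < 3:
            raise ValueError("PCA needs >= 3 samples")
        var = X.var(axis=0, ddof=1)
        if np.all(var == 0):
            raise ValueError("all sites have zero variance; samples identical")
        # drop the lowest-variance fraction; zero-variance always goes
        n_drop = int(np.floor(self.remove_var_fraction * p))
        order = np.argsort(var, kind="stable")
        drop = set(order[:n_drop].tolist()) | set(np.flatnonzero(var == 0).tolist())
        keep = np.array([j for j in range(p) if j not in drop], dtype=int)
        if keep.size == 0:
            raise ValueError("variance filter removed every site")

        Xk = X[:, keep]
        self.mean_ = Xk.mean(axis=0) if self.center else np.zeros(keep.size)
        Xc = Xk - self.mean_
        if self.scale:
            self.scale_ = Xc.std(axis=0, ddof=1)
            self.scale_[self.scale_ == 0] = 1.0
            Xc = Xc / self.scale_
        else:
            self.scale_ = np.ones(keep.size)

        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        # sign convention: the largest-magnitude loading of each component
        # is positive
        for k in range(Vt.shape[0]):
            j = np.argmax(np.abs(Vt[k]))
            if Vt[k, j] < 0:
                Vt[k] *= -1
                U[:, k] *= -1
        self.kept_sites_ = keep
        self.loadings_ = Vt.T
        self.scores_ = U * s
        tot = (s ** 2).sum()
        self.variance_explained_ = (s ** 2) / tot
        self.singular_values_ = s
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "loadings_")
        X = np.asarray(X, dtype=float)
        Xc = (X[:, self.kept_sites_] - self.mean_) / self.scale_
        return Xc @ self.loadings_


def pca(levels: pd.DataFrame | np.ndarray, remove_var_fraction: float = 0.1,
        center: bool = True, scale: bool = False) -> MethylPCA:
    """Fit :class:`MethylPCA` on a sites x samples matrix (transposed in)."""
    X = (levels.to_numpy(dtype=float) if isinstance(levels, pd.DataFrame)
         else np.asarray(levels, dtype=float))
    return MethylPCA(remove_var_fraction, center, scale).fit(X.T)


def pc_age_correlation(scores: np.ndarray, ages: Sequence[float]) -> np.ndarray:
    """Squared Pearson correlation of each component's scores with age.

    Constant components give NaN.
    """
    scores = np.asarray(scores, dtype=float)
    ages = np.asarray(ages, dtype=float)
    out = np.full(scores.shape[1], np.nan)
    for k in range(scores.shape[1]):
        s = scores[:, k]
        if np.std(s) == 0 or np.std(ages) == 0:
            continue
        out[k] = np.corrcoef(s, ages)[0, 1] ** 2
    return out


def sample_correlation_cluster(
    levels: pd.DataFrame,
    method: str = "spearman",
    linkage: str = "complete",
    k: int | None = None,
) -> dict:
    """Sample–sample correlation heat-map structure.

    Correlates samples (columns of the sites x samples matrix) by Spearman
    (default) or Pearson, converts to distance 1 − r, and clusters by the
    requested linkage. Leaf order is made deterministic by seriating on the
    distance matrix with sample_id tie-breaks (columns are pre-sorted by id
    before linkage). Returns the correlation matrix, the scipy linkage
    matrix, the leaf order, flat labels at ``k`` (if given) and the
    dendrogram in Newick form.
    """
    if levels.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    const = levels.std(axis=0) == 0
    if const.any():
        bad = list(levels.columns[const])
        raise ValueError(f"constant methylation column(s): {bad}")
    levels = levels[sorted(levels.columns)]
    corr = levels.corr(method=method)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    out = {
        "correlation": corr,
        "linkage": Z,
        "leaf_order": [corr.columns[i] for i in leaves],
        "newick": _linkage_to_newick(Z, list(corr.columns)),
    }
    if k is not None:
        out["labels"] = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return out


def _linkage_to_newick(Z: np.ndarray, names: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"


def top_variable_sites(levels: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """The n sites of largest cross-sample variance, ties by genomic order.

    Input and output are sites x samples; the output preserves genomic
    order restricted to the chosen sites' variance ranking.
    """
    if n > levels.shape[0]:
        raise ValueError(f"n={n} exceeds {levels.shape[0]} sites")
    var = levels.var(axis=1, ddof=1).to_numpy()
    # stable sort on -variance keeps genomic (input) order within ties
    order = np.argsort(-var, kind="stable")[:n]
    return levels.iloc[order]


def site_cluster(levels: pd.DataFrame, linkage: str = "complete",
                 k: int = 5, ages: Sequence[float] | None = None) -> dict:
    """Complete-linkage clustering of sites on their level vectors.

    Euclidean distance between sites' cross-sample level vectors, cut at
    ``k`` flat clusters. When ``ages`` is given, each cluster also reports
    its mean age-trend direction (mean per-site slope sign of level vs
    age), separating falling from rising clusters.

    Returns labels (1..k per site), the linkage matrix, cluster sizes and
    the per-cluster trend table.
    """
    n_sites = levels.shape[0]
    if k > n_sites:
        raise ValueError(f"k={k} exceeds {n_sites} sites")
    X = levels.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    out = {
        "labels": labels,
        "linkage": Z,
        "sizes": pd.Series(labels).value_counts().sort_index().to_dict(),
    }
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        ac = ages - ages.mean()
        slopes = (X - X.mean(axis=1, keepdims=True)) @ ac / (ac ** 2).sum()
        trend = pd.DataFrame({"cluster": labels, "slope": slopes})
        out["trend"] = trend.groupby("cluster")["slope"].agg(
            mean_slope="mean",
            fraction_rising=lambda s: float((s > 0).mean()),
        )
    return out
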
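"""Elastic-net epigenetic clock with leave-one-out cross-validation.

The clock is a penalized linear regression of chronological age on CpG
methylation fractions, minimizing

    (1 / 2n) * ||y - Xw - b||^2
        + alpha * l1_ratio * ||w||_1
        + 0.5 * alpha * (1 - l1_ratio) * ||w||^2

— the scikit-learn ElasticNet convention, under which the reference
hyperparameters alpha = 0.00283693 and l1_ratio = 0.5 are meaningful.
Note alpha is convention-dependent: the same fit under glmnet's
parameterization would carry a different number.

Features are raw methylation fractions (no standardization by default; a
switch exists). Performance is assessed by LOOCV: each sample's age is
predicted by a model trained on the remaining n−1, and the n held-out
predictions are summarized by MAE (years) and R² — reported both as the
squared Pearson correlation of predicted vs actual age and as the
coefficient of determination, which differ for biased predictions. The
union of sites with nonzero weight in at least one fold is the clock's
feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.utils.validation import check_is_fitted

from .association import CaptureRegion

__all__ = [
    "EpigeneticClock",
    "ClockEvaluation",
    "elastic_net_fit",
    "loocv_predict",
    "grid_search_hyperparams",
    "feature_overlap",
]

#: Reference hyperparameters from the original nine-frog grid search.
DEFAULT_ALPHA = 0.00283693
DEFAULT_L1_RATIO = 0.5


class EpigeneticClock(RegressorMixin, BaseEstimator):
    """Elastic-net age predictor over a samples x sites level matrix.

    Parameters
    ----------
    alpha : float
        Overall penalty strength in the (1/2n) objective convention.
    l1_ratio : float
        L1/L2 mix in [0, 1]; 0.5 is the reference value.
    standardize : bool
        Z-score features before fitting (off by default; weights are
        reported on the original scale either way).
    tol, max_iter :
        Coordinate-descent convergence controls. Feature order is fixed
        (no random selection), so fits are reproducible bit-for-bit.

    Attributes
    ----------
    intercept_ : float
    coef_ : (n_sites,) weights, mostly exactly zero.
    nonzero_sites_ : integer indices of sites with nonzero weight.
    feature_index_ : the site index supplied at fit time, if any.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA,
                 l1_ratio: float = DEFAULT_L1_RATIO,
                 standardize: bool = False,
                 tol: float = 1e-6, max_iter: int = 500_000):
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, feature_index: pd.Index | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be samples x sites matching y")
        if X.shape[0] < 2:
            raise ValueError("need >= 2 samples")
        if np.isnan(X).any():
            raise ValueError("X has missing cells; the matrix must be complete")

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Xf = (X - mu) / sd
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
            Xf = X

        if self.alpha == 0:
            # exact unpenalized limit: least squares, bypassing coordinate
            # descent (which is ill-posed at alpha = 0)
            A = np.column_stack([np.ones(Xf.shape[0]), Xf])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            intercept, w = beta[0], beta[1:]
        else:
            est = ElasticNet(alpha=self.alpha, l1_ratio=self.l1_ratio,
                             fit_intercept=True, tol=self.tol,
                             max_iter=self.max_iter, selection="cyclic")
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    est.fit(Xf, y)
                except ConvergenceWarning as cw:
                    raise RuntimeError(
                        f"elastic net did not converge in {self.max_iter} "
                        f"iterations: {cw}") from cw
            intercept, w = float(est.intercept_), est.coef_.copy()

        # report weights on the original feature scale
        self.coef_ = w / sd
        self.intercept_ = float(intercept - (self.coef_ * mu).sum())
        self.nonzero_sites_ = np.flatnonzero(self.coef_ != 0)
        self.feature_index_ = feature_index
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def objective(self, X, y) -> float:
        """Value of the penalized objective at the fitted solution."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        n = y.size
        w = self.coef_
        return float(
            (resid ** 2).sum() / (2 * n)
            + self.alpha * self.l1_ratio * np.abs(w).sum()
            + 0.5 * self.alpha * (1 - self.l1_ratio) * (w ** 2).sum()
        )

    def to_frame(self) -> pd.DataFrame:
        """Nonzero weights as a (site, weight) table."""
        check_is_fitted(self, "coef_")
        idx = self.nonzero_sites_
        sites = (self.feature_index_[idx] if self.feature_index_ is not None
                 else idx)
        return pd.DataFrame({"site": list(sites), "weight": self.coef_[idx]})


def elastic_net_fit(X, y, alpha: float = DEFAULT_ALPHA,
                    l1_ratio: float = DEFAULT_L1_RATIO,
                    **kwargs) -> EpigeneticClock:
    """Fit one elastic-net clock (thin wrapper over EpigeneticClock)."""
    return EpigeneticClock(alpha=alpha, l1_ratio=l1_ratio, **kwargs).fit(X, y)


@dataclass
class ClockEvaluation:
    """LOOCV summary: held-out predictions, metrics, per-fold models."""

    sample_ids: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    mae: float                      # mean absolute error, years
    r2_pearson: float               # squared Pearson corr(predicted, actual)
    r2_cod: float                   # coefficient of determination
    fold_models: list[EpigeneticClock]
    feature_union: pd.DataFrame     # site, fold_count for every site used

    @property
    def n_distinct_features(self) -> int:
        return len(self.feature_union)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": self.sample_ids,
            "actual_age": self.actual,
            "predicted_age": self.predicted,
        })


def loocv_predict(X, y, alpha: float = DEFAULT_ALPHA,
                  l1_ratio: float = DEFAULT_L1_RATIO,
                  sample_ids: Sequence[str] | None = None,
                  feature_index: pd.Index | None = None,
                  **kwargs) -> ClockEvaluation:
    """Leave-one-out cross-validated clock evaluation.

    Fits n models, each on n−1 samples, predicting the held-out one.
    ``feature_union`` lists every site with nonzero weight in >= 1 fold,
    with the number of folds that used it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("LOOCV needs >= 3 samples")
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]

    preds = np.empty(n)
    models: list[EpigeneticClock] = []
    fold_counts = np.zeros(X.shape[1], dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = EpigeneticClock(alpha=alpha, l1_ratio=l1_ratio, **kwargs)
        try:
            model.fit(X[mask], y[mask], feature_index=feature_index)
        except Exception as exc:
            raise RuntimeError(f"LOOCV fold for sample {ids[i]} failed: {exc}"
                               ) from exc
        preds[i] = model.predict(X[[i]])[0]
        fold_counts[model.nonzero_sites_] += 1
        models.append(model)

    mae = float(np.abs(preds - y).mean())
    if np.std(preds) == 0 or np.std(y) == 0:
        r2p = float("nan")
    else:
        r2p = float(np.corrcoef(preds, y)[0, 1] ** 2)
    ss_res = float(((y - preds) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2c = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    used = np.flatnonzero(fold_counts)
    sites = feature_index[used] if feature_index is not None else used
    union = pd.DataFrame({"site": list(sites), "fold_count": fold_counts[used]})
    return ClockEvaluation(
        sample_ids=ids, actual=y, predicted=preds, mae=mae,
        r2_pearson=r2p, r2_cod=r2c, fold_models=models, feature_union=union)


def grid_search_hyperparams(
    X, y,
    alpha_grid: Sequence[float],
    l1_grid: Sequence[float] = (DEFAULT_L1_RATIO,),
    **kwargs,
) -> tuple[float, float]:
    """LOOCV grid search for (alpha, l1_ratio) minimizing mean squared error.

    Ties break toward larger alpha (the sparser model), then larger
    l1_ratio.
    """
    if not len(alpha_grid) or not len(l1_grid):
        raise ValueError("grids must be non-empty")
    y = np.asarray(y, dtype=float)
    best: tuple[float, float, float] | None = None
    for alpha in alpha_grid:
        for l1 in l1_grid:
            ev = loocv_predict(X, y, alpha=alpha, l1_ratio=l1, **kwargs)
            mse = float(((ev.predicted - y) ** 2).mean())
            cand = (mse, -alpha, -l1)
            if best is None or cand < (best[0], -best[1], -best[2]):
                best = (mse, alpha, l1)
    return best[1], best[2]


def feature_overlap(
    feature_union: pd.DataFrame,
    regions: Sequence[CaptureRegion],
    sites: Sequence[tuple[str, int]] | None = None,
) -> dict:
    """Partition clock features by capture-region membership.

    ``feature_union`` is the loocv_predict output; ``sites`` supplies the
    (chrom, 1-based pos) of each union member when the union's ``site``
    column is not already such tuples. Membership is point-in-interval on
    the 0-based half-open region coordinates. Returns counts inside /
    outside plus the fold-count distribution split by membership.
    """
    if sites is None:
        sites = [tuple(s) if not isinstance(s, tuple) else s
                 for s in feature_union["site"]]
    by_chrom: dict[str, list[CaptureRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    inside_mask = []
    for chrom, pos in sites:
        p = pos - 1
        inside_mask.append(any(r.start <= p < r.end
                               for r in by_chrom.get(chrom, ())))
    inside_mask = np.asarray(inside_mask, dtype=bool)
    folds = feature_union["fold_count"].to_numpy()
    return {
        "n_union": len(sites),
        "n_inside": int(inside_mask.sum()),
        "n_outside": int((~inside_mask).sum()),
        "fraction_inside": float(inside_mask.mean()) if len(sites) else float("nan"),
        "fold_count_inside": pd.Series(folds[inside_mask]).value_counts().to_dict(),
        "fold_count_outside": pd.Series(folds[~inside_mask]).value_counts().to_dict(),
    }
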
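"""Per-site age-association testing and capture-panel construction.

Each CpG site is tested two ways against the cohort's ages: Pearson
correlation with numeric age in years (two-sided t-based p-value) and a
one-way ANOVA across the age-group labels. Both p-value sets are
Benjamini–Hochberg adjusted; sites are ranked by the sum of their two
adjusted-p ranks and the top N (4500 in the original capture design)
flagged for probe design. Selected sites are merged into padded capture
regions and annotated with their nearest genomic element (bedtools-closest
semantics: all equidistant ties reported).

The fit/transform surface is :class:`AgeAssociationSelector`; the
module-level functions are the underlying steps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .io import GenomicElement

__all__ = [
    "site_age_stats",
    "adjust_pvalues",
    "rank_and_select",
    "collapse_to_regions",
    "annotate_nearest_element",
    "AgeAssociationSelector",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "pearson_r", "pearson_p", "anova_F", "anova_p",
    "adj_p_pearson", "adj_p_anova", "combined_rank", "selected",
]


def site_age_stats(
    levels: pd.DataFrame | np.ndarray,
    ages: Sequence[float],
    groups: Sequence[str],
) -> pd.DataFrame:
    """Pearson-vs-age and one-way-ANOVA-across-groups statistics per site.

    ``levels`` is sites x samples. Zero-variance sites get NaN statistics
    (they carry no age information and are excluded from ranking); their
    count is logged. Vectorized over sites; p-values from the t and F
    distributions.
    """
    X = np.asarray(levels, dtype=float)
    ages = np.asarray(ages, dtype=float)
    groups = np.asarray(groups)
    n = ages.size
    if X.shape[1] != n:
        raise ValueError("levels and ages disagree on sample count")
    if n < 3:
        raise ValueError("need >= 3 samples")
    if np.ptp(ages) == 0:
        raise ValueError("ages are constant; correlation with age undefined")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need >= 2 age groups for ANOVA")

    xc = X - X.mean(axis=1, keepdims=True)
    yc = ages - ages.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    zero_var = sx == 0
    if zero_var.any():
        logger.info("site_age_stats: %d zero-variance site(s) excluded "
                    "from ranking", int(zero_var.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df_t = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df_t / (1.0 - r ** 2))
    pearson_p = 2.0 * sps.t.sf(np.abs(t), df_t)
    pearson_p = np.where(np.isclose(np.abs(r), 1.0), 0.0, pearson_p)

    # one-way ANOVA: between/within mean squares across group labels
    k = uniq.size
    grand = X.mean(axis=1)
    ss_between = np.zeros(X.shape[0])
    ss_within = np.zeros(X.shape[0])
    for g in uniq:
        sel = groups == g
        m = X[:, sel].mean(axis=1)
        ss_between += sel.sum() * (m - grand) ** 2
        ss_within += ((X[:, sel] - m[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n - k
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    anova_p = sps.f.sf(F, df_b, df_w)
    anova_p = np.where(np.isinf(F), 0.0, anova_p)

    r[zero_var] = np.nan
    pearson_p[zero_var] = np.nan
    F[zero_var] = np.nan
    anova_p[zero_var] = np.nan

    index = (levels.index if isinstance(levels, pd.DataFrame)
             else pd.RangeIndex(X.shape[0]))
    return pd.DataFrame(
        {"pearson_r": r, "pearson_p": pearson_p,
         "anova_F": F, "anova_p": anova_p},
        index=index,
    )


def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg (default) adjustment; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method=method)[1]
    return out


def rank_and_select(results: pd.DataFrame, top_n: int = 4500) -> pd.DataFrame:
    """Rank sites by the sum of the two adjusted-p ranks; flag the top N.

    Both criteria (correlation and ANOVA) are treated symmetrically:
    combined_rank is the rank-sum of the ascending ranks of adj_p_pearson
    and adj_p_anova. Ties break by smaller adj_p_pearson, then genomic
    order, so the output is deterministic. Sites with NaN statistics
    (zero variance) are never selected. Adds adj_p_pearson / adj_p_anova
    if absent.
    """
    out = results.copy()
    if "adj_p_pearson" not in out:
        out["adj_p_pearson"] = adjust_pvalues(out["pearson_p"])
    if "adj_p_anova" not in out:
        out["adj_p_anova"] = adjust_pvalues(out["anova_p"])

    valid = ~(out["adj_p_pearson"].isna() | out["adj_p_anova"].isna())
    rank_p = out.loc[valid, "adj_p_pearson"].rank(method="average")
    rank_a = out.loc[valid, "adj_p_anova"].rank(method="average")
    rank_sum = rank_p + rank_a

    out["combined_rank"] = np.nan
    order = pd.DataFrame({
        "rank_sum": rank_sum,
        "adj_p_pearson": out.loc[valid, "adj_p_pearson"],
        "genomic": np.arange(valid.sum()),
    }).sort_values(["rank_sum", "adj_p_pearson", "genomic"], kind="stable")
    out.loc[order.index, "combined_rank"] = np.arange(1, len(order) + 1, dtype=float)

    n_valid = int(valid.sum())
    if top_n > n_valid:
        warnings.warn(
            f"top_n={top_n} exceeds the {n_valid} rankable sites; "
            "selecting all of them", stacklevel=2)
        top_n = n_valid
    out["selected"] = out["combined_rank"] <= top_n
    return out


@dataclass(frozen=True)
class CaptureRegion:
    """A merged, padded interval of selected age-associated sites."""

    chrom: str
    start: int
    end: int
    member_sites: tuple[int, ...]        # 1-based member positions
    direction_summary: float             # fraction of members with r > 0

    def __len__(self) -> int:
        return self.end - self.start


def collapse_to_regions(
    selected: pd.DataFrame,
    merge_gap_bp: int = 200,
    pad_bp: int = 60,
) -> list[CaptureRegion]:
    """Merge selected sites within ``merge_gap_bp`` and pad by ``pad_bp``.

    ``selected`` needs a (chrom, pos, ...) index and a pearson_r column.
    Regions are 0-based half-open, non-overlapping after the merge (padding
    that would re-introduce overlap is re-merged), and clipped at 0.
    """
    sites = selected.reset_index()[["chrom", "pos", "pearson_r"]]
    sites = sites.sort_values(["chrom", "pos"], kind="stable")
    regions: list[CaptureRegion] = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        positions = grp["pos"].to_numpy()
        rs = grp["pearson_r"].to_numpy()
        runs: list[list[int]] = [[0]]
        for i in range(1, len(positions)):
            if positions[i] - positions[i - 1] <= merge_gap_bp:
                runs[-1].append(i)
            else:
                runs.append([i])
        merged: list[tuple[int, int, list[int]]] = []
        for run in runs:
            p0, p1 = positions[run[0]], positions[run[-1]]
            start = max(0, p0 - 1 - pad_bp)
            end = p1 + pad_bp
            if merged and start < merged[-1][1]:
                prev = merged.pop()
                merged.append((prev[0], end, prev[2] + run))
            else:
                merged.append((start, end, list(run)))
        for start, end, idxs in merged:
            regions.append(
                CaptureRegion(
                    chrom=chrom, start=int(start), end=int(end),
                    member_sites=tuple(int(positions[i]) for i in idxs),
                    direction_summary=float((rs[idxs] > 0).mean()),
                )
            )
    return regions


def regions_to_elements(regions: Sequence[CaptureRegion]) -> list[GenomicElement]:
    return [
        GenomicElement(r.chrom, r.start, r.end, ".", "target_region",
                       f"region_{i + 1}")
        for i, r in enumerate(regions)
    ]


def annotate_nearest_element(
    sites: Sequence[tuple[str, int]],
    elements: Sequence[GenomicElement],
) -> pd.DataFrame:
    """Nearest gene/repeat per site with all equidistant ties reported.

    Distance is 0 when the site (1-based point) lies inside an element,
    otherwise the bp gap to the nearest boundary. A site on a chromosome
    with no elements gets a row with NaN distance (and is logged). Columns:
    chrom, pos, element_name, element_kind, distance.
    """
    by_chrom: dict[str, list[GenomicElement]] = {}
    for el in elements:
        by_chrom.setdefault(el.chrom, []).append(el)
    rows = []
    n_orphan = 0
    for chrom, pos in sites:
        els = by_chrom.get(chrom)
        if not els:
            rows.append((chrom, pos, None, None, np.nan))
            n_orphan += 1
            continue
        p = pos - 1  # 0-based point
        best = None
        ties: list[GenomicElement] = []
        for el in els:
            if el.start <= p < el.end:
                d = 0
            elif p < el.start:
                d = el.start - p
            else:
                d = p - (el.end - 1)
            if best is None or d < best:
                best, ties = d, [el]
            elif d == best:
                ties.append(el)
        for el in ties:
            rows.append((chrom, pos, el.name, el.kind, best))
    if n_orphan:
        logger.warning("annotate_nearest_element: %d site(s) on chromosomes "
                       "with no annotation", n_orphan)
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "element_name", "element_kind", "distance"])


class AgeAssociationSelector(SelectorMixin, BaseEstimator):
    """Select age-associated CpG sites by Pearson + ANOVA rank-sum.

    A scikit-learn feature selector over a samples x sites methylation
    matrix. ``fit(X, y)`` takes ages as ``y`` (years) and age-group labels
    via ``groups`` (defaulting to one group per distinct age); ``transform``
    keeps the selected sites' columns.

    Parameters
    ----------
    top_n : int, default 4500
        Number of sites to flag, the size of the original capture design.

    Attributes
    ----------
    results_ : DataFrame with per-site statistics, adjusted p-values,
        combined_rank and the selected flag.
    support_ : boolean mask of selected columns.
    """

    def __init__(self, top_n: int = 4500):
        self.top_n = top_n

    def fit(self, X, y, groups: Sequence[str] | None = None,
            feature_index: pd.Index | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if groups is None:
            groups = np.asarray([str(a) for a in y])
        res = site_age_stats(
            pd.DataFrame(X.T, index=feature_index) if feature_index is not None
            else X.T,
            y, groups)
        res = rank_and_select(res, top_n=self.top_n)
        self.results_ = res
        self.support_ = res["selected"].to_numpy(dtype=bool)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags
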
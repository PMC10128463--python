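"""Global methylome descriptors.

Context-level mean methylation (the per-sample CpG / CpA / CpC / CpT table),
level distributions with the bimodal-methylome summary fractions,
chromosome tracks in fixed-width bins, two-sample Kolmogorov–Smirnov
comparison of pooled age groups, and neighbor-rank autocorrelation of CpG
levels (correlation between the i-th and (i+k)-th CpG in genomic order,
k = 1..20 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MethylationRecord

__all__ = [
    "context_means",
    "level_histogram",
    "LevelHistogram",
    "chromosome_bins",
    "BinTrack",
    "ks_compare",
    "neighbor_autocorrelation",
]

DINUC_ORDER = ["CG", "CA", "CC", "CT"]


def context_means(
    records: Sequence[MethylationRecord],
    coverage_floor: int = 1,
) -> pd.Series:
    """Mean methylation percent per dinucleotide context for one sample.

    Unweighted mean of per-site levels x 100 over sites with
    total_count >= coverage_floor, reported for CpG, CpA, CpC, CpT.
    Absent contexts give NaN.
    """
    sums = dict.fromkeys(DINUC_ORDER, 0.0)
    ns = dict.fromkeys(DINUC_ORDER, 0)
    for r in records:
        if r.total_count < coverage_floor:
            continue
        d = r.dinucleotide
        if d in sums:
            sums[d] += r.meth_count / r.total_count
            ns[d] += 1
    out = pd.Series(
        {d: (100.0 * sums[d] / ns[d]) if ns[d] else np.nan for d in DINUC_ORDER},
        name="mean_5mC_percent",
    )
    out.index.name = "dinucleotide"
    return out


@dataclass
class LevelHistogram:
    """Binned density of methylation levels plus headline fractions."""

    bin_edges: np.ndarray
    density: np.ndarray          # sums to 1 together with the point masses
    mass_exact_zero: float
    mass_exact_one: float
    fraction_above_080: float
    fraction_below_005: float
    n: int


def level_histogram(
    values: Iterable[float],
    bin_edges: Sequence[float] | None = None,
) -> LevelHistogram:
    """Distribution of methylation levels over [0, 1].

    Default 20 equal bins; the exact-0 and exact-1 point masses are reported
    separately (and excluded from the interior bins). Also reports the
    fraction of sites above 0.80 and below 0.05 — the summary in which a
    vertebrate methylome shows ~70% of CpGs highly methylated and a few
    percent unmethylated.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("level_histogram: empty input")
    if (v < 0).any() or (v > 1).any():
        raise ValueError("levels must lie in [0, 1]")
    edges = np.asarray(bin_edges if bin_edges is not None
                       else np.linspace(0.0, 1.0, 21), dtype=float)
    is_zero = v == 0.0
    is_one = v == 1.0
    interior = v[~is_zero & ~is_one]
    counts, _ = np.histogram(interior, bins=edges)
    n = v.size
    return LevelHistogram(
        bin_edges=edges,
        density=counts / n,
        mass_exact_zero=is_zero.mean(),
        mass_exact_one=is_one.mean(),
        fraction_above_080=(v > 0.80).mean(),
        fraction_below_005=(v < 0.05).mean(),
        n=n,
    )


@dataclass(frozen=True)
class BinTrack:
    """Mean methylation in one fixed-width chromosome bin (0-based start)."""

    chrom: str
    bin_start: int
    mean_level: float  # NaN when the bin holds no qualifying site
    n_sites: int


def chromosome_bins(
    records: Sequence[MethylationRecord],
    bin_size: int = 500_000,
    coverage_floor: int = 3,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[BinTrack]:
    """Chromosome methylation track: mean CpG level per fixed-width bin.

    Bins tile each chromosome in 0-based half-open windows of ``bin_size``
    (default 500 kb). Lengths default to the maximum observed position per
    chromosome. Bins with no qualifying CG site carry NaN.
    """
    per_chrom: dict[str, list[MethylationRecord]] = {}
    for r in records:
        if r.context != "CG" or r.total_count < coverage_floor:
            continue
        per_chrom.setdefault(r.chrom, []).append(r)

    lengths = dict(chrom_lengths) if chrom_lengths else {
        chrom: max(r.pos for r in recs) for chrom, recs in per_chrom.items()
    }
    tracks: list[BinTrack] = []
    for chrom in sorted(lengths):
        n_bins = int(np.ceil(lengths[chrom] / bin_size))
        sums = np.zeros(n_bins)
        ns = np.zeros(n_bins, dtype=int)
        for r in per_chrom.get(chrom, ()):
            b = (r.pos - 1) // bin_size
            if b < n_bins:
                sums[b] += r.meth_count / r.total_count
                ns[b] += 1
        for b in range(n_bins):
            tracks.append(
                BinTrack(
                    chrom=chrom,
                    bin_start=b * bin_size,
                    mean_level=sums[b] / ns[b] if ns[b] else float("nan"),
                    n_sites=int(ns[b]),
                )
            )
    return tracks


def bins_to_bedgraph(tracks: Sequence[BinTrack], path, bin_size: int = 500_000):
    """Export a bin track as bedGraph (bins without sites are skipped)."""
    with open(path, "w") as fh:
        for t in tracks:
            if t.n_sites > 0:
                fh.write(f"{t.chrom}\t{t.bin_start}\t{t.bin_start + bin_size}"
                         f"\t{t.mean_level:.6g}\n")
    return path


def ks_compare(levels_a: Sequence[float], levels_b: Sequence[float]
               ) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of two level sets.

    D is the supremum ECDF distance; the p-value uses the asymptotic
    two-sample distribution, adequate at methylome site counts.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("ks_compare needs >= 2 values per group")
    res = sps.ks_2samp(a, b, mode="asymp")
    return float(res.statistic), float(res.pvalue)


def neighbor_autocorrelation(
    records: Sequence[MethylationRecord],
    max_lag: int = 20,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Autocorrelation of CpG levels over the k closest CpG neighbors.

    For each lag k = 1..max_lag, the Pearson correlation between the level
    of the i-th CpG and the (i+k)-th CpG in genomic order, pooled over
    chromosomes (pairs never span a chromosome boundary). Lags with fewer
    than ``min_pairs`` pairs, or zero variance in either margin, give NaN.

    Returns a DataFrame with columns lag, correlation, n_pairs.
    """
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    for r in records:
        if r.context != "CG":
            continue
        per_chrom.setdefault(r.chrom, []).append(
            (r.pos, r.meth_count / r.total_count))
    series = []
    for chrom in per_chrom:
        per_chrom[chrom].sort()
        series.append(np.array([lv for _, lv in per_chrom[chrom]]))

    rows = []
    for lag in range(1, max_lag + 1):
        xs, ys = [], []
        for s in series:
            if s.size > lag:
                xs.append(s[:-lag])
                ys.append(s[lag:])
        if not xs:
            rows.append((lag, np.nan, 0))
            continue
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        n = x.size
        if n < min_pairs or x.std() == 0 or y.std() == 0:
            rows.append((lag, np.nan, n))
        else:
            rows.append((lag, float(np.corrcoef(x, y)[0, 1]), n))
    return pd.DataFrame(rows, columns=["lag", "correlation", "n_pairs"])
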
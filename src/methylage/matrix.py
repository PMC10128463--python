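"""Common-site methylation matrices, age-group pooling, region coverage.

A "common" site is one whose read coverage reaches the floor in *every*
sample of the cohort; the study design builds such matrices at floors of
3x and 5x (whole-genome), 10x (group-level statistics) and 100x (targeted
capture data). Cells hold per-sample methylation fractions; the coverage
that justified each cell is retained alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenomicElement, MethylationRecord, SampleMeta, read_cgmap

__all__ = [
    "MethylMatrix",
    "build_common_matrix",
    "pool_group",
    "region_mean_coverage",
]

SITE_COLUMNS = ["chrom", "pos", "context"]


@dataclass
class MethylMatrix:
    """Sites x samples methylation-level matrix with coverage provenance.

    ``levels`` and ``coverage`` are DataFrames indexed by a (chrom, pos,
    context) MultiIndex sorted by (chrom, pos), one column per sample_id.
    ``coverage_floor`` is the threshold every retained cell satisfies.
    """

    levels: pd.DataFrame
    coverage: pd.DataFrame
    coverage_floor: int
    context_filter: str = "CG"

    @property
    def site_index(self) -> pd.MultiIndex:
        return self.levels.index

    @property
    def sample_index(self) -> list[str]:
        return list(self.levels.columns)

    @property
    def n_sites(self) -> int:
        return self.levels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.levels.shape[1]

    def values(self) -> np.ndarray:
        """Sites x samples float array of methylation fractions."""
        return self.levels.to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> Path:
        """Serialize as TSV: chrom, pos, context, then one column per sample."""
        path = Path(path)
        out = self.levels.reset_index()
        out.columns = SITE_COLUMNS + self.sample_index
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, coverage_floor: int = 0,
                 context_filter: str = "CG") -> "MethylMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
        df = df.set_index(SITE_COLUMNS)
        cov = pd.DataFrame(np.nan, index=df.index, columns=df.columns)
        return cls(levels=df, coverage=cov, coverage_floor=coverage_floor,
                   context_filter=context_filter)

    def subset_sites(self, mask_or_index) -> "MethylMatrix":
        return MethylMatrix(
            levels=self.levels.loc[mask_or_index],
            coverage=self.coverage.loc[mask_or_index],
            coverage_floor=self.coverage_floor,
            context_filter=self.context_filter,
        )


def _records_to_frame(records: Sequence[MethylationRecord], context: str | None
                      ) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.context, r.meth_count, r.total_count)
        for r in records
        if context is None or r.context == context
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "context", "meth", "total"])


def build_common_matrix(
    samples: Sequence[SampleMeta],
    coverage_floor: int = 5,
    context: str = "CG",
    records_by_sample: Mapping[str, Sequence[MethylationRecord]] | None = None,
    min_samples: int | None = None,
) -> MethylMatrix:
    """Build the common-site matrix across a cohort at a coverage floor.

    A site survives only if its total read count reaches ``coverage_floor``
    in all samples (or in at least ``min_samples`` of them when the any-k
    relaxation is requested). Records are read from each sample's
    ``cgmap_path`` unless supplied via ``records_by_sample``.

    Returns an empty matrix (with a warning) rather than raising when no
    site survives.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to build a common matrix")
    if coverage_floor < 1:
        raise ValueError("coverage_floor must be >= 1")
    need = len(samples) if min_samples is None else min_samples

    frames = []
    for s in samples:
        recs = (records_by_sample[s.sample_id] if records_by_sample is not None
                else read_cgmap(s.cgmap_path))
        df = _records_to_frame(recs, context)
        df = df[df["total"] >= coverage_floor]
        df = df.set_index(SITE_COLUMNS)
        if df.index.duplicated().any():
            raise ValueError(f"sample {s.sample_id}: duplicate sites in CGmap")
        frames.append(df)

    all_sites = frames[0].index
    counts = pd.Series(1, index=all_sites)
    for df in frames[1:]:
        counts = counts.add(pd.Series(1, index=df.index), fill_value=0)
    keep = counts.index[counts >= need]

    if len(keep) == 0:
        warnings.warn(
            f"no site reaches {coverage_floor}x coverage in all "
            f"{len(samples)} samples; returning an empty matrix",
            stacklevel=2,
        )
    levels = pd.DataFrame(index=keep, columns=[s.sample_id for s in samples],
                          dtype=float)
    coverage = levels.copy()
    for s, df in zip(samples, frames):
        sub = df.reindex(keep)
        levels[s.sample_id] = sub["meth"] / sub["total"]
        coverage[s.sample_id] = sub["total"]
    order = levels.index.to_frame(index=False).sort_values(["chrom", "pos"]).index
    levels = levels.iloc[order]
    coverage = coverage.iloc[order]
    levels.index.names = SITE_COLUMNS
    coverage.index.names = SITE_COLUMNS
    return MethylMatrix(levels=levels, coverage=coverage,
                        coverage_floor=coverage_floor, context_filter=context)


def pool_group(
    records_per_sample: Sequence[Sequence[MethylationRecord]],
) -> list[MethylationRecord]:
    """Pool one age group's samples by summing read counts per site.

    Per site, meth_count and total_count are summed across the group members
    and the level recomputed from the pooled counts — the desk equivalent of
    merging the group's alignments and re-calling methylation. Sites absent
    from some members still pool over the members that cover them.
    """
    if not records_per_sample:
        raise ValueError("pool_group needs at least one sample")
    pooled: dict[tuple, list] = {}
    for recs in records_per_sample:
        for r in recs:
            key = (r.chrom, r.pos, r.context, r.dinucleotide, r.base)
            if key in pooled:
                pooled[key][0] += r.meth_count
                pooled[key][1] += r.total_count
            else:
                pooled[key] = [r.meth_count, r.total_count]
    out = []
    for (chrom, pos, context, dinuc, base), (meth, total) in sorted(pooled.items()):
        out.append(
            MethylationRecord(
                chrom=chrom, base=base, pos=pos, context=context,
                dinucleotide=dinuc, level=meth / total,
                meth_count=meth, total_count=total,
            )
        )
    return out


def region_mean_coverage(
    records_by_sample: Mapping[str, Sequence[MethylationRecord]],
    regions: Sequence[GenomicElement],
    context: str = "CG",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean read coverage per capture region per sample.

    For each region, the mean total_count over CG sites with 1-based
    position falling in [start, end) (half-open on the 0-based interval,
    i.e. start < pos <= end in 1-based terms maps to start <= pos-1 < end).
    Regions with no sites report NaN. Also returns a per-sample on/off-target
    summary: the fraction of reads (total_count mass) on sites inside any
    region.

    Returns ``(per_region, summary)``: per_region is regions x samples;
    summary has columns on_target_reads, total_reads, on_target_fraction.
    """
    region_labels = [
        f"{r.chrom}:{r.start}-{r.end}" + (f":{r.name}" if r.name else "")
        for r in regions
    ]
    per_region = pd.DataFrame(index=region_labels,
                              columns=list(records_by_sample), dtype=float)
    summary = pd.DataFrame(
        index=list(records_by_sample),
        columns=["on_target_reads", "total_reads", "on_target_fraction"],
        dtype=float,
    )
    by_chrom: dict[str, list[GenomicElement]] = {}
    idx_of = {id(r): i for i, r in enumerate(regions)}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)

    for sample_id, recs in records_by_sample.items():
        sums = np.zeros(len(regions))
        ns = np.zeros(len(regions), dtype=int)
        on_target = 0
        total_reads = 0
        for rec in recs:
            if context is not None and rec.context != context:
                continue
            total_reads += rec.total_count
            zero_based = rec.pos - 1
            hit = False
            for region in by_chrom.get(rec.chrom, ()):
                if region.start <= zero_based < region.end:
                    i = idx_of[id(region)]
                    sums[i] += rec.total_count
                    ns[i] += 1
                    hit = True
            if hit:
                on_target += rec.total_count
        with np.errstate(invalid="ignore"):
            per_region[sample_id] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
        summary.loc[sample_id] = [
            on_target, total_reads,
            on_target / total_reads if total_reads else np.nan,
        ]
    return per_region, summary
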
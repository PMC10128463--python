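"""Metagene-style methylation profiles over genes and repeats.

Each element body is scaled into a fixed number of fractional bins
(deciles by default) measured TSS→TTS, i.e. strand-aware; flanks of fixed
genomic width are split into fixed-width bins. A CpG falling within an
element contributes one observation per element it overlaps; per-bin means
average over all (site, element) observations. Repeats shorter than a
length floor (1 kb for the repeat-body profile) can be excluded, and
strandless elements are profiled as if on the + strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomicElement, MethylationRecord

__all__ = ["ProfileResult", "metagene_profile"]


@dataclass
class ProfileResult:
    """Per-bin mean methylation with observation counts.

    ``table`` columns: bin_label, bin_index, mean_level, n_observations.
    Bin order: upstream flank (most distal first), body fractions, then
    downstream flank.
    """

    table: pd.DataFrame
    flank_bp: int
    body_bins: int
    flank_bin_bp: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    def body_means(self) -> np.ndarray:
        mask = self.table["bin_label"].str.startswith("body")
        return self.table.loc[mask, "mean_level"].to_numpy()


def _bin_labels(flank_bp: int, body_bins: int, flank_bin_bp: int) -> list[str]:
    nf = flank_bp // flank_bin_bp
    up = [f"up_{-(flank_bp - i * flank_bin_bp)}bp" for i in range(nf)]
    body = [f"body_{i + 1}of{body_bins}" for i in range(body_bins)]
    down = [f"down_+{i * flank_bin_bp}bp" for i in range(nf)]
    return up + body + down


def metagene_profile(
    records: Sequence[MethylationRecord],
    elements: Sequence[GenomicElement],
    flank_bp: int = 2000,
    body_bins: int = 10,
    flank_bin_bp: int = 200,
    min_element_length: int = 0,
    coverage_floor: int = 1,
) -> ProfileResult:
    """Average methylation along elements with scaled bodies and fixed flanks.

    A site inside an element maps to the body bin of its fractional
    position along the element (0 at the TSS, 1 at the TTS; minus-strand
    elements are traversed in reverse). Sites in the ``flank_bp`` upstream
    or downstream of an element map to fixed ``flank_bin_bp`` bins. Flanks
    are genomic — not clipped at neighboring elements — and a site
    overlapping several elements contributes once per element.
    """
    if flank_bp % flank_bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    for el in elements:
        if len(el) <= 0:
            raise ValueError(f"zero-length element {el.name or el.chrom}")
    kept = [el for el in elements if len(el) >= min_element_length]

    nf = flank_bp // flank_bin_bp
    n_bins = 2 * nf + body_bins
    sums = np.zeros(n_bins)
    ns = np.zeros(n_bins, dtype=int)

    sites_by_chrom: dict[str, list[tuple[int, float]]] = {}
    for r in records:
        if r.context != "CG" or r.total_count < coverage_floor:
            continue
        sites_by_chrom.setdefault(r.chrom, []).append(
            (r.pos - 1, r.meth_count / r.total_count))  # 0-based point
    for chrom in sites_by_chrom:
        sites_by_chrom[chrom].sort()

    for el in kept:
        sites = sites_by_chrom.get(el.chrom)
        if not sites:
            continue
        positions = np.array([p for p, _ in sites])
        levels = np.array([lv for _, lv in sites])
        lo, hi = el.start - flank_bp, el.end + flank_bp
        i0, i1 = np.searchsorted(positions, [lo, hi])
        minus = el.strand == "-"
        length = len(el)
        for p, lv in zip(positions[i0:i1], levels[i0:i1]):
            if p < el.start:           # genomically left of the element
                off = el.start - 1 - p          # 0 .. flank_bp-1 from edge
                fbin = nf - 1 - off // flank_bin_bp
                b = (n_bins - 1 - fbin) if minus else fbin
            elif p >= el.end:          # genomically right
                off = p - el.end
                fbin = off // flank_bin_bp
                b = (nf - 1 - fbin) if minus else (nf + body_bins + fbin)
            else:                      # inside the body
                frac = ((el.end - 1 - p) if minus else (p - el.start)) / length
                b = nf + min(int(frac * body_bins), body_bins - 1)
            sums[b] += lv
            ns[b] += 1

    with np.errstate(invalid="ignore"):
        means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    table = pd.DataFrame(
        {
            "bin_label": _bin_labels(flank_bp, body_bins, flank_bin_bp),
            "bin_index": np.arange(n_bins),
            "mean_level": means,
            "n_observations": ns,
        }
    )
    return ProfileResult(table=table, flank_bp=flank_bp, body_bins=body_bins,
                         flank_bin_bp=flank_bin_bp)
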
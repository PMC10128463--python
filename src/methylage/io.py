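"""Readers and writers for the text formats the pipeline touches.

CGmap is the per-cytosine methylation call format emitted by bisulfite
callers: eight tab-separated columns per line —

    chrom  base  pos  context  dinucleotide  level  meth_count  total_count

``pos`` is 1-based; ``base`` is the reference nucleotide on the reported
strand (``C`` for Watson-strand cytosines, ``G`` for Crick-strand ones);
``context`` is the three-letter class (CG / CHG / CHH) and ``dinucleotide``
the two-letter subcontext (CA / CC / CG / CT); ``level`` is the rounded
methylation fraction meth_count / total_count.

Genomic intervals (genes, repeats, capture targets) are held internally in
0-based half-open coordinates; the GFF reader converts from the 1-based
closed convention on the way in, the BED reader passes coordinates through
unchanged. These converters are the only place the two conventions meet.

Symmetric CpG dyads are NOT merged across strands by default: the reported
position of a Crick-strand cytosine is the G's own coordinate, and site
counts downstream are per reported position. An opt-in merge is provided.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges as pr

__all__ = [
    "MethylationRecord",
    "SampleMeta",
    "GenomicElement",
    "CgmapParseError",
    "read_cgmap",
    "write_cgmap",
    "merge_symmetric_cpg",
    "read_elements",
    "read_bed",
    "write_bed",
    "read_sample_sheet",
    "write_sample_sheet",
]

#: Rounding slack tolerated between a CGmap file's printed level column and
#: meth_count / total_count (callers print 2-6 decimals).
LEVEL_PRINT_TOL = 0.005

_CONTEXTS = frozenset({"CG", "CHG", "CHH"})
_DINUCS = frozenset({"CA", "CC", "CG", "CT"})


class CgmapParseError(ValueError):
    """A CGmap line could not be parsed; the message names the line number."""


@dataclass(frozen=True, slots=True)
class MethylationRecord:
    """One cytosine site in one sample."""

    chrom: str
    base: str           # reference nucleotide on the reported strand: C or G
    pos: int            # 1-based genomic position
    context: str        # CG | CHG | CHH
    dinucleotide: str   # CA | CC | CG | CT
    level: float        # methylation fraction in [0, 1]
    meth_count: int
    total_count: int

    def validate(self) -> None:
        if self.base not in ("C", "G"):
            raise ValueError(f"{self!r}: base must be C or G")
        if self.pos < 1:
            raise ValueError(f"{self!r}: pos must be 1-based (>= 1)")
        if self.context not in _CONTEXTS:
            raise ValueError(f"{self!r}: unknown context {self.context!r}")
        if self.dinucleotide not in _DINUCS:
            raise ValueError(f"{self!r}: unknown dinucleotide {self.dinucleotide!r}")
        if (self.context == "CG") != (self.dinucleotide == "CG"):
            raise ValueError(f"{self!r}: context CG <=> dinucleotide CG violated")
        if not (0 <= self.meth_count <= self.total_count):
            raise ValueError(f"{self!r}: need 0 <= meth_count <= total_count")
        if self.total_count < 1:
            raise ValueError(f"{self!r}: total_count must be >= 1")
        if abs(self.level - self.meth_count / self.total_count) > LEVEL_PRINT_TOL:
            raise ValueError(
                f"{self!r}: level inconsistent with meth_count/total_count"
            )


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """One cohort member: id, age in years, age-group label, strain, file."""

    sample_id: str
    age_years: float
    group: str
    strain: str = ""
    cgmap_path: str = ""

    def __post_init__(self) -> None:
        if self.age_years <= 0:
            raise ValueError(f"sample {self.sample_id}: age_years must be > 0")


@dataclass(frozen=True, slots=True)
class GenomicElement:
    """A gene, repeat or capture-target interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."      # '+', '-' or '.' (unknown; repeats often lack strand)
    kind: str = "region"   # gene | repeat | target_region | region
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"element {self.name or self.chrom}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# CGmap
# ---------------------------------------------------------------------------

def read_cgmap(path: str | Path) -> list[MethylationRecord]:
    """Read a CGmap file into records, preserving file order.

    Raises FileNotFoundError for a missing file and :class:`CgmapParseError`
    (naming the line) for a malformed one.
    """
    path = Path(path)
    records: list[MethylationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise CgmapParseError(
                    f"{path}:{lineno}: expected 8 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, base, pos_s, context, dinuc, level_s, meth_s, total_s = fields
            try:
                rec = MethylationRecord(
                    chrom=chrom,
                    base=base,
                    pos=int(pos_s),
                    context=context,
                    dinucleotide=dinuc,
                    level=float(level_s),
                    meth_count=int(meth_s),
                    total_count=int(total_s),
                )
                rec.validate()
            except ValueError as exc:
                raise CgmapParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_cgmap(records: Iterable[MethylationRecord], path: str | Path) -> Path:
    """Write records as 8-column CGmap; the level column is recomputed as
    meth_count / total_count so read∘write round-trips counts exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            rec.validate()
            level = rec.meth_count / rec.total_count
            fh.write(
                f"{rec.chrom}\t{rec.base}\t{rec.pos}\t{rec.context}\t"
                f"{rec.dinucleotide}\t{level:.6g}\t{rec.meth_count}\t"
                f"{rec.total_count}\n"
            )
    return path


def merge_symmetric_cpg(records: Sequence[MethylationRecord]) -> list[MethylationRecord]:
    """Optionally merge Watson/Crick CpG dyads (C at pos, G at pos+1) by
    summing counts onto the C position. Off the default path; non-CG records
    pass through untouched."""
    by_pos = {(r.chrom, r.pos): r for r in records if r.context == "CG"}
    out: list[MethylationRecord] = []
    consumed: set[tuple[str, int]] = set()
    for rec in records:
        if rec.context != "CG":
            out.append(rec)
            continue
        key = (rec.chrom, rec.pos)
        if key in consumed:
            continue
        if rec.base == "C":
            partner = by_pos.get((rec.chrom, rec.pos + 1))
            if partner is not None and partner.base == "G":
                meth = rec.meth_count + partner.meth_count
                total = rec.total_count + partner.total_count
                rec = replace(rec, meth_count=meth, total_count=total,
                              level=meth / total)
                consumed.add((rec.chrom, rec.pos + 1))
            out.append(rec)
        else:  # lone G-strand record: keep as is
            partner = by_pos.get((rec.chrom, rec.pos - 1))
            if partner is None or partner.base != "C":
                out.append(rec)
    return out


# ---------------------------------------------------------------------------
# GFF / BED
# ---------------------------------------------------------------------------

def read_elements(path: str | Path, source_kind: str) -> list[GenomicElement]:
    """Read gene or repeat intervals from GFF3/GFF.

    For ``source_kind='gene'`` only top-level ``gene`` features are kept
    (mRNA/exon children collapse into their parent gene); for ``'repeat'``
    every feature line is an element. pyranges converts GFF's 1-based closed
    coordinates to the internal 0-based half-open convention. Input order is
    not assumed sorted; output is sorted by (chrom, start, end).
    """
    if source_kind not in ("gene", "repeat"):
        raise ValueError(f"source_kind must be 'gene' or 'repeat', got {source_kind!r}")
    df = pr.read_gff3(str(path)).df
    if df.empty:
        return []
    if source_kind == "gene" and "Feature" in df.columns:
        df = df[df["Feature"] == "gene"]
    elements = []
    for row in df.itertuples(index=False):
        name = ""
        for attr in ("ID", "Name", "Target"):
            val = getattr(row, attr, None)
            if isinstance(val, str) and val:
                name = val
                break
        strand = getattr(row, "Strand", ".")
        if strand not in ("+", "-"):
            strand = "."
        elements.append(
            GenomicElement(
                chrom=str(row.Chromosome),
                start=int(row.Start),
                end=int(row.End),
                strand=strand,
                kind=source_kind,
                name=name,
            )
        )
    elements.sort(key=lambda e: (e.chrom, e.start, e.end))
    return elements


def read_bed(path: str | Path) -> list[GenomicElement]:
    """Read BED3+ target regions (0-based half-open, passed through)."""
    path = Path(path)
    elements: list[GenomicElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                elements.append(
                    GenomicElement(chrom, start, end, strand, "target_region", name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return elements


def write_bed(elements: Iterable[GenomicElement], path: str | Path) -> Path:
    """Write elements as BED4 (chrom, start, end, name)."""
    path = Path(path)
    with open(path, "w") as fh:
        for el in elements:
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\t{el.name or '.'}\n")
    return path


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "age_years", "group", "strain", "cgmap_path"]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the cohort CSV (sample_id, age_years, group, strain, cgmap_path)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group": str, "strain": str})
    missing = [c for c in ("sample_id", "age_years", "group") if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in {path}: {dupes}")
    samples = []
    for row in df.itertuples(index=False):
        samples.append(
            SampleMeta(
                sample_id=row.sample_id,
                age_years=float(row.age_years),
                group=row.group,
                strain=str(getattr(row, "strain", "") or ""),
                cgmap_path=str(getattr(row, "cgmap_path", "") or ""),
            )
        )
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for s in samples:
            writer.writerow([s.sample_id, s.age_years, s.group, s.strain, s.cgmap_path])
    return path
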
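"""Synthetic WGBS/TBSeq cohorts with known ground truth.

The generator emulates the statistical structure of a vertebrate skin
methylome aging cohort so that every pipeline stage can be exercised and
validated without the sequencing data:

* a bimodal baseline level distribution — most CpGs highly methylated
  (~70% of sites above 0.8), a small unmethylated mass (~3% below 0.05),
  the remainder spread — drawn from a three-component beta mixture;
* a planted subset of drift sites whose latent level moves linearly with
  age, the majority losing methylation (global hypomethylation with age)
  and a minority gaining it;
* spatially correlated noise along each chromosome, AR(1) in site order,
  with a per-age-group correlation parameter that decreases from young to
  old (methylation maintenance degrades with age);
* integer read coverage per site and sample from a shifted negative
  binomial (mean ~12, matching 9–15x whole-genome depth; a targeted-capture
  preset uses mean 300), with binomial sampling of methylated reads;
* non-CpG cytosines at near-zero methylation (mean < 0.01).

The default design is three ages x three replicates at 1, 5 and 9 years.
All outputs (CGmap per sample, sample sheet, annotation, truth JSON) are
byte-reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import (
    GenomicElement,
    MethylationRecord,
    SampleMeta,
    write_bed,
    write_cgmap,
    write_sample_sheet,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "CohortSim",
    "simulate_cohort",
    "simulate_annotation",
    "simulate_ar1_methylome",
    "tbseq_config",
]

DEFAULT_AGES = (1.0, 1.0, 1.0, 5.0, 5.0, 5.0, 9.0, 9.0, 9.0)
DEFAULT_GROUPS = ("Young",) * 3 + ("Mid",) * 3 + ("Old",) * 3


@dataclass
class SimConfig:
    """Generator parameters; the defaults are the reference study design."""

    ages: tuple = DEFAULT_AGES
    groups: tuple = DEFAULT_GROUPS
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_cg_sites: int = 5000
    n_noncg_sites: int = 600

    # baseline beta mixture: (weight, a, b) per component; weights sum to 1
    mass_high: float = 0.70       # highly methylated component (> 0.8)
    mass_low: float = 0.03        # unmethylated component (< 0.05)
    high_beta: tuple = (40.0, 2.5)
    low_beta: tuple = (1.5, 60.0)
    mid_beta: tuple = (2.0, 2.0)

    # planted age drift; the slope range corresponds to total level changes
    # of ~0.25-0.65 across a 1-9 year span, the dynamic range the most
    # strongly age-associated CpGs exhibit in capture-panel heatmaps
    fraction_drift_sites: float = 0.04
    slope_min: float = 0.03       # |slope| per year
    slope_max: float = 0.08
    fraction_negative: float = 0.85

    # spatially correlated noise (AR(1) in site order within chromosomes)
    rho_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"Young": 0.55, "Mid": 0.45, "Old": 0.35})
    noise_sd: float = 0.03

    # read sampling
    coverage_mean: float = 12.0
    coverage_dispersion: float = 4.0
    noncg_mean_level: float = 0.005

    seed: int = 0

    def validate(self) -> None:
        if len(self.ages) != len(self.groups):
            raise ValueError("ages and groups must be the same length")
        if not 0 <= self.fraction_drift_sites <= 1:
            raise ValueError("fraction_drift_sites must lie in [0, 1]")
        if self.mass_high + self.mass_low > 1:
            raise ValueError("mixture masses exceed 1")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")
        if not 0 < self.slope_min <= self.slope_max:
            raise ValueError("need 0 < slope_min <= slope_max")
        for g in set(self.groups):
            if g not in self.rho_by_group:
                raise ValueError(f"no rho for group {g!r}")


@dataclass
class SimTruth:
    """Ground truth for every emitted CpG site and sample."""

    chroms: list[str]
    positions: list[int]
    baseline: list[float]
    slope: list[float]
    is_drift: list[bool]
    sample_ages: dict[str, float]
    rho_by_group: dict[str, float]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def drift_site_keys(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, d in
                zip(self.chroms, self.positions, self.is_drift) if d}


@dataclass
class CohortSim:
    """Paths and truth of one simulated cohort."""

    samples: list[SampleMeta]
    sample_sheet: Path
    truth: SimTruth
    truth_path: Path
    out_dir: Path


def _site_positions(rng: np.random.Generator, n_sites: int, n_chrom: int,
                    length: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct positions (spacing >= 2 so CpGs never overlap) per chromosome."""
    per = np.full(n_chrom, n_sites // n_chrom)
    per[: n_sites % n_chrom] += 1
    chrom_idx, positions = [], []
    for c in range(n_chrom):
        # sample on a /2 grid then scale: guarantees >= 2 bp spacing
        grid = rng.choice(length // 2 - 1, size=per[c], replace=False)
        pos = np.sort(grid) * 2 + 1  # 1-based, odd positions
        chrom_idx.append(np.full(per[c], c))
        positions.append(pos)
    return np.concatenate(chrom_idx), np.concatenate(positions)


def _baseline_mixture(rng: np.random.Generator, cfg: SimConfig, n: int
                      ) -> np.ndarray:
    comp = rng.choice(
        3, size=n,
        p=[cfg.mass_high, cfg.mass_low, 1 - cfg.mass_high - cfg.mass_low])
    out = np.empty(n)
    for c, (a, b) in enumerate((cfg.high_beta, cfg.low_beta, cfg.mid_beta)):
        m = comp == c
        out[m] = rng.beta(a, b, size=m.sum())
    return out


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float
               ) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation sd."""
    eps = rng.normal(size=n)
    out = np.empty(n)
    out[0] = eps[0]
    scale = np.sqrt(1 - rho ** 2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + scale * eps[i]
    return out * sd


def _shifted_negbin(rng: np.random.Generator, mean: float, dispersion: float,
                    size) -> np.ndarray:
    """Coverage >= 1: 1 + NB with the requested mean."""
    m = mean - 1.0
    if m <= 0:
        return np.ones(size, dtype=int)
    p = dispersion / (dispersion + m)
    return 1 + rng.negative_binomial(dispersion, p, size=size)


def simulate_cohort(
    config: SimConfig | None = None,
    out_dir: str | Path = "sim_cohort",
    low_regions: Sequence[GenomicElement] = (),
) -> CohortSim:
    """Generate per-sample CGmap files, a sample sheet and ground truth.

    Per site and sample the latent level is
    ``clamp(baseline + slope * age + AR(1) noise, 0, 1)`` and the observed
    methylated count is Binomial(total_count, latent). ``low_regions``
    optionally forces near-zero baselines inside given intervals (planted
    promoter hypomethylation, used to validate the metagene profile).
    """
    cfg = config or SimConfig()
    cfg.validate()
    n_drift = int(round(cfg.fraction_drift_sites * cfg.n_cg_sites))
    if n_drift > cfg.n_cg_sites:
        raise ValueError("more drift sites than sites")
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]
    chrom_idx, positions = _site_positions(
        rng, cfg.n_cg_sites, cfg.n_chromosomes, cfg.chrom_length)
    baseline = _baseline_mixture(rng, cfg, cfg.n_cg_sites)

    if low_regions:
        for el in low_regions:
            c = chrom_names.index(el.chrom) if el.chrom in chrom_names else -1
            if c < 0:
                continue
            inside = (chrom_idx == c) & (positions - 1 >= el.start) \
                     & (positions - 1 < el.end)
            baseline[inside] = rng.beta(*cfg.low_beta, size=inside.sum())

    slope = np.zeros(cfg.n_cg_sites)
    is_drift = np.zeros(cfg.n_cg_sites, dtype=bool)
    drift_idx = rng.choice(cfg.n_cg_sites, size=n_drift, replace=False)
    is_drift[drift_idx] = True
    mag = rng.uniform(cfg.slope_min, cfg.slope_max, size=n_drift)
    sign = np.where(rng.random(n_drift) < cfg.fraction_negative, -1.0, 1.0)
    slope[drift_idx] = sign * mag
    # keep drifting levels inside (0.02, 0.98) over the cohort's age span so
    # clamping never flattens the planted signal
    amax = max(cfg.ages)
    for i, s in zip(drift_idx, slope[drift_idx]):
        lo = 0.02 + max(0.0, -s * amax)
        hi = 0.98 - max(0.0, s * amax)
        baseline[i] = rng.uniform(lo, hi)

    n_noncg = cfg.n_noncg_sites
    nc_chrom_idx, nc_positions = _site_positions(
        np.random.default_rng(rng.integers(2 ** 31)),
        n_noncg, cfg.n_chromosomes, cfg.chrom_length) if n_noncg else (
        np.array([], dtype=int), np.array([], dtype=int))
    nc_dinuc = rng.choice(["CA", "CC", "CT"], size=n_noncg)

    samples: list[SampleMeta] = []
    group_counter: dict[str, int] = {}
    for age, group in zip(cfg.ages, cfg.groups):
        group_counter[group] = group_counter.get(group, 0) + 1
        sample_id = f"{group}_{group_counter[group]}"
        cg_path = out_dir / f"{sample_id}.cgmap"

        latent = baseline + slope * age
        for c in range(cfg.n_chromosomes):
            m = chrom_idx == c
            latent[m] = latent[m] + _ar1_noise(
                rng, int(m.sum()), cfg.rho_by_group[group], cfg.noise_sd)
        latent = np.clip(latent, 0.0, 1.0)
        coverage = _shifted_negbin(rng, cfg.coverage_mean,
                                   cfg.coverage_dispersion, cfg.n_cg_sites)
        meth = rng.binomial(coverage, latent)

        records: list[MethylationRecord] = []
        for i in range(cfg.n_cg_sites):
            records.append(MethylationRecord(
                chrom=chrom_names[chrom_idx[i]], base="C",
                pos=int(positions[i]), context="CG", dinucleotide="CG",
                level=meth[i] / coverage[i],
                meth_count=int(meth[i]), total_count=int(coverage[i])))
        if n_noncg:
            nc_latent = np.clip(rng.exponential(cfg.noncg_mean_level, n_noncg),
                                0.0, 1.0)
            nc_cov = _shifted_negbin(rng, cfg.coverage_mean,
                                     cfg.coverage_dispersion, n_noncg)
            nc_meth = rng.binomial(nc_cov, nc_latent)
            for i in range(n_noncg):
                records.append(MethylationRecord(
                    chrom=chrom_names[nc_chrom_idx[i]], base="C",
                    pos=int(nc_positions[i]),
                    context="CHH" if nc_dinuc[i] != "CG" else "CG",
                    dinucleotide=str(nc_dinuc[i]),
                    level=nc_meth[i] / nc_cov[i],
                    meth_count=int(nc_meth[i]), total_count=int(nc_cov[i])))
        records.sort(key=lambda r: (r.chrom, r.pos))
        write_cgmap(records, cg_path)
        samples.append(SampleMeta(sample_id=sample_id, age_years=float(age),
                                  group=group, strain="synthetic",
                                  cgmap_path=str(cg_path)))

    sheet_path = write_sample_sheet(samples, out_dir / "samples.csv")
    truth = SimTruth(
        chroms=[chrom_names[c] for c in chrom_idx],
        positions=[int(p) for p in positions],
        baseline=[float(b) for b in baseline],
        slope=[float(s) for s in slope],
        is_drift=[bool(d) for d in is_drift],
        sample_ages={s.sample_id: s.age_years for s in samples},
        rho_by_group={g: float(r) for g, r in cfg.rho_by_group.items()
                      if g in set(cfg.groups)},
    )
    truth_path = truth.to_json(out_dir / "truth.json")
    return CohortSim(samples=samples, sample_sheet=sheet_path, truth=truth,
                     truth_path=truth_path, out_dir=out_dir)


def simulate_annotation(
    config: SimConfig | None = None,
    out_dir: str | Path = "sim_cohort",
    n_genes_per_chrom: int = 20,
    n_repeats_per_chrom: int = 30,
    seed_offset: int = 1,
) -> dict:
    """Generate gene GFF3, repeat GFF and capture-target BED for the genome.

    Genes are non-overlapping, >= 1 kb apart, 2–10 kb long, with strands;
    repeats are 300–3000 bp (so a subset exceeds the 1 kb floor the repeat
    profile uses) and strandless. Also returns each gene's promoter
    interval (1 kb upstream of the TSS plus the first kb of the body) for
    planting hypomethylation. Elements never exceed chromosome bounds.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed + seed_offset)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes: list[GenomicElement] = []
    repeats: list[GenomicElement] = []
    promoters: list[GenomicElement] = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        slot = cfg.chrom_length // max(n_genes_per_chrom, 1) if n_genes_per_chrom else 0
        for g in range(n_genes_per_chrom):
            length = int(rng.integers(2000, 10001))
            lo = g * slot + 1000
            hi = (g + 1) * slot - length - 1000
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            el = GenomicElement(chrom, start, start + length, strand, "gene",
                                f"gene_{chrom}_{g + 1}")
            genes.append(el)
            if strand == "+":
                promoters.append(GenomicElement(
                    chrom, max(0, start - 1000), start + 1000, strand,
                    "region", f"prom_{el.name}"))
            else:
                promoters.append(GenomicElement(
                    chrom, el.end - 1000, min(cfg.chrom_length, el.end + 1000),
                    strand, "region", f"prom_{el.name}"))
        for r in range(n_repeats_per_chrom):
            length = int(rng.integers(300, 3001))
            start = int(rng.integers(0, cfg.chrom_length - length))
            repeats.append(GenomicElement(chrom, start, start + length, ".",
                                          "repeat", f"rep_{chrom}_{r + 1}"))
    repeats.sort(key=lambda e: (e.chrom, e.start, e.end))

    gene_gff = out_dir / "genes.gff3"
    with open(gene_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in genes:
            fh.write(f"{el.chrom}\tsim\tgene\t{el.start + 1}\t{el.end}\t.\t"
                     f"{el.strand}\t.\tID={el.name};Name={el.name}\n")
    repeat_gff = out_dir / "repeats.gff"
    with open(repeat_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in repeats:
            fh.write(f"{el.chrom}\tsim\tdispersed_repeat\t{el.start + 1}\t"
                     f"{el.end}\t.\t.\t.\tID={el.name}\n")
    bed_path = write_bed(repeats[: len(repeats) // 2] or repeats,
                         out_dir / "targets.bed")
    return {
        "genes": genes,
        "repeats": repeats,
        "promoters": promoters,
        "gene_gff": gene_gff,
        "repeat_gff": repeat_gff,
        "target_bed": bed_path,
    }


def simulate_ar1_methylome(
    n_sites: int = 20_000,
    rho: float = 0.6,
    mean: float = 0.7,
    sd: float = 0.1,
    coverage: int = 1000,
    seed: int = 0,
    chrom: str = "chr1",
) -> list[MethylationRecord]:
    """A single chromosome of CpGs whose levels follow a stationary AR(1).

    Levels are ``mean + AR(1) Gaussian`` clipped to (0.005, 0.995), read
    out at high fixed coverage with deterministic rounding, so the lag-k
    Pearson autocorrelation of the emitted levels is rho**k up to sampling
    error — the closed-form oracle for the neighbor-autocorrelation
    statistic, and the generator behind the young > mid > old correlation
    ordering (maintenance fidelity falls with age, so rho does too).
    """
    rng = np.random.default_rng(seed)
    levels = np.clip(mean + _ar1_noise(rng, n_sites, rho, sd), 0.005, 0.995)
    meth = np.rint(levels * coverage).astype(int)
    return [
        MethylationRecord(chrom=chrom, base="C", pos=2 * i + 1, context="CG",
                          dinucleotide="CG", level=meth[i] / coverage,
                          meth_count=int(meth[i]), total_count=coverage)
        for i in range(n_sites)
    ]


def tbseq_config(seed: int = 0) -> SimConfig:
    """Targeted-capture preset: 16 samples over nine ages, coverage ~300x."""
    ages = (2.3, 2.3, 3.6, 3.6, 4.2, 4.2, 4.6, 4.6,
            6.9, 6.9, 7.9, 7.9, 8.5, 8.7, 10.9, 10.9)
    groups = tuple("Young" if a < 4.5 else ("Mid" if a < 8.0 else "Old")
                   for a in ages)
    return SimConfig(
        ages=ages, groups=groups, n_cg_sites=2000, n_noncg_sites=0,
        coverage_mean=300.0, coverage_dispersion=8.0, seed=seed)
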
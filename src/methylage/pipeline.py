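"""End-to-end pipeline orchestration with validated config and provenance.

Stages run in dependency order — matrix building, then methylome stats /
profiles / age association in any order, then the clock and cohort
structure — each writing its artifacts plus a provenance JSON recording
the exact parameters (and seed) that produced them, sufficient to rerun
any stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import clock as clk
from . import stats as mstats
from . import structure as struct
from .io import read_cgmap, read_elements, read_sample_sheet, write_bed
from .matrix import build_common_matrix, pool_group
from .profiles import metagene_profile

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and an exit-code category."""

    def __init__(self, stage: str, message: str, exit_code: int = 4):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """All paths and stage parameters; validated before any stage runs."""

    sample_sheet: str = ""
    gene_gff: str = ""
    repeat_gff: str = ""
    target_bed: str = ""
    out_dir: str = "methylage_out"

    matrix_floor: int = 5
    stats_floor: int = 10
    track_floor: int = 3
    bin_size: int = 500_000
    flank_bp: int = 2000
    body_bins: int = 10
    flank_bin_bp: int = 200
    repeat_min_length: int = 1000
    max_lag: int = 20
    top_n: int = 4500
    merge_gap_bp: int = 200
    pad_bp: int = 60
    remove_var: float = 0.1
    alpha: float = clk.DEFAULT_ALPHA
    l1_ratio: float = clk.DEFAULT_L1_RATIO
    top_variable: int = 500
    cluster_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.matrix_floor >= 1, "matrix_floor must be >= 1"),
            (self.bin_size >= 1, "bin_size must be >= 1"),
            (self.flank_bp % self.flank_bin_bp == 0,
             "flank_bp must be a multiple of flank_bin_bp"),
            (self.body_bins >= 1, "body_bins must be >= 1"),
            (self.max_lag >= 1, "max_lag must be >= 1"),
            (self.top_n >= 1, "top_n must be >= 1"),
            (0 <= self.remove_var < 1, "remove_var must lie in [0, 1)"),
            (self.alpha >= 0, "alpha must be >= 0"),
            (0 <= self.l1_ratio <= 1, "l1_ratio must lie in [0, 1]"),
            (self.cluster_k >= 1, "cluster_k must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write_provenance(out_dir: Path, config: PipelineConfig, stages: dict):
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump({"config": asdict(config), "stages": stages}, fh, indent=2,
                  sort_keys=True)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a cohort; returns the output directory.

    Raises :class:`PipelineError` naming the failing stage. Input problems
    (missing sample sheet, unreadable CGmap) surface before any compute.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def stage(name):
        logger.info("stage %s", name)
        stages[name] = {"started": time.time()}
        return name

    name = stage("inputs")
    if not config.sample_sheet or not Path(config.sample_sheet).exists():
        raise PipelineError(name, f"sample sheet not found: "
                            f"{config.sample_sheet!r}", exit_code=2)
    samples = read_sample_sheet(config.sample_sheet)
    for s in samples:
        if not Path(s.cgmap_path).exists():
            raise PipelineError(name, f"CGmap for {s.sample_id} not found: "
                                f"{s.cgmap_path}", exit_code=2)
    records = {s.sample_id: read_cgmap(s.cgmap_path) for s in samples}
    ages = [s.age_years for s in samples]
    groups = [s.group for s in samples]

    try:
        name = stage("matrix")
        mat = build_common_matrix(samples, config.matrix_floor,
                                  records_by_sample=records)
        mat.to_tsv(out_dir / f"matrix_{config.matrix_floor}x.tsv")
        mat10 = build_common_matrix(samples, config.stats_floor,
                                    records_by_sample=records)

        name = stage("stats")
        cm = pd.DataFrame({s.sample_id: mstats.context_means(records[s.sample_id])
                           for s in samples}).T
        cm.index.name = "sample_id"
        cm.to_csv(out_dir / "context_means.tsv", sep="\t",
                  float_format="%.4f")
        pooled = {}
        for g in dict.fromkeys(groups):
            members = [records[s.sample_id] for s in samples if s.group == g]
            pooled[g] = pool_group(members)
        track_rows = []
        for g, recs in pooled.items():
            for t in mstats.chromosome_bins(recs, config.bin_size,
                                            config.track_floor):
                track_rows.append((g, t.chrom, t.bin_start, t.mean_level,
                                   t.n_sites))
        pd.DataFrame(track_rows, columns=["group", "chrom", "bin_start",
                                          "mean_level", "n_sites"]).to_csv(
            out_dir / "chromosome_bins.tsv", sep="\t", index=False,
            float_format="%.6g")
        group_names = list(pooled)
        ks_rows = []
        lvl10 = {g: [r.meth_count / r.total_count
                     for r in pooled[g]
                     if r.context == "CG" and r.total_count >= config.stats_floor]
                 for g in group_names}
        for i in range(len(group_names)):
            for j in range(i + 1, len(group_names)):
                a, b = group_names[i], group_names[j]
                d, p = mstats.ks_compare(lvl10[a], lvl10[b])
                ks_rows.append((a, b, d, p))
        pd.DataFrame(ks_rows, columns=["group_a", "group_b", "D", "p"]).to_csv(
            out_dir / "ks_pairwise.tsv", sep="\t", index=False,
            float_format="%.6g")
        ac_rows = []
        for s in samples:
            prof = mstats.neighbor_autocorrelation(records[s.sample_id],
                                                   config.max_lag)
            prof.insert(0, "sample_id", s.sample_id)
            ac_rows.append(prof)
        pd.concat(ac_rows).to_csv(out_dir / "autocorrelation.tsv", sep="\t",
                                  index=False, float_format="%.6g")

        name = stage("profiles")
        if config.gene_gff and Path(config.gene_gff).exists():
            genes = read_elements(config.gene_gff, "gene")
            for g, recs in pooled.items():
                prof = metagene_profile(recs, genes, config.flank_bp,
                                        config.body_bins, config.flank_bin_bp)
                prof.table.assign(group=g).to_csv(
                    out_dir / f"metagene_{g}.tsv", sep="\t", index=False,
                    float_format="%.6g")
        if config.repeat_gff and Path(config.repeat_gff).exists():
            repeats = read_elements(config.repeat_gff, "repeat")
            for g, recs in pooled.items():
                prof = metagene_profile(
                    recs, repeats, config.flank_bp, config.body_bins,
                    config.flank_bin_bp,
                    min_element_length=config.repeat_min_length)
                prof.table.assign(group=g).to_csv(
                    out_dir / f"repeat_profile_{g}.tsv", sep="\t", index=False,
                    float_format="%.6g")

        name = stage("associate")
        res = assoc.site_age_stats(mat10.levels, ages, groups)
        res = assoc.rank_and_select(res, top_n=min(config.top_n, len(res)))
        res.to_csv(out_dir / "age_association.tsv", sep="\t",
                   float_format="%.6g")
        selected = res[res["selected"]]
        regions = assoc.collapse_to_regions(selected, config.merge_gap_bp,
                                            config.pad_bp)
        write_bed(assoc.regions_to_elements(regions),
                  out_dir / "capture_regions.bed")
        elements = []
        if config.gene_gff and Path(config.gene_gff).exists():
            elements += read_elements(config.gene_gff, "gene")
        if config.repeat_gff and Path(config.repeat_gff).exists():
            elements += read_elements(config.repeat_gff, "repeat")
        if elements:
            sites = [(c, p) for c, p, _ in selected.index]
            ann = assoc.annotate_nearest_element(sites, elements)
            ann.to_csv(out_dir / "nearest_elements.tsv", sep="\t", index=False)

        name = stage("clock")
        X = mat.values().T
        ev = clk.loocv_predict(X, ages, alpha=config.alpha,
                               l1_ratio=config.l1_ratio,
                               sample_ids=[s.sample_id for s in samples],
                               feature_index=mat.site_index)
        ev.to_frame().to_csv(out_dir / "clock_loocv.tsv", sep="\t",
                             index=False, float_format="%.6g")
        union = ev.feature_union.copy()
        union["site"] = union["site"].astype(str)
        union.to_csv(out_dir / "clock_features.tsv", sep="\t", index=False)
        overlap = clk.feature_overlap(
            ev.feature_union, regions,
            sites=[(s[0], s[1]) for s in ev.feature_union["site"]])
        final = clk.elastic_net_fit(X, ages, alpha=config.alpha,
                                    l1_ratio=config.l1_ratio)
        final.feature_index_ = mat.site_index
        final.to_frame().to_csv(out_dir / "clock_model.tsv", sep="\t",
                                index=False, float_format="%.10g")
        with open(out_dir / "clock_report.json", "w") as fh:
            json.dump({
                "alpha": config.alpha, "l1_ratio": config.l1_ratio,
                "mae_years": ev.mae, "r2_pearson": ev.r2_pearson,
                "r2_cod": ev.r2_cod,
                "n_distinct_features": ev.n_distinct_features,
                "intercept": final.intercept_,
                "feature_region_overlap": {
                    k: v for k, v in overlap.items()
                    if not isinstance(v, dict)},
            }, fh, indent=2, sort_keys=True)

        name = stage("structure")
        p = struct.pca(mat.levels, remove_var_fraction=config.remove_var)
        scores = pd.DataFrame(
            p.scores_, index=mat.sample_index,
            columns=[f"PC{i + 1}" for i in range(p.scores_.shape[1])])
        scores.to_csv(out_dir / "pca_scores.tsv", sep="\t",
                      float_format="%.6g")
        r2 = struct.pc_age_correlation(p.scores_, ages)
        pd.DataFrame({"component": scores.columns, "age_r2": r2,
                      "variance_explained": p.variance_explained_}).to_csv(
            out_dir / "pc_age_r2.tsv", sep="\t", index=False,
            float_format="%.6g")
        cluster = struct.sample_correlation_cluster(mat.levels)
        with open(out_dir / "sample_dendrogram.nwk", "w") as fh:
            fh.write(cluster["newick"] + "\n")
        top = struct.top_variable_sites(
            mat.levels, min(config.top_variable, mat.n_sites))
        sc = struct.site_cluster(top, k=min(config.cluster_k, top.shape[0]),
                                 ages=ages)
        lab = top.index.to_frame(index=False)
        lab["cluster"] = sc["labels"]
        lab.to_csv(out_dir / "site_clusters.tsv", sep="\t", index=False)
    except PipelineError:
        raise
    except (ValueError, OSError) as exc:
        raise PipelineError(name, str(exc), exit_code=3) from exc
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        raise PipelineError(name, str(exc), exit_code=4) from exc

    for st in stages.values():
        st["elapsed_s"] = round(time.time() - st.pop("started"), 3)
    _write_provenance(out_dir, config, stages)
    return out_dir
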
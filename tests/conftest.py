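"""Shared fixtures: small synthetic cohorts and record collections."""

from __future__ import annotations

import numpy as np
import pytest

from methylage.io import MethylationRecord, read_cgmap
from methylage.matrix import build_common_matrix
from methylage.simulate import SimConfig, simulate_cohort


def make_records(n, chrom="chr1", start=1, step=10, levels=None, coverage=10,
                 context="CG", rng=None):
    """Deterministic helper: n CG records with given or random levels."""
    if rng is None:
        rng = np.random.default_rng(0)
    if levels is None:
        levels = rng.uniform(0, 1, n)
    cov = np.full(n, coverage) if np.isscalar(coverage) else np.asarray(coverage)
    out = []
    for i in range(n):
        meth = int(round(levels[i] * cov[i]))
        out.append(MethylationRecord(
            chrom=chrom, base="C", pos=start + i * step, context=context,
            dinucleotide="CG" if context == "CG" else "CA",
            level=meth / cov[i], meth_count=meth, total_count=int(cov[i])))
    return out


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default 3 ages x 3 replicates cohort at seed 1, read back."""
    out = tmp_path_factory.mktemp("cohort")
    sim = simulate_cohort(SimConfig(seed=1), out_dir=out)
    records = {s.sample_id: read_cgmap(s.cgmap_path) for s in sim.samples}
    return sim, records


@pytest.fixture(scope="session")
def cohort_matrix(default_cohort):
    """Coverage-floor-5 common matrix of the default cohort."""
    sim, records = default_cohort
    return build_common_matrix(sim.samples, coverage_floor=5,
                               records_by_sample=records)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A fast 800-site cohort for end-to-end / CLI tests."""
    out = tmp_path_factory.mktemp("small")
    cfg = SimConfig(seed=7, n_cg_sites=800, n_noncg_sites=100,
                    n_chromosomes=2, chrom_length=400_000)
    sim = simulate_cohort(cfg, out_dir=out)
    return cfg, sim
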
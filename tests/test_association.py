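"""Age-association statistics, ranking, region collapse and annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from methylage.association import (
    AgeAssociationSelector,
    adjust_pvalues,
    annotate_nearest_element,
    collapse_to_regions,
    rank_and_select,
    site_age_stats,
)
from methylage.io import GenomicElement

AGES = np.array([1, 1, 1, 5, 5, 5, 9, 9, 9], dtype=float)
GROUPS = np.array(["Y"] * 3 + ["M"] * 3 + ["O"] * 3)


def _index(n, chrom="chr1"):
    return pd.MultiIndex.from_arrays(
        [[chrom] * n, np.arange(1, 2 * n, 2), ["CG"] * n],
        names=["chrom", "pos", "context"])


class TestSiteAgeStats:
    def test_exactly_linear_site_has_unit_correlation(self):
        X = pd.DataFrame([0.1 + 0.05 * AGES, 0.9 - 0.05 * AGES],
                         index=_index(2))
        res = site_age_stats(X, AGES, GROUPS)
        assert res["pearson_r"].tolist() == pytest.approx([1.0, -1.0])
        assert (res["pearson_p"] < 1e-12).all()

    def test_zero_variance_site_excluded(self):
        X = pd.DataFrame([np.full(9, 0.5), 0.1 + 0.02 * AGES], index=_index(2))
        res = rank_and_select(site_age_stats(X, AGES, GROUPS), top_n=1)
        assert np.isnan(res["pearson_r"].iloc[0])
        assert not res["selected"].iloc[0] and res["selected"].iloc[1]

    def test_constant_ages_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).uniform(size=(3, 9)))
        with pytest.raises(ValueError, match="constant"):
            site_age_stats(X, np.ones(9), GROUPS)

    def test_matches_reference_statistics(self):
        """Vectorized r/F/p agree with scipy's per-site tests to 1e-10."""
        rng = np.random.default_rng(41)
        X = pd.DataFrame(rng.uniform(0, 1, (500, 9)), index=_index(500))
        res = site_age_stats(X, AGES, GROUPS)
        for i in range(0, 500, 7):
            row = X.iloc[i].to_numpy()
            r_ref, p_ref = sps.pearsonr(row, AGES)
            f_ref, fp_ref = sps.f_oneway(row[:3], row[3:6], row[6:])
            assert res["pearson_r"].iloc[i] == pytest.approx(r_ref, abs=1e-10)
            assert res["pearson_p"].iloc[i] == pytest.approx(p_ref, abs=1e-10)
            assert res["anova_F"].iloc[i] == pytest.approx(f_ref, abs=1e-8)
            assert res["anova_p"].iloc[i] == pytest.approx(fp_ref, abs=1e-10)


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_bh(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(42)
        p = rng.uniform(0, 1, 200)
        # brute-force BH: p_(i) * n / i with running minimum from the top
        order = np.argsort(p)
        n = p.size
        scaled = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(scaled[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj, 1)
        np.testing.assert_allclose(adjust_pvalues(p), expected, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(43)
        p = rng.uniform(0, 1, 500)
        assert (adjust_pvalues(p) >= p - 1e-15).all()

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=100))
    def test_bh_properties_hold_for_any_pvalues(self, p):
        adj = adjust_pvalues(p)
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1 + 1e-12)).all()
        # monotone: a smaller raw p never gets a larger adjusted p
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_null_data_bh_calibration(self):
        """On null data the BH-significant fraction stays near nominal."""
        rng = np.random.default_rng(44)
        n = 2000
        X = pd.DataFrame(rng.uniform(0.2, 0.8, (n, 9)), index=_index(n))
        res = rank_and_select(site_age_stats(X, AGES, GROUPS), top_n=10)
        frac = (res["adj_p_pearson"] < 0.05).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestRankAndSelect:
    def test_best_on_both_criteria_ranks_first(self):
        X = pd.DataFrame(
            np.vstack([0.1 + 0.08 * AGES + 0.001 * np.arange(9),
                       np.random.default_rng(1).uniform(0.4, 0.6, 9),
                       np.random.default_rng(2).uniform(0.4, 0.6, 9)]),
            index=_index(3))
        res = rank_and_select(site_age_stats(X, AGES, GROUPS), top_n=1)
        assert res["combined_rank"].iloc[0] == 1
        assert res["selected"].iloc[0]

    def test_identical_sites_tie_broken_by_genomic_order(self):
        row = 0.2 + 0.05 * AGES
        X = pd.DataFrame([row, row], index=_index(2))
        res = rank_and_select(site_age_stats(X, AGES, GROUPS), top_n=1)
        assert res["combined_rank"].tolist() == [1.0, 2.0]
        assert res["selected"].tolist() == [True, False]

    def test_top_n_larger_than_sites_selects_all_with_warning(self):
        X = pd.DataFrame(np.random.default_rng(3).uniform(size=(5, 9)),
                         index=_index(5))
        with pytest.warns(UserWarning, match="top_n"):
            res = rank_and_select(site_age_stats(X, AGES, GROUPS), top_n=50)
        assert res["selected"].all()

    def test_planted_drift_sites_dominate_top_ranks(self):
        """Matrix-level cohort: 50 planted slopes among 1000 sites."""
        rng = np.random.default_rng(45)
        n, k = 1000, 50
        X = rng.uniform(0.3, 0.7, (n, 9))
        planted = rng.choice(n, k, replace=False)
        slopes = rng.uniform(0.02, 0.04, k) * rng.choice([-1, 1], k)
        X[planted] = 0.5 + slopes[:, None] * (AGES - 5)[None, :]
        X += rng.normal(0, 0.03, X.shape)
        df = pd.DataFrame(np.clip(X, 0, 1), index=_index(n))
        res = rank_and_select(site_age_stats(df, AGES, GROUPS), top_n=k)
        top = set(np.flatnonzero(res["selected"].to_numpy()))
        assert len(top & set(planted)) >= 45

    def test_recovery_monotone_in_effect_size(self):
        rng = np.random.default_rng(46)
        n, k = 600, 40
        planted = rng.choice(n, k, replace=False)
        recoveries = []
        for scale in (0.005, 0.02, 0.06):
            X = rng.uniform(0.3, 0.7, (n, 9))
            X[planted] = 0.5 + scale * (AGES - 5)[None, :]
            X += rng.normal(0, 0.03, X.shape)
            df = pd.DataFrame(np.clip(X, 0, 1), index=_index(n))
            res = rank_and_select(site_age_stats(df, AGES, GROUPS), top_n=k)
            top = set(np.flatnonzero(res["selected"].to_numpy()))
            recoveries.append(len(top & set(planted)))
        assert recoveries == sorted(recoveries)


def _selected_frame(chrom_pos, rs=None):
    idx = pd.MultiIndex.from_tuples(
        [(c, p, "CG") for c, p in chrom_pos], names=["chrom", "pos", "context"])
    return pd.DataFrame(
        {"pearson_r": rs if rs is not None else np.ones(len(chrom_pos))},
        index=idx)


class TestCollapseToRegions:
    def test_nearby_sites_merge(self):
        regions = collapse_to_regions(
            _selected_frame([("chr1", 100), ("chr1", 200)]), merge_gap_bp=200)
        assert len(regions) == 1
        assert regions[0].member_sites == (100, 200)

    def test_distant_sites_stay_separate(self):
        regions = collapse_to_regions(
            _selected_frame([("chr1", 100), ("chr1", 10_100)]))
        assert len(regions) == 2

    def test_direction_summary(self):
        regions = collapse_to_regions(
            _selected_frame([("chr1", 100), ("chr1", 150)], rs=[0.9, -0.8]))
        assert regions[0].direction_summary == pytest.approx(0.5)

    def test_matches_brute_force_interval_merge(self):
        rng = np.random.default_rng(47)
        pos = np.sort(rng.choice(500_000, 4500, replace=False)) + 1
        regions = collapse_to_regions(_selected_frame(
            [("chr1", int(p)) for p in pos]), merge_gap_bp=200, pad_bp=60)
        # brute force: chain positions within 200 bp, pad, re-merge overlaps
        runs = [[pos[0]]]
        for p in pos[1:]:
            if p - runs[-1][-1] <= 200:
                runs[-1].append(p)
            else:
                runs.append([p])
        intervals = [(max(0, r[0] - 1 - 60), r[-1] + 60) for r in runs]
        merged = [list(intervals[0])]
        for s, e in intervals[1:]:
            if s < merged[-1][1]:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        assert [(r.start, r.end) for r in regions] == \
            [tuple(m) for m in merged]
        assert len(regions) <= len(pos)

    def test_members_inside_and_regions_disjoint(self):
        rng = np.random.default_rng(48)
        pos = np.sort(rng.choice(100_000, 800, replace=False)) + 1
        regions = collapse_to_regions(
            _selected_frame([("chr1", int(p)) for p in pos]))
        prev_end = -1
        for r in regions:
            assert r.start >= prev_end
            prev_end = r.end
            for p in r.member_sites:
                assert r.start <= p - 1 < r.end

    def test_idempotent_under_recollapse(self):
        rng = np.random.default_rng(49)
        pos = np.sort(rng.choice(50_000, 300, replace=False)) + 1
        regions = collapse_to_regions(
            _selected_frame([("chr1", int(p)) for p in pos]))
        again = collapse_to_regions(
            _selected_frame([("chr1", p) for r in regions
                             for p in r.member_sites]))
        assert [(r.start, r.end, r.member_sites) for r in regions] == \
            [(r.start, r.end, r.member_sites) for r in again]


class TestAnnotateNearest:
    GENE = GenomicElement("chr1", 1000, 2000, "+", "gene", "g1")
    REPEAT = GenomicElement("chr1", 3000, 3500, ".", "repeat", "r1")

    def test_site_inside_gene_distance_zero(self):
        ann = annotate_nearest_element([("chr1", 1500)], [self.GENE, self.REPEAT])
        assert len(ann) == 1
        assert ann.iloc[0]["element_name"] == "g1"
        assert ann.iloc[0]["distance"] == 0

    def test_equidistant_ties_all_reported(self):
        a = GenomicElement("chr1", 0, 100, "+", "gene", "g")
        # site 200 (0-based 199) sits 100 bp from a's last base (99) and
        # 100 bp from b's first base (299)
        b = GenomicElement("chr1", 299, 400, ".", "repeat", "r")
        ann = annotate_nearest_element([("chr1", 200)], [a, b])
        assert sorted(ann["element_name"]) == ["g", "r"]
        assert (ann["distance"] == 100).all()

    def test_unannotated_chromosome_logged_missing(self):
        ann = annotate_nearest_element([("chrZ", 10)], [self.GENE])
        assert np.isnan(ann.iloc[0]["distance"])

    def test_matches_brute_force_nearest_scan(self):
        rng = np.random.default_rng(50)
        elements = []
        for i in range(200):
            s = int(rng.integers(0, 500_000))
            kind = "gene" if i % 2 else "repeat"
            elements.append(GenomicElement("chr1", s, s + int(rng.integers(100, 5000)),
                                           "+", kind, f"{kind}{i}"))
        sites = [("chr1", int(p))
                 for p in rng.integers(1, 510_000, 1000)]
        ann = annotate_nearest_element(sites, elements)
        got = ann.groupby(["chrom", "pos"])["distance"].first()
        for chrom, pos in sites:
            p = pos - 1
            dists = [0 if e.start <= p < e.end
                     else (e.start - p if p < e.start else p - e.end + 1)
                     for e in elements]
            assert got.loc[(chrom, pos)] == min(dists)


class TestSelectorEstimator:
    def test_transform_keeps_selected_columns(self):
        rng = np.random.default_rng(51)
        X = rng.uniform(0, 1, (9, 60)).copy()
        X[:, 5] = 0.1 + 0.08 * AGES
        sel = AgeAssociationSelector(top_n=3).fit(X, AGES, groups=GROUPS)
        assert sel.support_[5]
        assert sel.transform(X).shape == (9, 3)
        params = sel.get_params()
        assert params == {"top_n": 3}
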
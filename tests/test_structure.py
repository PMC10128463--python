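"""PCA, correlation clustering and variable-site selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from methylage.structure import (
    MethylPCA,
    pc_age_correlation,
    pca,
    sample_correlation_cluster,
    site_cluster,
    top_variable_sites,
)

AGES = np.array([1, 1, 1, 5, 5, 5, 9, 9, 9], dtype=float)


def _levels(n_sites=100, n_samples=9, seed=81):
    rng = np.random.default_rng(seed)
    idx = pd.MultiIndex.from_arrays(
        [["chr1"] * n_sites, np.arange(1, 2 * n_sites, 2), ["CG"] * n_sites],
        names=["chrom", "pos", "context"])
    return pd.DataFrame(rng.uniform(0, 1, (n_sites, n_samples)), index=idx,
                        columns=[f"S{i}" for i in range(n_samples)])


class TestPca:
    def test_identical_samples_error(self):
        X = np.tile(np.linspace(0, 1, 50), (4, 1))
        with pytest.raises(ValueError, match="zero variance"):
            MethylPCA().fit(X)

    def test_two_cluster_separation(self):
        rng = np.random.default_rng(82)
        a = rng.uniform(0, 1, 80)
        b = a + 0.5 * rng.choice([-1, 1], 80)
        X = np.vstack([a, a, a, b, b, b]) + rng.normal(0, 1e-4, (6, 80))
        p = MethylPCA(remove_var_fraction=0.0).fit(X)
        assert p.variance_explained_[0] > 0.99
        assert np.sign(p.scores_[0, 0]) != np.sign(p.scores_[3, 0])

    def test_matches_eigendecomposition_oracle(self):
        levels = _levels()
        p = pca(levels, remove_var_fraction=0.1)
        X = levels.to_numpy().T[:, p.kept_sites_]
        Xc = X - X.mean(axis=0)
        # brute force: eigenvectors of the Gram matrix give the scores
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for k in range(5):
            score_ref = evecs[:, k] * np.sqrt(max(evals[k], 0))
            got = p.scores_[:, k]
            sign = np.sign(score_ref @ got)
            np.testing.assert_allclose(got, sign * score_ref, atol=1e-8)
        np.testing.assert_allclose(
            p.variance_explained_[:5],
            evals[:5] / evals[evals > 1e-12].sum(), atol=1e-10)

    def test_variance_explained_non_increasing_and_orthogonal(self):
        p = pca(_levels(seed=83))
        assert np.all(np.diff(p.variance_explained_) <= 1e-12)
        G = p.loadings_.T @ p.loadings_
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_reconstruction_from_all_components(self):
        levels = _levels(seed=84)
        p = pca(levels, remove_var_fraction=0.1)
        X = levels.to_numpy().T[:, p.kept_sites_]
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(p.scores_ @ p.loadings_.T, Xc, atol=1e-8)

    def test_remove_var_drops_lowest_variance_fraction(self):
        levels = _levels(seed=85)
        levels.iloc[:10] = 0.5  # zero-variance block
        p = pca(levels, remove_var_fraction=0.2)
        var = levels.var(axis=1, ddof=1).to_numpy()
        dropped = set(range(levels.shape[0])) - set(p.kept_sites_)
        kept_min = var[list(p.kept_sites_)].min()
        assert var[list(dropped)].max() <= kept_min + 1e-15
        assert len(dropped) >= int(0.2 * levels.shape[0])


class TestPcAgeCorrelation:
    def test_scores_proportional_to_age(self):
        scores = np.column_stack([2.5 * AGES - 3, np.zeros(9)])
        r2 = pc_age_correlation(scores, AGES)
        assert r2[0] == pytest.approx(1.0)
        assert np.isnan(r2[1])

    def test_orthogonal_scores_near_zero(self):
        x = AGES - AGES.mean()
        rng = np.random.default_rng(86)
        z = rng.uniform(size=9)
        zc = z - z.mean()
        zc -= (zc @ x) / (x @ x) * x  # remove the age component
        r2 = pc_age_correlation(zc[:, None], AGES)
        assert r2[0] == pytest.approx(0.0, abs=1e-12)


class TestSampleCorrelationCluster:
    def test_duplicated_sample_merges_first(self):
        levels = _levels(n_samples=4, seed=87)
        levels["S1"] = levels["S0"]
        res = sample_correlation_cluster(levels)
        assert res["correlation"].loc["S0", "S1"] == pytest.approx(1.0)
        first = res["linkage"][0]
        ids = sorted(res["correlation"].columns[int(i)] for i in first[:2])
        assert ids == ["S0", "S1"]
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_merges_last(self):
        base = np.linspace(0, 1, 60)
        rng = np.random.default_rng(88)
        levels = pd.DataFrame({
            "A": base, "B": base + rng.normal(0, 0.01, 60),
            "C": 1 - base,
        })
        res = sample_correlation_cluster(levels, method="pearson")
        assert res["linkage"][-1][2] > 1.9  # distance ~2 for r ~ -1

    def test_constant_sample_named_in_error(self):
        levels = _levels(n_samples=3, seed=89)
        levels["S1"] = 0.5
        with pytest.raises(ValueError, match="S1"):
            sample_correlation_cluster(levels)

    def test_linkage_matches_brute_force_agglomeration(self):
        levels = _levels(n_sites=40, n_samples=6, seed=90)
        res = sample_correlation_cluster(levels)
        corr = levels.corr(method="spearman").to_numpy()
        D = 1 - corr
        # brute-force complete-linkage agglomeration
        clusters = {i: {i} for i in range(6)}
        heights = []
        nxt = 6
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a < b:
                        d = max(D[i, j] for i in clusters[a]
                                for j in clusters[b])
                        if best is None or d < best[0]:
                            best = (d, a, b)
            d, a, b = best
            heights.append(d)
            clusters[nxt] = clusters.pop(a) | clusters.pop(b)
            nxt += 1
        np.testing.assert_allclose(res["linkage"][:, 2], heights, atol=1e-10)

    def test_newick_contains_all_samples(self):
        levels = _levels(n_samples=5, seed=91)
        res = sample_correlation_cluster(levels, k=2)
        for sid in levels.columns:
            assert sid in res["newick"]
        assert len(set(res["labels"])) == 2


class TestTopVariableSites:
    def test_constant_sites_never_beat_varying(self):
        levels = _levels(n_sites=20, seed=92)
        levels.iloc[:10] = 0.3
        top = top_variable_sites(levels, 10)
        assert not top.index.isin(levels.index[:10]).any()

    def test_n_equals_all_is_variance_sort(self):
        levels = _levels(n_sites=30, seed=93)
        top = top_variable_sites(levels, 30)
        var = top.var(axis=1, ddof=1).to_numpy()
        assert np.all(np.diff(var) <= 1e-15)

    def test_matches_brute_force_variance_sort(self):
        levels = _levels(n_sites=200, seed=94)
        top = top_variable_sites(levels, 50)
        brute = levels.loc[
            levels.var(axis=1, ddof=1).sort_values(
                ascending=False, kind="stable").index[:50]]
        assert set(top.index) == set(brute.index)

    def test_n_too_large_raises(self):
        with pytest.raises(ValueError):
            top_variable_sites(_levels(n_sites=5), 6)


class TestSiteCluster:
    def test_k_one_single_cluster(self):
        res = site_cluster(_levels(n_sites=10, seed=95), k=1)
        assert set(res["labels"]) == {1}

    def test_two_planted_families_partition_perfectly(self):
        rng = np.random.default_rng(96)
        lo = rng.normal(0.1, 0.01, (20, 9))
        hi = rng.normal(0.9, 0.01, (15, 9))
        levels = pd.DataFrame(np.vstack([lo, hi]))
        res = site_cluster(levels, k=2)
        labels = res["labels"]
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_matches_independent_agglomeration(self):
        from sklearn.cluster import AgglomerativeClustering

        levels = _levels(n_sites=200, seed=97)
        res = site_cluster(levels, k=5)
        ref = AgglomerativeClustering(n_clusters=5, linkage="complete",
                                      metric="euclidean"
                                      ).fit_predict(levels.to_numpy())
        # partitions must agree up to label renaming
        mapping = {}
        for mine, theirs in zip(res["labels"], ref):
            assert mapping.setdefault(mine, theirs) == theirs
        assert len(set(mapping.values())) == 5
        assert sum(res["sizes"].values()) == 200

    def test_trend_direction_reported(self):
        rng = np.random.default_rng(98)
        rising = 0.2 + 0.05 * AGES + rng.normal(0, 0.005, (30, 9))
        falling = 0.9 - 0.05 * AGES + rng.normal(0, 0.005, (30, 9))
        levels = pd.DataFrame(np.vstack([rising, falling]))
        res = site_cluster(levels, k=2, ages=AGES)
        trend = res["trend"]
        assert trend["fraction_rising"].max() == pytest.approx(1.0)
        assert trend["fraction_rising"].min() == pytest.approx(0.0)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            site_cluster(_levels(n_sites=3), k=4)
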
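import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from gutmarkers import CountTable
from gutmarkers.diversity import (
    alpha_diversity,
    alpha_diversity_vector,
    anosim,
    beta_distance,
    expected_rarefied_richness,
    pcoa,
    permanova,
    rarefaction_curve,
    rarefy,
)


class TestAlpha:
    def test_chao1_hand_value(self):
        res = alpha_diversity_vector([5, 3, 1, 1, 2])
        assert res["observed_features"] == 5
        # S_obs + F1(F1-1)/(2(F2+1)) = 5 + 2*1/(2*2)
        assert res["chao1"] == pytest.approx(5.5)

    def test_ace_hand_value(self):
        # counts [1,1,2,3,11]: S_abund=1, S_rare=4, N_rare=7, F1=2, C=5/7,
        # gamma^2 = max(5.6*8/42 - 1, 0) = 1/15 -> ACE = 1 + 5.6 + 2.8/15
        res = alpha_diversity_vector([1, 1, 2, 3, 11])
        assert res["ace"] == pytest.approx(1 + 5.6 + 2.8 / 15, rel=1e-12)

    def test_two_singletons(self):
        res = alpha_diversity_vector([1, 1])
        assert res["shannon"] == pytest.approx(math.log(2))
        assert res["simpson"] == 0.0

    def test_single_dominant_feature(self):
        res = alpha_diversity_vector([4])
        assert res["shannon"] == 0.0
        assert res["simpson"] == 1.0

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity_vector([0, 0])

    def test_invariants_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 30, size=40)
            if x.sum() == 0:
                continue
            res = alpha_diversity_vector(x)
            assert res["chao1"] >= res["observed_features"]
            assert res["shannon"] >= 0
            assert 0 <= res["simpson"] <= 1

    def test_table_wrapper(self, tiny_counts):
        table = alpha_diversity(tiny_counts)
        assert list(table.index) == tiny_counts.sample_ids


class TestRarefaction:
    def test_identity_at_full_depth(self, tiny_counts):
        depth = int(tiny_counts.sample_totals().min())
        out = rarefy(tiny_counts, depth, seed=0)
        kept = out.sample_ids
        for s in kept:
            if tiny_counts.sample_totals()[s] == depth:
                assert out.data[s].equals(tiny_counts.data[s])

    def test_column_sums_equal_depth(self, small_dataset):
        counts = small_dataset.counts
        depth = int(counts.sample_totals().min())
        out = rarefy(counts, depth, seed=1)
        assert (out.sample_totals() == depth).all()

    def test_shallow_samples_dropped(self, tiny_counts):
        # totals: S1=6, S2=7, S3=6 -> depth 7 keeps only S2
        out = rarefy(tiny_counts, 7, seed=0)
        assert out.sample_ids == ["S2"]
        out_all = rarefy(tiny_counts, 6, seed=0)
        assert set(out_all.sample_ids) == {"S1", "S2", "S3"}

    def test_depth_must_be_positive(self, tiny_counts):
        with pytest.raises(ValueError):
            rarefy(tiny_counts, 0)

    def test_expected_richness_matches_hypergeometric(self):
        """Mean rarefied richness over 1,000 draws matches
        E[S] = sum_i (1 - C(N-n_i, d)/C(N, d))."""
        x = np.array([12, 7, 3, 1, 1, 2, 0, 25])
        depth = 20
        expected = expected_rarefied_richness(x, depth)
        # independent closed form via scipy.comb as a cross-check
        n_total = x.sum()
        direct = sum(
            1 - comb(n_total - xi, depth) / comb(n_total, depth)
            for xi in x[x > 0]
        )
        assert expected == pytest.approx(direct, rel=1e-9)
        ct = CountTable(pd.DataFrame({"S": x[x > 0]},
                                     index=[f"f{i}" for i in range(np.sum(x > 0))]))
        rng_draws = []
        for seed in range(1000):
            out = rarefy(ct, depth, seed=seed)
            rng_draws.append((out.data["S"] > 0).sum())
        mc = np.mean(rng_draws)
        se = np.std(rng_draws, ddof=1) / math.sqrt(len(rng_draws))
        assert abs(mc - expected) < 4 * se + 1e-9

    def test_curve_monotone_and_endpoint(self, tiny_counts):
        totals = tiny_counts.sample_totals()
        depths = [2, 4, int(totals.min())]
        curve = rarefaction_curve(tiny_counts, depths, replicates=50, seed=0)
        for s in tiny_counts.sample_ids:
            vals = curve.loc[s].dropna().to_numpy()
            assert np.all(np.diff(vals) >= -1e-9)
        # at a sample's full depth the curve equals observed richness
        s0 = totals.idxmin()
        assert curve.loc[s0, int(totals.min())] == (tiny_counts.data[s0] > 0).sum()

    def test_single_feature_sample_flat_at_one(self):
        ct = CountTable(pd.DataFrame({"S": [30]}, index=["only"]))
        curve = rarefaction_curve(ct, [5, 10, 30], replicates=5, seed=0)
        assert (curve.loc["S"].dropna() == 1.0).all()


class TestBetaDistance:
    def test_bray_curtis_hand_value(self):
        ct = CountTable(pd.DataFrame({"X": [2, 2], "Y": [1, 3]}, index=["a", "b"]))
        dm = beta_distance(ct, "bray_curtis")
        assert dm["X", "Y"] == pytest.approx(0.25)

    def test_disjoint_presence_jaccard_one(self):
        ct = CountTable(pd.DataFrame({"X": [2, 0], "Y": [0, 3]}, index=["a", "b"]))
        dm = beta_distance(ct, "jaccard_binary")
        assert dm["X", "Y"] == pytest.approx(1.0)

    def test_identical_samples_zero_everywhere(self):
        ct = CountTable(pd.DataFrame({"X": [2, 1], "Y": [2, 1]}, index=["a", "b"]))
        tree = TreeNode.read(["(a:1,b:1):0;"])
        for metric in ("bray_curtis", "jaccard_binary",
                       "unweighted_unifrac", "weighted_unifrac"):
            dm = beta_distance(ct, metric, tree=tree)
            assert dm["X", "Y"] == pytest.approx(0.0)

    def test_star_tree_unifrac_no_shared_branches(self):
        ct = CountTable(pd.DataFrame({"X": [1, 0], "Y": [0, 1]}, index=["A", "B"]))
        tree = TreeNode.read(["(A:1,B:1):0;"])
        dm = beta_distance(ct, "unweighted_unifrac", tree=tree)
        assert dm["X", "Y"] == pytest.approx(1.0)

    def test_unweighted_unifrac_equals_jaccard_on_star_tree(self):
        """On a star tree with unit branches, unshared/total branch length
        reduces to the binary Jaccard distance."""
        rng = np.random.default_rng(4)
        n_feat = 12
        names = [f"t{i}" for i in range(n_feat)]
        # star topology expressed with a bifurcating, zero-length internal
        # split so the tree is rooted; metrically identical to a star
        half = n_feat // 2
        newick = ("((" + ",".join(f"{n}:1" for n in names[:half]) + "):0,("
                  + ",".join(f"{n}:1" for n in names[half:]) + "):0):0;")
        tree = TreeNode.read([newick])
        presence = rng.integers(0, 2, size=(n_feat, 6))
        presence[:, 0] = 1  # avoid empty samples
        ct = CountTable(pd.DataFrame(presence, index=names,
                                     columns=[f"S{j}" for j in range(6)]))
        uni = beta_distance(ct, "unweighted_unifrac", tree=tree)
        jac = beta_distance(ct, "jaccard_binary")
        assert np.allclose(uni.data, jac.data, atol=1e-9)

    def test_metric_properties(self, small_dataset):
        for metric in ("bray_curtis", "jaccard_binary"):
            dm = beta_distance(small_dataset.counts, metric)
            assert np.allclose(np.diag(dm.data), 0)
            assert np.allclose(dm.data, dm.data.T)
            assert dm.data.min() >= 0 and dm.data.max() <= 1

    def test_unifrac_requires_tree(self, tiny_counts):
        with pytest.raises(ValueError, match="tree"):
            beta_distance(tiny_counts, "weighted_unifrac")


class TestPcoa:
    def test_two_samples_at_distance_d(self):
        dm = DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["a", "b"])
        res = pcoa(dm)
        coords = res.coordinates["PC1"].to_numpy()
        assert sorted(np.round(coords, 9).tolist()) == [-1.5, 1.5]

    def test_euclidean_embedding_reproduces_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(8)]))
        emb = res.coordinates.to_numpy()
        d2 = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        assert np.allclose(d, d2, atol=1e-9)

    def test_all_zero_distances(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm)
        assert np.allclose(res.eigenvalues, 0)
        assert res.coordinates.shape[1] == 0

    def test_eigenvalues_non_increasing_and_proportions(self, small_dataset):
        dm = beta_distance(small_dataset.counts, "bray_curtis")
        res = pcoa(dm)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-9


def _perfect_separation_dm():
    # two tight pairs far apart
    d = np.array([
        [0.0, 0.1, 1.0, 1.1],
        [0.1, 0.0, 1.2, 1.0],
        [1.0, 1.2, 0.0, 0.1],
        [1.1, 1.0, 0.1, 0.0],
    ])
    return DistanceMatrix(d, ids=list("abcd"))


class TestPermutationTests:
    def test_exhaustive_permanova_small(self):
        dm = _perfect_separation_dm()
        res = permanova(dm, ["g1", "g1", "g2", "g2"])
        assert res.method == "exhaustive"
        assert res.n_permutations == 6
        assert res.p_value == pytest.approx(2 / 6)

    def test_group_relabeling_invariance(self):
        dm = _perfect_separation_dm()
        a = permanova(dm, ["g1", "g1", "g2", "g2"])
        b = permanova(dm, ["g2", "g2", "g1", "g1"])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_anosim_perfect_separation_r_one(self):
        dm = _perfect_separation_dm()
        res = anosim(dm, ["g1", "g1", "g2", "g2"])
        assert res.statistic == pytest.approx(1.0)

    def test_statistics_match_skbio(self, small_dataset):
        """Pseudo-F and R agree with the scikit-bio implementations."""
        dm = beta_distance(small_dataset.counts, "bray_curtis")
        groups = list(small_dataset.metadata.groups)
        ours_f = permanova(dm, groups, n_permutations=9).statistic
        ours_r = anosim(dm, groups, n_permutations=9).statistic
        sk_f = skbio_permanova(dm, groups, permutations=9)["test statistic"]
        sk_r = skbio_anosim(dm, groups, permutations=9)["test statistic"]
        assert ours_f == pytest.approx(sk_f, rel=1e-9)
        assert ours_r == pytest.approx(sk_r, rel=1e-9)

    def test_exhaustive_matches_large_permutation_sample(self):
        """On n=6 the exhaustive p equals the limit of random permutations."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        groups = ["a", "a", "a", "b", "b", "b"]
        exact = anosim(dm, groups).p_value
        # manual Monte-Carlo over random assignments (with replacement)
        from gutmarkers.diversity import _anosim_stat, _group_arrays
        from scipy.stats import rankdata

        codes, _ = _group_arrays(dm, groups)
        iu = np.triu_indices(6, 1)
        ranks = rankdata(dm.data[iu])
        rank_mat = np.zeros((6, 6))
        rank_mat[iu] = ranks
        rank_mat += rank_mat.T
        obs = _anosim_stat(rank_mat, codes)
        hits = 0
        m = 20000
        perm = codes.copy()
        for _ in range(m):
            rng.shuffle(perm)
            if _anosim_stat(rank_mat, perm) >= obs - 1e-12:
                hits += 1
        assert exact == pytest.approx(hits / m, abs=0.02)

    def test_p_value_never_zero(self):
        dm = _perfect_separation_dm()
        res = permanova(dm, ["x", "x", "y", "y"])
        assert res.p_value > 0

    def test_single_group_rejected(self):
        dm = _perfect_separation_dm()
        with pytest.raises(ValueError):
            permanova(dm, ["g", "g", "g", "g"])
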
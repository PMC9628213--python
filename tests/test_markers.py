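import itertools

import numpy as np
import pandas as pd
import pytest

from gutmarkers import CountTable
from gutmarkers.abundance import relative_abundance
from gutmarkers.markers import (
    BaggedForest,
    candidate_filter,
    cv_marker_selection,
    fit_forest,
    pod_index,
    roc_auc,
    stratified_split,
    train_test_evaluate,
)


def separable_frame(n_per=10, n_noise=6, seed=0):
    """One perfectly separating feature among noise, samples x features."""
    rng = np.random.default_rng(seed)
    sep = np.concatenate([rng.uniform(0.6, 1.0, n_per), rng.uniform(0.0, 0.4, n_per)])
    data = {"sep": sep}
    for i in range(n_noise):
        data[f"noise{i}"] = rng.uniform(0, 1, 2 * n_per)
    idx = [f"s{i}" for i in range(2 * n_per)]
    x = pd.DataFrame(data, index=idx)
    y = pd.Series(["dis"] * n_per + ["ctl"] * n_per, index=idx)
    return x, y


class TestCandidateFilter:
    def make_counts(self):
        rng = np.random.default_rng(1)
        n = 10
        base = rng.integers(50, 150, size=(6, 2 * n))
        base[0, :n] *= 6  # differential, abundant
        df = pd.DataFrame(base, index=[f"f{i}" for i in range(6)],
                          columns=[f"s{i}" for i in range(2 * n)])
        ct = CountTable(df)
        groups = pd.Series(["a"] * n + ["b"] * n, index=df.columns)
        return ct, groups

    def test_high_p_feature_excluded(self):
        ct, groups = self.make_counts()
        cand = candidate_filter(ct, groups)
        res_p = cand.table["p_value"]
        assert (res_p < 0.05).all()
        assert "f0" in cand.feature_ids

    def test_low_abundance_feature_excluded(self):
        rng = np.random.default_rng(2)
        n = 12
        common = rng.integers(9000, 11000, size=(2, 2 * n))
        rare = np.concatenate([np.ones(n, dtype=int) * 2,
                               np.zeros(n, dtype=int)])  # differential but rare
        df = pd.DataFrame(np.vstack([common, rare]),
                          index=["c0", "c1", "rare"],
                          columns=[f"s{i}" for i in range(2 * n)])
        ct = CountTable(df)
        groups = pd.Series(["a"] * n + ["b"] * n, index=df.columns)
        rel_max = relative_abundance(ct).loc["rare"].max()
        assert rel_max < 0.001  # genuinely below the abundance floor
        with pytest.raises(ValueError):
            # only the rare feature differs, so the candidate set is empty
            candidate_filter(ct, groups)

    def test_empty_candidate_set_is_an_error(self):
        rng = np.random.default_rng(3)
        n = 8
        df = pd.DataFrame(rng.integers(50, 150, size=(5, 2 * n)),
                          index=[f"f{i}" for i in range(5)],
                          columns=[f"s{i}" for i in range(2 * n)])
        ct = CountTable(df)
        groups = pd.Series(["a"] * n + ["b"] * n, index=df.columns)
        with pytest.raises(ValueError, match="no features"):
            candidate_filter(ct, groups, p_threshold=1e-9)


class TestForest:
    def test_training_error_zero_on_separable(self):
        x, y = separable_frame()
        forest = fit_forest(x, y, n_trees=60, seed=0)
        assert (forest.predict(x) == y.to_numpy()).all()

    def test_seed_determinism(self):
        x, y = separable_frame()
        v1 = fit_forest(x, y, n_trees=40, seed=5).tree_votes(x)
        v2 = fit_forest(x, y, n_trees=40, seed=5).tree_votes(x)
        assert np.array_equal(v1, v2)

    def test_votes_sum_to_n_trees(self):
        x, y = separable_frame()
        forest = fit_forest(x, y, n_trees=33, seed=1)
        votes = forest.tree_votes(x)
        assert (votes.sum(axis=1) == 33).all()

    def test_single_class_rejected(self):
        x, _ = separable_frame()
        with pytest.raises(ValueError, match="single class"):
            fit_forest(x, pd.Series(["a"] * len(x), index=x.index))

    def test_mda_ranks_signal_first(self):
        x, y = separable_frame(n_per=15, seed=2)
        forest = fit_forest(x, y, n_trees=120, seed=3)
        mda = forest.importance_mda(seed=4)
        assert mda.idxmax() == "sep"
        gini = forest.importance_gini()
        assert gini.idxmax() == "sep"


class TestCvSelection:
    def test_separable_instance_selects_single_marker(self):
        x, y = separable_frame(n_per=12, n_noise=8, seed=4)
        res = cv_marker_selection(x, y, k=4, n_repeats=2, n_trees=60, seed=5)
        assert res.optimal_count == 1
        assert res.markers == ["sep"]

    def test_cv_errors_bounded(self):
        x, y = separable_frame(n_per=8, n_noise=4, seed=6)
        res = cv_marker_selection(x, y, k=4, n_repeats=1, n_trees=40, seed=7)
        assert res.cv_curve["mean_error"].between(0, 1).all()

    def test_too_few_features_rejected(self):
        x, y = separable_frame()
        with pytest.raises(ValueError):
            cv_marker_selection(x[["sep"]], y)


class TestPod:
    def test_pod_arithmetic(self):
        x, y = separable_frame()
        forest = fit_forest(x, y, n_trees=500, seed=8)
        pod = pod_index(forest, x, positive_class="dis")
        row = pod.table.iloc[0]
        assert row["disease_votes"] + row["control_votes"] == 500
        if np.isfinite(row["pod_ratio"]):
            assert row["pod_ratio"] == pytest.approx(
                row["pod_fraction"] / (1 - row["pod_fraction"]))

    def test_all_disease_votes_gives_inf_ratio(self):
        x, y = separable_frame(n_per=12, n_noise=0, seed=9)
        x["pad"] = 0.0  # need >=1 feature; keep sep dominant
        forest = fit_forest(x[["sep", "pad"]], y, n_trees=200, seed=10)
        pod = pod_index(forest, x[["sep", "pad"]], positive_class="dis")
        top = pod.table.loc[pod.table["pod_fraction"] == 1.0]
        assert len(top) > 0
        assert np.isinf(top["pod_ratio"]).all()

    def test_ranking_invariant_fraction_vs_ratio(self):
        rng = np.random.default_rng(11)
        votes = rng.integers(1, 99, size=30)  # no all-or-nothing votes
        frac = votes / 100.0
        ratio = votes / (100.0 - votes)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        lab = np.where(labels == 1, "d", "c")
        a1 = roc_auc(frac, lab, "d").auc
        a2 = roc_auc(ratio, lab, "d").auc
        assert a1 == pytest.approx(a2)

    def test_oob_votes_sum_to_oob_tree_count(self):
        x, y = separable_frame()
        forest = fit_forest(x, y, n_trees=100, seed=12)
        oob = forest.oob_votes()
        expected = np.array([sum(m[i] for m in forest.oob_masks_)
                             for i in range(len(x))])
        assert np.array_equal(oob.sum(axis=1), expected)


def auc_by_pair_counting(scores, labels, positive):
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation_auc_one(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], ["d", "d", "c", "c"], "d")
        assert r.auc == 1.0
        assert r.curve.iloc[0].tolist() == [0.0, 0.0]
        assert r.curve.iloc[-1].tolist() == [1.0, 1.0]

    def test_pure_ties_auc_half(self):
        r = roc_auc([0.5] * 6, ["d"] * 3 + ["c"] * 3, "d")
        assert r.auc == pytest.approx(0.5)
        assert r.p_value == 1.0

    def test_hand_counted_example(self):
        r = roc_auc([0.9, 0.8, 0.4, 0.7, 0.3], ["d", "d", "d", "c", "c"], "d")
        assert r.auc == pytest.approx(5 / 6)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            n1, n2 = rng.integers(3, 20, size=2)
            scores = np.round(rng.normal(size=n1 + n2), 1)  # induce ties
            labels = ["d"] * n1 + ["c"] * n2
            r = roc_auc(scores, labels, "d")
            assert r.auc == pytest.approx(
                auc_by_pair_counting(scores, labels, "d"), abs=1e-12)

    def test_delong_ci_matches_reference_implementation(self):
        """CI frozen from R pROC ci.auc(..., method='delong') on this input."""
        scores = [0.92, 0.81, 0.77, 0.65, 0.60, 0.44, 0.38,
                  0.85, 0.55, 0.50, 0.41, 0.30, 0.22, 0.18]
        labels = ["p"] * 7 + ["n"] * 7
        r = roc_auc(scores, labels, "p")
        assert r.auc == pytest.approx(0.7755102, abs=1e-6)
        assert r.ci_low == pytest.approx(0.5042220, abs=1e-6)
        assert r.ci_high == pytest.approx(1.0, abs=1e-9)

    def test_curve_monotone(self):
        rng = np.random.default_rng(14)
        scores = rng.normal(size=40)
        labels = rng.choice(["d", "c"], size=40).tolist()
        labels[0], labels[1] = "d", "c"
        r = roc_auc(scores, labels, "d")
        assert (r.curve.diff().dropna() >= -1e-12).all().all()

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], ["d", "d", "d"], "d")


class TestTrainTest:
    def test_no_leakage_and_manifest(self, small_dataset):
        ds = small_dataset
        res = train_test_evaluate(
            ds.counts, ds.metadata.groups, positive_class="case",
            test_fraction=1 / 3, n_trees=60, n_repeats=1, seed=15,
        )
        assert not set(res.train_ids) & set(res.test_ids)
        assert set(res.manifest["train_ids"]) == set(res.train_ids)
        assert res.manifest["markers"] == res.markers
        assert len(res.markers) == res.selection.optimal_count

    def test_stratified_split_preserves_balance(self):
        ids = [f"s{i}" for i in range(30)]
        groups = pd.Series(["a"] * 15 + ["b"] * 15, index=ids)
        train, test = stratified_split(ids, groups, 1 / 3, seed=0)
        assert len(test) == 10
        assert (groups.loc[test] == "a").sum() == 5

    def test_single_class_test_set_rejected(self, small_dataset):
        ds = small_dataset
        case_ids = [s for s in ds.counts.sample_ids if s.startswith("CASE")]
        ctrl_ids = [s for s in ds.counts.sample_ids if s.startswith("CTRL")]
        with pytest.raises(ValueError, match="single class"):
            train_test_evaluate(
                ds.counts, ds.metadata.groups, positive_class="case",
                train_ids=case_ids[:8] + ctrl_ids, test_ids=case_ids[8:],
                n_trees=20, n_repeats=1, seed=0,
            )

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        kw = dict(positive_class="case", test_fraction=1 / 3,
                  n_trees=40, n_repeats=1, seed=16)
        a = train_test_evaluate(ds.counts, ds.metadata.groups, **kw)
        b = train_test_evaluate(ds.counts, ds.metadata.groups, **kw)
        assert a.markers == b.markers
        pd.testing.assert_frame_equal(a.test_pod.table, b.test_pod.table)
        assert a.test_roc.auc == b.test_roc.auc
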
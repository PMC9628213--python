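"""Random-forest diagnostic marker selection and the POD index.

The workflow mirrors a standard microbiome biomarker pipeline: candidate
ASVs are screened by a Mann-Whitney test plus an abundance floor, a
five-fold cross-validated random forest selects the optimal marker count
from a descending feature grid (features re-ranked inside each training
fold, so selection never sees held-out data), and a final forest on the
selected markers yields a per-sample probability-of-disease (POD) index:
the ratio of decision trees voting "disease" versus "control".  Ranking
statistics (ROC/AUC with a DeLong confidence interval, Mann-Whitney group
difference) are computed on the vote *fraction*, a strictly monotone
transform of the ratio that avoids infinities.

The forest is a bagging ensemble of CART trees with per-tree vote and
out-of-bag (OOB) access; training-set POD uses OOB votes because
resubstitution votes of a forest are nearly pure and would inflate the
training AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier

from .abundance import mann_whitney, relative_abundance
from .io import CountTable


# ---------------------------------------------------------------------------
# candidate filter
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Features passing the differential-abundance candidate filter."""

    table: pd.DataFrame  # index feature; columns p_value, max_rel_abundance
    p_threshold: float
    abundance_threshold: float

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def candidate_filter(
    counts: CountTable,
    groups,
    p_threshold: float = 0.05,
    abundance_threshold: float = 0.001,
) -> CandidateSet:
    """Keep features with Mann-Whitney p < ``p_threshold`` AND a relative
    abundance above ``abundance_threshold`` in at least one sample.

    Both tests run on per-sample proportions; the raw (unadjusted)
    two-sided p is used.
    """
    labels = pd.Series(groups)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[counts.sample_ids]
    labels = labels.astype(str)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("candidate_filter requires exactly two groups")
    rel = relative_abundance(counts)
    g0 = rel.loc[:, labels[labels == levels[0]].index].to_numpy()
    g1 = rel.loc[:, labels[labels == levels[1]].index].to_numpy()
    max_rel = rel.max(axis=1).to_numpy()

    pvals = np.ones(rel.shape[0])
    for i in range(rel.shape[0]):
        both = np.concatenate([g0[i], g1[i]])
        if np.ptp(both) == 0:
            continue
        _, pvals[i], _ = mann_whitney(g0[i], g1[i])
    keep = (pvals < p_threshold) & (max_rel > abundance_threshold)
    table = pd.DataFrame(
        {"p_value": pvals, "max_rel_abundance": max_rel}, index=rel.index
    ).loc[keep]
    if table.empty:
        raise ValueError(
            "candidate filter returned no features "
            f"(min p = {pvals.min():.3g}, max abundance = {max_rel.max():.3g}, "
            f"thresholds p < {p_threshold}, abundance > {abundance_threshold})"
        )
    return CandidateSet(table, p_threshold, abundance_threshold)


# ---------------------------------------------------------------------------
# bagged forest with per-tree vote access
# ---------------------------------------------------------------------------

class BaggedForest:
    """Bagging ensemble of CART trees with vote-level access.

    mtry (features considered per split) is ⌊√p⌋ with a floor of 1, trees
    are grown to purity, and each tree trains on a bootstrap sample of the
    rows; the out-of-bag rows of each tree are retained for OOB votes and
    mean-decrease-in-accuracy importances.
    """

    def __init__(self, n_trees: int = 500, seed: int | None = None):
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, x: pd.DataFrame, y) -> "BaggedForest":
        labels = pd.Series(y)
        if not labels.index.equals(pd.RangeIndex(len(labels))):
            labels = labels.loc[x.index]
        self.classes_ = np.array(sorted(labels.astype(str).unique()))
        if len(self.classes_) < 2:
            raise ValueError("labels contain a single class")
        self.feature_names_ = list(x.columns)
        self._x = x.to_numpy(dtype=float)
        self._y = np.searchsorted(self.classes_, labels.astype(str).to_numpy())
        n = self._x.shape[0]
        p = self._x.shape[1]
        mtry = max(int(math.isqrt(p)), 1)
        rng = np.random.default_rng(self.seed)
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_masks_: list[np.ndarray] = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(self._x[idx], self._y[idx])
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
        return self

    def _check_x(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(x, pd.DataFrame):
            return x.loc[:, self.feature_names_].to_numpy(dtype=float)
        return np.asarray(x, dtype=float)

    def tree_votes(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Per-sample vote counts, one column per class (sums to n_trees)."""
        arr = self._check_x(x)
        votes = np.zeros((arr.shape[0], len(self.classes_)), dtype=int)
        for tree in self.trees_:
            # trees are fit on integer class codes, so predictions are codes
            pred = tree.predict(arr).astype(int)
            np.add.at(votes, (np.arange(arr.shape[0]), pred), 1)
        return votes

    def oob_votes(self) -> np.ndarray:
        """Vote counts on the training rows from trees that did not see them."""
        n = self._x.shape[0]
        votes = np.zeros((n, len(self.classes_)), dtype=int)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            pred = tree.predict(self._x[oob]).astype(int)
            np.add.at(votes, (np.flatnonzero(oob), pred), 1)
        return votes

    def predict(self, x: pd.DataFrame | np.ndarray) -> np.ndarray:
        votes = self.tree_votes(x)
        return self.classes_[votes.argmax(axis=1)]

    def importance_gini(self) -> pd.Series:
        """Mean decrease in Gini impurity, averaged over trees."""
        imp = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        return pd.Series(imp, index=self.feature_names_)

    def importance_mda(self, seed: int | None = None) -> pd.Series:
        """Mean decrease in OOB accuracy under per-feature permutation.

        Only features actually used by a tree are permuted for that tree
        (unused features cannot change its predictions).
        """
        rng = np.random.default_rng(seed)
        p = len(self.feature_names_)
        drops = np.zeros(p)
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if not oob.any():
                continue
            xo = self._x[oob]
            yo = self._y[oob]
            base_pred = tree.predict(xo).astype(int)
            base_acc = float(np.mean(base_pred == yo))
            used = np.unique(tree.tree_.feature)
            used = used[used >= 0]
            for f in used:
                xp = xo.copy()
                xp[:, f] = rng.permutation(xp[:, f])
                pred = tree.predict(xp).astype(int)
                drops[f] += base_acc - float(np.mean(pred == yo))
        return pd.Series(drops / self.n_trees, index=self.feature_names_)


def fit_forest(
    x: pd.DataFrame, y, n_trees: int = 500, seed: int | None = None
) -> BaggedForest:
    """Fit a :class:`BaggedForest` on samples × features data."""
    return BaggedForest(n_trees=n_trees, seed=seed).fit(x, y)


# ---------------------------------------------------------------------------
# CV marker selection
# ---------------------------------------------------------------------------

@dataclass
class MarkerModelResult:
    cv_curve: pd.DataFrame  # columns: n_markers, mean_error, sd_error
    optimal_count: int
    markers: list[str]
    importance: pd.DataFrame  # columns: mda, gini (full-data ranking forest)
    n_trees: int
    seed: int | None


def _count_grid(p: int) -> list[int]:
    """Descending evaluation grid: all features, halving steps, and 1..10."""
    grid = set()
    c = p
    while c >= 1:
        grid.add(c)
        c //= 2
    grid.update(range(1, min(p, 10) + 1))
    return sorted(grid, reverse=True)


def cv_marker_selection(
    x: pd.DataFrame,
    y,
    k: int = 5,
    n_repeats: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
    ranking: str = "mda",
) -> MarkerModelResult:
    """Choose the optimal marker count by repeated stratified k-fold CV.

    Within each training fold a ranking forest orders the features (by
    mean-decrease-in-accuracy by default, ``ranking="gini"`` for mean
    decrease in impurity); held-out misclassification error is then
    measured at each count of the descending grid.  The optimal count
    minimises the mean CV error, with ties resolved toward the smaller
    (more parsimonious) count, and the final marker list is the top of a
    ranking fit on the full data.
    """
    if x.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    labels = pd.Series(y)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[x.index]
    labels = labels.astype(str)
    if labels.nunique() < 2:
        raise ValueError("both classes must be present")
    grid = _count_grid(x.shape[1])
    ss = np.random.SeedSequence(seed)
    cv_seed, rank_seed, final_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                                      for s in ss.spawn(3))
    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=n_repeats,
                                       random_state=cv_seed)
    errors = {c: [] for c in grid}
    fold_rng = np.random.default_rng(rank_seed)
    x_np_index = np.arange(x.shape[0])
    for train_idx, test_idx in splitter.split(x_np_index, labels.to_numpy()):
        if labels.iloc[train_idx].nunique() < 2 or labels.iloc[test_idx].nunique() < 1:
            raise ValueError("a CV fold lost a class; too few samples per class")
        x_tr, x_te = x.iloc[train_idx], x.iloc[test_idx]
        y_tr, y_te = labels.iloc[train_idx], labels.iloc[test_idx]
        rank_forest = fit_forest(x_tr, y_tr, n_trees=n_trees,
                                 seed=int(fold_rng.integers(0, 2**31 - 1)))
        if ranking == "mda":
            imp = rank_forest.importance_mda(seed=int(fold_rng.integers(0, 2**31 - 1)))
        else:
            imp = rank_forest.importance_gini()
        order = imp.sort_values(ascending=False, kind="mergesort").index
        for c in grid:
            feats = list(order[:c])
            forest = fit_forest(x_tr[feats], y_tr, n_trees=n_trees,
                                seed=int(fold_rng.integers(0, 2**31 - 1)))
            pred = forest.predict(x_te[feats])
            errors[c].append(float(np.mean(pred != y_te.to_numpy())))

    curve = pd.DataFrame(
        {
            "n_markers": grid,
            "mean_error": [float(np.mean(errors[c])) for c in grid],
            "sd_error": [float(np.std(errors[c], ddof=1)) for c in grid],
        }
    ).sort_values("n_markers").reset_index(drop=True)
    best = curve["mean_error"].min()
    optimal = int(curve.loc[curve["mean_error"] <= best + 1e-12, "n_markers"].min())

    final_forest = fit_forest(x, labels, n_trees=n_trees, seed=final_seed)
    mda = final_forest.importance_mda(seed=final_seed)
    gini = final_forest.importance_gini()
    rank_series = mda if ranking == "mda" else gini
    markers = list(rank_series.sort_values(ascending=False, kind="mergesort").index[:optimal])
    importance = pd.DataFrame({"mda": mda, "gini": gini})
    return MarkerModelResult(curve, optimal, markers, importance, n_trees, seed)


# ---------------------------------------------------------------------------
# POD index
# ---------------------------------------------------------------------------

@dataclass
class PODResult:
    """Per-sample disease/control vote counts and the POD index.

    ``pod_fraction`` = disease votes / total votes; ``pod_ratio`` is the
    literal disease/control vote ratio (``inf`` when no tree votes
    control).  For full-forest votes the two vote counts sum to the number
    of trees; for OOB votes they sum to the number of trees that held the
    sample out.
    """

    table: pd.DataFrame  # disease_votes, control_votes, pod_fraction, pod_ratio
    positive_class: str
    source: str  # "full" or "oob"


def pod_index(
    forest: BaggedForest,
    x: pd.DataFrame | None = None,
    positive_class: str | None = None,
    oob: bool = False,
    sample_ids=None,
) -> PODResult:
    """POD index from per-tree votes.

    With ``oob=True`` the training rows are scored by the trees that did
    not train on them (``x`` is ignored); otherwise every tree votes on the
    rows of ``x``.
    """
    positive = positive_class or forest.classes_[0]
    if positive not in forest.classes_:
        raise ValueError(f"positive class {positive!r} not among {forest.classes_}")
    pos_col = int(np.flatnonzero(forest.classes_ == positive)[0])
    if oob:
        votes = forest.oob_votes()
    else:
        if x is None:
            raise ValueError("x is required unless oob=True")
        votes = forest.tree_votes(x)
        if sample_ids is None and isinstance(x, pd.DataFrame):
            sample_ids = list(x.index)
    disease = votes[:, pos_col]
    control = votes.sum(axis=1) - disease
    total = votes.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, disease / np.maximum(total, 1), np.nan)
        ratio = np.where(control > 0, disease / np.maximum(control, 1), np.inf)
    table = pd.DataFrame(
        {
            "disease_votes": disease,
            "control_votes": control,
            "pod_fraction": frac,
            "pod_ratio": ratio,
        },
        index=sample_ids if sample_ids is not None else pd.RangeIndex(len(disease)),
    )
    return PODResult(table, positive, "oob" if oob else "full")


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong CI
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float  # Mann-Whitney on scores between the two labels
    curve: pd.DataFrame  # columns fpr, tpr
    n_positive: int
    n_negative: int


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative score vectors."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = _midranks(all_scores)
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_pos) / n          # structural components per positive
    v01 = 1.0 - (r_all[m:] - r_neg) / m    # per negative
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return float(auc), s10 / m + s01 / n


def roc_auc(scores, labels, positive_class: str) -> ROCResult:
    """ROC curve, Mann-Whitney AUC, DeLong 95% CI, and group-difference p.

    The AUC uses the Mann-Whitney identity with midrank tie handling; the
    CI is DeLong's asymptotic interval clipped to [0, 1]; the p-value is a
    two-sided Mann-Whitney test of the scores between labels.
    """
    scores = np.asarray(pd.Series(scores), dtype=float)
    labels = np.asarray(pd.Series(labels).astype(str))
    pos = scores[labels == positive_class]
    neg = scores[labels != positive_class]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present in the labels")
    auc, var = _delong_variance(pos, neg)
    z = stats.norm.ppf(0.975)
    half = z * math.sqrt(max(var, 0.0))
    ci_low, ci_high = max(auc - half, 0.0), min(auc + half, 1.0)
    if np.ptp(scores) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(pos, neg, alternative="two-sided").pvalue)

    # ROC curve points over all score thresholds (descending)
    order = np.argsort(-scores, kind="mergesort")
    sorted_lab = labels[order] == positive_class
    sorted_scores = scores[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_lab)[distinct]
    fps = np.cumsum(~sorted_lab)[distinct]
    tpr = np.r_[0.0, tps / len(pos)]
    fpr = np.r_[0.0, fps / len(neg)]
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return ROCResult(auc, ci_low, ci_high, p, curve, len(pos), len(neg))


# ---------------------------------------------------------------------------
# end-to-end train/test evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainTestResult:
    train_roc: ROCResult
    test_roc: ROCResult
    train_pod: PODResult
    test_pod: PODResult
    markers: list[str]
    selection: MarkerModelResult
    candidates: CandidateSet
    train_ids: list[str]
    test_ids: list[str]
    manifest: dict = field(default_factory=dict)


def stratified_split(
    sample_ids: list[str], groups, test_fraction: float, seed: int | None
) -> tuple[list[str], list[str]]:
    """Seeded stratified train/test split of sample IDs."""
    labels = pd.Series(groups)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[sample_ids]
    sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction,
                                 random_state=seed)
    idx = np.arange(len(sample_ids))
    train_idx, test_idx = next(sss.split(idx, labels.astype(str).to_numpy()))
    return [sample_ids[i] for i in train_idx], [sample_ids[i] for i in test_idx]


def train_test_evaluate(
    counts: CountTable,
    groups,
    positive_class: str,
    train_ids: list[str] | None = None,
    test_ids: list[str] | None = None,
    test_fraction: float | None = None,
    p_threshold: float = 0.05,
    abundance_threshold: float = 0.001,
    k: int = 5,
    n_repeats: int = 5,
    n_trees: int = 500,
    seed: int | None = None,
    resubstitution: bool = False,
) -> TrainTestResult:
    """Full diagnostic-model evaluation with a leak-free train/test split.

    Candidate filtering, marker selection and forest fitting use the
    training samples only; the training ROC uses OOB votes (unless
    ``resubstitution`` is requested) and the test ROC uses full-forest
    votes on the held-out samples.
    """
    labels = pd.Series(groups)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[counts.sample_ids]
    else:
        labels.index = counts.sample_ids
    labels = labels.astype(str)
    if train_ids is None or test_ids is None:
        if test_fraction is None:
            raise ValueError("provide train_ids/test_ids or test_fraction")
        train_ids, test_ids = stratified_split(
            counts.sample_ids, labels, test_fraction, seed
        )
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)}")
    if labels.loc[test_ids].nunique() < 2:
        raise ValueError("test set contains a single class")

    train_counts = counts.filter_samples(train_ids)
    cand = candidate_filter(train_counts, labels.loc[train_ids],
                            p_threshold, abundance_threshold)
    rel_train = relative_abundance(train_counts).loc[cand.feature_ids].T
    selection = cv_marker_selection(
        rel_train, labels.loc[train_ids], k=k, n_repeats=n_repeats,
        n_trees=n_trees, seed=seed,
    )
    markers_ = selection.markers
    forest = fit_forest(rel_train[markers_], labels.loc[train_ids],
                        n_trees=n_trees, seed=seed)

    train_pod = pod_index(forest, rel_train[markers_], positive_class,
                          oob=not resubstitution,
                          sample_ids=train_ids)
    rel_test = relative_abundance(counts.filter_samples(test_ids)).loc[
        cand.feature_ids].T
    test_pod = pod_index(forest, rel_test[markers_], positive_class,
                         sample_ids=test_ids)
    train_roc = roc_auc(train_pod.table["pod_fraction"], labels.loc[train_ids],
                        positive_class)
    test_roc = roc_auc(test_pod.table["pod_fraction"], labels.loc[test_ids],
                       positive_class)
    manifest = {
        "train_ids": list(train_ids),
        "test_ids": list(test_ids),
        "n_candidates": len(cand),
        "markers": markers_,
        "optimal_count": selection.optimal_count,
        "n_trees": n_trees,
        "k": k,
        "n_repeats": n_repeats,
        "p_threshold": p_threshold,
        "abundance_threshold": abundance_threshold,
        "seed": seed,
        "train_pod_source": train_pod.source,
    }
    return TrainTestResult(train_roc, test_roc, train_pod, test_pod,
                           markers_, selection, cand, list(train_ids),
                           list(test_ids), manifest)
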
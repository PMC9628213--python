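"""Alpha/beta diversity, ordination, and permutation tests.

Alpha metrics follow the mothur conventions: bias-corrected Chao1, ACE with
rare-class cutoff 10, Shannon in nats, and Simpson as the dominance form
D = Σ nᵢ(nᵢ−1) / (N(N−1)).  Beta diversity offers Bray-Curtis, binary
Jaccard, and the two UniFrac variants (tree-based, via scikit-bio).  PCoA is
the classical double-centred eigendecomposition.  PERMANOVA (pseudo-F) and
ANOSIM (rank-based R) use label permutation with the (1+b)/(1+m) p-value
estimator, switching to exhaustive enumeration of all distinct label
assignments whenever there are at most ``ENUMERATION_LIMIT`` of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity as _skbio_beta

from .io import CountTable, check_tree_covers

ENUMERATION_LIMIT = 20_000
ACE_RARE_CUTOFF = 10

BETA_METRICS = ("bray_curtis", "jaccard_binary", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity_vector(counts: np.ndarray) -> dict[str, float]:
    """Alpha metrics for a single sample's count vector.

    Returns observed richness, bias-corrected Chao1, ACE (rare cutoff 10),
    Shannon entropy in nats, and Simpson dominance D (with 1−D alongside).
    """
    x = np.asarray(counts)
    if np.any(x < 0):
        raise ValueError("negative counts")
    x = x[x > 0].astype(np.int64)
    if x.size == 0:
        raise ValueError("all-zero count vector")
    n_total = int(x.sum())
    s_obs = int(x.size)

    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))

    rare = x[x <= ACE_RARE_CUTOFF]
    abund = x[x > ACE_RARE_CUTOFF]
    s_rare, s_abund = rare.size, abund.size
    n_rare = int(rare.sum())
    if s_rare == 0:
        ace = float(s_abund)
    else:
        c_ace = 1.0 - f1 / n_rare if n_rare > 0 else 0.0
        if c_ace == 0.0:
            # every rare individual is a singleton; ACE degenerates to Chao1
            ace = float(chao1)
        else:
            ssum = sum(i * (i - 1) * int(np.sum(rare == i)) for i in range(1, ACE_RARE_CUTOFF + 1))
            if n_rare > 1:
                gamma2 = max((s_rare / c_ace) * ssum / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
            else:
                gamma2 = 0.0
            ace = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2

    p = x / n_total
    shannon = float(-np.sum(p * np.log(p)))
    if n_total > 1:
        simpson = float(np.sum(x * (x - 1.0)) / (n_total * (n_total - 1.0)))
    else:
        simpson = 1.0
    return {
        "observed_features": s_obs,
        "chao1": float(chao1),
        "ace": float(ace),
        "shannon": shannon,
        "simpson": simpson,
        "inverse_simpson_complement": 1.0 - simpson,
    }


def alpha_diversity(counts: CountTable) -> pd.DataFrame:
    """Per-sample alpha diversity table (samples as rows)."""
    rows = {s: alpha_diversity_vector(counts.data[s].to_numpy()) for s in counts.sample_ids}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def _rarefy_vector(x: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    reads = np.repeat(np.arange(x.size), x)
    keep = rng.choice(reads.size, size=depth, replace=False)
    return np.bincount(reads[keep], minlength=x.size)


def rarefy(counts: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with totals below ``depth`` are dropped (logged via the returned
    table's columns).  Reproducible given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = counts.sample_totals()
    kept = [s for s in counts.sample_ids if totals[s] >= depth]
    if not kept:
        raise ValueError(f"no sample reaches depth {depth}")
    out = {}
    for s in kept:
        x = counts.data[s].to_numpy()
        out[s] = x if totals[s] == depth else _rarefy_vector(x, depth, rng)
    df = pd.DataFrame(out, index=counts.feature_ids)
    return CountTable(df)


def rarefaction_curve(
    counts: CountTable,
    depths: np.ndarray | list[int],
    replicates: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean observed richness per sample across a grid of rarefaction depths.

    Depths beyond a sample's total are skipped for that sample (NaN).
    """
    depths = np.asarray(sorted(depths))
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    rng = np.random.default_rng(seed)
    totals = counts.sample_totals()
    result = pd.DataFrame(index=counts.sample_ids, columns=depths, dtype=float)
    for s in counts.sample_ids:
        x = counts.data[s].to_numpy()
        for d in depths:
            if d > totals[s]:
                continue
            if d == totals[s]:
                result.loc[s, d] = float(np.count_nonzero(x))
                continue
            richness = [np.count_nonzero(_rarefy_vector(x, int(d), rng))
                        for _ in range(replicates)]
            result.loc[s, d] = float(np.mean(richness))
    return result


def expected_rarefied_richness(x: np.ndarray, depth: int) -> float:
    """Hypergeometric closed form E[S] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d))."""
    x = np.asarray(x)
    x = x[x > 0]
    n_total = int(x.sum())
    log_denom = math.lgamma(n_total + 1) - math.lgamma(depth + 1) - math.lgamma(n_total - depth + 1)
    total = 0.0
    for ni in x:
        m = n_total - int(ni)
        if m < depth:
            total += 1.0
            continue
        log_num = math.lgamma(m + 1) - math.lgamma(depth + 1) - math.lgamma(m - depth + 1)
        total += 1.0 - math.exp(log_num - log_denom)
    return total


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def beta_distance(
    counts: CountTable,
    metric: str,
    tree: TreeNode | None = None,
) -> DistanceMatrix:
    """Sample × sample dissimilarity matrix for one of the four metrics.

    ``unweighted_unifrac`` and ``weighted_unifrac`` (normalised variant)
    require a rooted tree covering every feature; Bray-Curtis uses raw
    counts; binary Jaccard uses presence/absence.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    mat = counts.matrix.T  # samples x features
    ids = counts.sample_ids
    if metric == "bray_curtis":
        d = pdist(mat, metric="braycurtis")
        return DistanceMatrix(squareform(d), ids=ids)
    if metric == "jaccard_binary":
        d = pdist(mat > 0, metric="jaccard")
        return DistanceMatrix(squareform(d), ids=ids)
    if tree is None:
        raise ValueError(f"{metric} requires a phylogenetic tree")
    check_tree_covers(tree, counts.feature_ids)
    kwargs = {"tree": tree, "taxa": counts.feature_ids}
    if metric == "weighted_unifrac":
        kwargs["normalized"] = True
    return _skbio_beta(metric, mat, ids=ids, **kwargs)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes, axes named PC1, PC2, ...
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric multidimensional scaling (principal coordinates).

    The squared distance matrix is double-centred (−½ J D² J) and
    eigendecomposed; coordinates are eigenvectors scaled by the square roots
    of the positive eigenvalues.  Negative eigenvalues are reported but
    excluded from the embedding.
    """
    d = dm.data
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12 * max(evals.max(), 1.0), 0.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str  # "permutation" or "exhaustive"
    test: str  # "permanova" or "anosim"
    seed: int | None = None


def _group_arrays(dm: DistanceMatrix, groups) -> tuple[np.ndarray, np.ndarray]:
    labels = pd.Series(groups)
    if set(labels.index) >= set(dm.ids) and not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[list(dm.ids)]
    codes, uniques = pd.factorize(labels.to_numpy())
    if len(uniques) < 2:
        raise ValueError("at least two groups are required")
    counts = np.bincount(codes)
    if np.any(counts < 1):
        raise ValueError("every group needs at least one sample")
    return codes, counts


def _n_assignments(group_sizes: np.ndarray) -> float:
    n = int(group_sizes.sum())
    log_m = math.lgamma(n + 1) - sum(math.lgamma(int(g) + 1) for g in group_sizes)
    return math.exp(log_m)


def _iter_assignments(codes: np.ndarray):
    """Yield every distinct assignment of the label multiset to positions."""
    n = len(codes)
    sizes = np.bincount(codes)

    def rec(positions: tuple[int, ...], remaining: list[int], out: np.ndarray):
        if not remaining:
            yield out.copy()
            return
        g = remaining[0]
        size = sizes[g]
        for chosen in combinations(positions, size):
            out[list(chosen)] = g
            rest = tuple(p for p in positions if p not in set(chosen))
            yield from rec(rest, remaining[1:], out)

    yield from rec(tuple(range(n)), list(range(len(sizes))), np.empty(n, dtype=int))


def _permanova_stat(d2: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> float:
    n = d2.shape[0]
    g = counts.size
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for k in range(g):
        idx = np.flatnonzero(codes == k)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else 0.0
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def _anosim_stat(rank_mat: np.ndarray, codes: np.ndarray) -> float:
    n = rank_mat.shape[0]
    same = codes[:, None] == codes[None, :]
    iu = np.triu_indices(n, 1)
    within = rank_mat[iu][same[iu]]
    between = rank_mat[iu][~same[iu]]
    m = n * (n - 1) / 2.0
    return float((between.mean() - within.mean()) / (m / 2.0))


def _permutation_test(
    stat_fn,
    codes: np.ndarray,
    counts: np.ndarray,
    n_permutations: int,
    seed: int | None,
) -> tuple[float, float, int, str]:
    observed = stat_fn(codes)
    n_distinct = _n_assignments(counts)
    if n_distinct <= ENUMERATION_LIMIT:
        stats_all = np.array([stat_fn(a) for a in _iter_assignments(codes)])
        # includes the observed assignment, so p >= 1/n_distinct
        p = float(np.mean(stats_all >= observed - 1e-12))
        return observed, p, int(round(n_distinct)), "exhaustive"
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if stat_fn(perm) >= observed - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_permutations)
    return observed, p, n_permutations, "permutation"


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way PERMANOVA pseudo-F test on a distance matrix.

    ``groups`` is a sequence or Series of labels (Series indexed by sample ID
    are aligned to the matrix).  p-values use (1+b)/(1+m) under random
    permutation, or exact enumeration when the number of distinct label
    assignments is at most ``ENUMERATION_LIMIT``.
    """
    codes, counts = _group_arrays(dm, groups)
    d2 = dm.data**2
    stat, p, nperm, method = _permutation_test(
        lambda c: _permanova_stat(d2, c, counts), codes, counts, n_permutations, seed
    )
    return PermutationTestResult(stat, p, nperm, method, "permanova", seed)


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """ANOSIM R statistic and permutation p-value.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 and midranks over all pairwise distances; R ∈ [−1, 1].
    """
    codes, counts = _group_arrays(dm, groups)
    n = dm.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = stats.rankdata(dm.data[iu])
    rank_mat = np.zeros((n, n))
    rank_mat[iu] = ranks
    rank_mat = rank_mat + rank_mat.T
    stat, p, nperm, method = _permutation_test(
        lambda c: _anosim_stat(rank_mat, c), codes, counts, n_permutations, seed
    )
    return PermutationTestResult(stat, p, nperm, method, "anosim", seed)
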
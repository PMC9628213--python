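"""Taxonomic aggregation, per-taxon group tests, Venn partition, Spearman
correlation maps, and cohort-table statistics from printed summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RANKS, CountTable, TaxonomyTable

#: switch from exact to tie-corrected normal Mann-Whitney above this group size
EXACT_MW_LIMIT = 8


# ---------------------------------------------------------------------------
# aggregation / normalisation
# ---------------------------------------------------------------------------

def aggregate_taxa(counts: CountTable, taxonomy: TaxonomyTable, rank: str) -> CountTable:
    """Sum counts of features sharing the full lineage down to ``rank``.

    The grouping key is the whole upstream lineage joined with ``;`` so two
    genera with the same name in different families stay separate, and
    features unclassified at ``rank`` are pooled under their parent lineage
    plus the unclassified sentinel.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    depth = RANKS.index(rank) + 1
    tax = taxonomy.filter_features(counts.feature_ids)
    keys = tax.data.iloc[:, :depth].apply(";".join, axis=1)
    grouped = counts.data.groupby(keys.to_numpy()).sum()
    grouped = grouped.sort_index()
    return CountTable(grouped)


def relative_abundance(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    df = counts.data if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample columns: {bad}")
    return df / totals


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U with midranks.

    Exact enumeration when both groups have at most ``EXACT_MW_LIMIT``
    observations and there are no cross-group ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    use_exact = max(len(x), len(y)) <= EXACT_MW_LIMIT and not ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def group_compare(
    features: pd.DataFrame,
    groups,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature nonparametric comparison across groups.

    ``features`` is features × samples (e.g. relative abundances);
    ``groups`` is a label per sample.  Two groups use Mann-Whitney, more use
    Kruskal-Wallis (tie-corrected).  Raw two-sided p-values are reported; a
    Benjamini-Hochberg ``q`` column is added when ``bh_adjust`` is set.
    """
    labels = pd.Series(groups)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[features.columns]
    labels = labels.astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lv in levels:
        if (labels == lv).sum() == 0:
            raise ValueError(f"group {lv!r} has no samples")
    cols = {lv: features.loc[:, labels[labels == lv].index].to_numpy() for lv in levels}

    rows = []
    for i, feat in enumerate(features.index):
        samples = [cols[lv][i] for lv in levels]
        row = {"feature": feat}
        for lv, vals in zip(levels, samples):
            row[f"mean_{lv}"] = float(np.mean(vals))
        if np.ptp(np.concatenate(samples)) == 0:
            # identical values everywhere: no evidence either way
            row.update(statistic=np.nan, p_value=1.0,
                       test="mann_whitney" if len(levels) == 2 else "kruskal_wallis",
                       method="degenerate")
            rows.append(row)
            continue
        if len(levels) == 2:
            stat, p, method = mann_whitney(samples[0], samples[1])
            row.update(statistic=stat, p_value=p, test="mann_whitney", method=method)
        else:
            stat, p = stats.kruskal(*samples)
            row.update(statistic=float(stat), p_value=float(p),
                       test="kruskal_wallis", method="chi2")
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    if bh_adjust:
        out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


# ---------------------------------------------------------------------------
# Venn partition of detected features
# ---------------------------------------------------------------------------

def venn_partition(counts: CountTable, groups) -> dict:
    """Shared/unique detected-feature counts for a two-group design.

    A feature is present in a group iff it has a nonzero count in at least
    one sample of that group.
    """
    labels = pd.Series(groups)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[counts.sample_ids]
    labels = labels.astype(str)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("venn_partition requires exactly two groups")
    present = {}
    for lv in levels:
        sub = counts.data.loc[:, labels[labels == lv].index]
        present[lv] = set(sub.index[(sub > 0).any(axis=1)])
    shared = present[levels[0]] & present[levels[1]]
    return {
        "groups": levels,
        "shared": len(shared),
        "unique": {lv: len(present[lv] - shared) for lv in levels},
        "total_detected": len(present[levels[0]] | present[levels[1]]),
        "shared_features": sorted(shared),
        "unique_features": {lv: sorted(present[lv] - shared) for lv in levels},
    }


# ---------------------------------------------------------------------------
# Spearman correlation map
# ---------------------------------------------------------------------------

def _tier(p: float) -> str:
    if p <= 0.01:
        return "strong"
    if p <= 0.05:
        return "moderate"
    return "none"


def spearman_map(
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    include_taxon_taxon: bool = False,
) -> pd.DataFrame:
    """Spearman ρ, two-sided p, and evidence tier for feature/covariate pairs.

    Tiers follow the heatmap convention: ``strong`` for p ≤ 0.01,
    ``moderate`` for 0.01 < p ≤ 0.05, else ``none``.  Missing covariate
    values use pairwise-complete observations; pairs with fewer than three
    complete observations or a constant vector are reported with a reason
    instead of a coefficient.
    """
    rows = []

    def one_pair(kind, a_name, a_vals, b_name, b_vals):
        a = np.asarray(a_vals, dtype=float)
        b = np.asarray(b_vals, dtype=float)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        row = {"kind": kind, "a": a_name, "b": b_name, "n": int(ok.sum())}
        if ok.sum() < 3:
            row.update(rho=np.nan, p_value=np.nan, tier="none",
                       note="fewer than 3 paired observations")
        elif np.ptp(a) == 0 or np.ptp(b) == 0:
            row.update(rho=np.nan, p_value=np.nan, tier="none",
                       note="constant vector; rho undefined")
        else:
            rho, p = stats.spearmanr(a, b)
            row.update(rho=float(rho), p_value=float(p), tier=_tier(float(p)), note="")
        rows.append(row)

    if covariates is not None:
        cov = covariates.loc[features.columns]
        numeric = cov.select_dtypes(include=[np.number])
        for feat in features.index:
            for cname in numeric.columns:
                one_pair("taxon_covariate", feat, features.loc[feat],
                         cname, numeric[cname])
    if include_taxon_taxon:
        feats = list(features.index)
        for i, fa in enumerate(feats):
            for fb in feats[i + 1:]:
                one_pair("taxon_taxon", fa, features.loc[fa], fb, features.loc[fb])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-table statistics from printed summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryTestResult:
    statistic: float
    df: float
    p_value: float
    test: str


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> SummaryTestResult:
    """Welch's unequal-variance t-test from group summaries.

    t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂) with the Welch–Satterthwaite degrees of
    freedom; two-sided p.  Useful for reproducing cohort tables that print
    only mean ± SD per group.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("SDs must be non-negative and not both zero")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return SummaryTestResult(float(t), float(df), float(p), "welch_t")


def student_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> SummaryTestResult:
    """Pooled-variance Student t-test from group summaries (for comparison)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return SummaryTestResult(float(t), float(df), float(p), "student_t")


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> SummaryTestResult:
    """Yates continuity-corrected χ² test on a 2×2 contingency table.

    χ² = N(|ad−bc| − N/2)² / (R₁R₂C₁C₂), clamped to 0 when |ad−bc| ≤ N/2;
    one degree of freedom.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin in 2x2 table")
    delta = abs(a * d - b * c)
    if delta <= n / 2.0:
        chi2 = 0.0
    else:
        chi2 = n * (delta - n / 2.0) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, 1)) if chi2 > 0 else 1.0
    return SummaryTestResult(float(chi2), 1.0, p, "yates_chi2")
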
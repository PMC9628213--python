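"""LDA effect size (LEfSe-style) differential-feature detection.

The procedure ranks features that discriminate classes by combining a
nonparametric class-difference screen with a linear-discriminant effect
size:

1. every sample is normalised to a total of 1e6 (per-million scale);
2. each feature is screened with a Kruskal-Wallis test across classes and
   dropped when p ≥ α (default 0.05);
3. surviving features enter a bootstrapped one-component linear
   discriminant: on each of ``n_boot`` subsamples (a fraction of each class,
   drawn with replacement) the discriminant direction is fit with a
   ridge-regularised pooled covariance, and the per-feature effect size is
   the average of the feature's raw class-mean difference and the
   feature's share of the class separation along the discriminant axis;
4. the LDA score is log10 of the bootstrap-mean effect, floored at
   log10(1) = 0; features pass when p < α and score ≥ the threshold
   (default 2.5);
5. the enriched class is the class with the larger mean normalised
   abundance; with more than two classes each class is contrasted
   one-against-all and a feature is scored for its enriched class.

Subclass-aware designs (a within-class Wilcoxon stage) are not modelled:
with no subclass column the canonical subclass stage is a no-op, which is
the only design handled here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NORMALIZATION_TOTAL = 1e6


@dataclass
class LefseParams:
    alpha: float = 0.05
    lda_threshold: float = 2.5
    n_boot: int = 30
    boot_fraction: float = 2.0 / 3.0
    seed: int | None = None
    ridge: float = 1e-6  # pooled-covariance ridge, scaled by its trace


def _lda_direction(x: np.ndarray, y: np.ndarray, ridge: float) -> np.ndarray:
    """Unit direction of a binary linear discriminant with ridge pooling."""
    m1 = x[y == 1].mean(axis=0)
    m0 = x[y == 0].mean(axis=0)
    xc = x.copy()
    xc[y == 1] -= m1
    xc[y == 0] -= m0
    n = x.shape[0]
    sw = xc.T @ xc / max(n - 2, 1)
    tr = np.trace(sw)
    eps = ridge * (tr if tr > 0 else 1.0)
    sw_reg = sw + eps * np.eye(sw.shape[0])
    w = np.linalg.solve(sw_reg, m1 - m0)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def _bootstrap_effect_sizes(
    x: np.ndarray,
    y: np.ndarray,
    params: LefseParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean per-feature effect size over bootstrap discriminant fits.

    ``x`` is samples × features (normalised), ``y`` binary class indicator.
    """
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    k1 = max(int(np.ceil(params.boot_fraction * idx1.size)), 2)
    k0 = max(int(np.ceil(params.boot_fraction * idx0.size)), 2)
    effects = np.zeros((params.n_boot, x.shape[1]))
    for b in range(params.n_boot):
        s1 = rng.choice(idx1, size=k1, replace=True)
        s0 = rng.choice(idx0, size=k0, replace=True)
        xs = np.vstack([x[s1], x[s0]])
        ys = np.concatenate([np.ones(k1, dtype=int), np.zeros(k0, dtype=int)])
        w = _lda_direction(xs, ys, params.ridge)
        mdiff = xs[ys == 1].mean(axis=0) - xs[ys == 0].mean(axis=0)
        # separation along the discriminant axis, apportioned to features
        axis_sep = abs(float(w @ mdiff))
        w_final = np.abs(w) * axis_sep
        effects[b] = 0.5 * (np.abs(mdiff) + w_final)
    return effects.mean(axis=0)


def lefse(
    features: pd.DataFrame,
    classes,
    params: LefseParams | None = None,
) -> pd.DataFrame:
    """Run the LDA-effect-size procedure on a features × samples table.

    ``classes`` is one label per sample (a Series indexed by sample ID is
    aligned to the columns).  Returns one row per feature with the enriched
    class, Kruskal-Wallis p, LDA score (log10), pass flag, and an exclusion
    reason for screened-out features.
    """
    params = params or LefseParams()
    labels = pd.Series(classes)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.loc[features.columns]
    labels = labels.astype(str)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least two classes")
    for lv in levels:
        if (labels == lv).sum() < 3:
            raise ValueError(f"class {lv!r} has fewer than 3 samples")

    # step 1: per-sample normalisation to 1e6
    norm = features / features.sum(axis=0) * NORMALIZATION_TOTAL
    x_all = norm.to_numpy().T  # samples x features
    y_codes = labels.to_numpy()

    class_means = {
        lv: norm.loc[:, labels[labels == lv].index].mean(axis=1) for lv in levels
    }
    mean_mat = pd.DataFrame(class_means)
    enriched = mean_mat.idxmax(axis=1)

    # step 2: Kruskal-Wallis screen
    kw_p = np.ones(len(features.index))
    excluded_reason = np.array([""] * len(features.index), dtype=object)
    raw = features.to_numpy()
    groups_np = [x_all[y_codes == lv] for lv in levels]
    for i in range(len(features.index)):
        vals = [g[:, i] for g in groups_np]
        # constancy is judged on the raw input: a feature identical in every
        # sample carries no class signal even if normalisation perturbs it
        if np.ptp(raw[i]) == 0 or np.ptp(np.concatenate(vals)) == 0:
            kw_p[i] = 1.0
            excluded_reason[i] = "constant feature"
            continue
        kw_p[i] = float(stats.kruskal(*vals).pvalue)
    survivors = np.flatnonzero((kw_p < params.alpha) & (excluded_reason == ""))
    excluded_reason[(kw_p >= params.alpha) & (excluded_reason == "")] = (
        "kruskal-wallis p >= alpha"
    )

    scores = np.zeros(len(features.index))
    if survivors.size > 0:
        rng = np.random.default_rng(params.seed)
        x_surv = x_all[:, survivors]
        if len(levels) == 2:
            y_bin = (y_codes == levels[0]).astype(int)
            eff = _bootstrap_effect_sizes(x_surv, y_bin, params, rng)
            scores[survivors] = np.log10(np.maximum(eff, 1.0))
        else:
            # one-against-all per class; each feature keeps the score of its
            # enriched class
            eff_by_class = {}
            for lv in levels:
                y_bin = (y_codes == lv).astype(int)
                eff_by_class[lv] = _bootstrap_effect_sizes(x_surv, y_bin, params, rng)
            for pos, i in enumerate(survivors):
                lv = enriched.iloc[i]
                scores[i] = np.log10(max(eff_by_class[lv][pos], 1.0))

    out = pd.DataFrame(
        {
            "enriched_class": enriched.to_numpy(),
            "kw_p": kw_p,
            "lda_score": scores,
            "excluded": excluded_reason != "",
            "reason": excluded_reason,
        },
        index=features.index,
    )
    out["pass"] = (out["kw_p"] < params.alpha) & (out["lda_score"] >= params.lda_threshold)
    return out


def lefse_report(result: pd.DataFrame) -> str:
    """Passing features as a ranked TSV-style text table.

    Rows are grouped by enriched class and sorted by descending LDA score;
    ties break lexicographically on the feature ID so the output is fully
    deterministic.
    """
    passing = result[result["pass"]].copy()
    passing = passing.reset_index().rename(columns={"index": "feature"})
    if "feature" not in passing.columns:  # index already named
        passing = passing.rename(columns={passing.columns[0]: "feature"})
    passing = passing.sort_values(
        by=["enriched_class", "lda_score", "feature"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    lines = ["feature\tenriched_class\tkw_p\tlda_score"]
    for _, row in passing.iterrows():
        lines.append(
            f"{row['feature']}\t{row['enriched_class']}\t"
            f"{row['kw_p']:.6g}\t{row['lda_score']:.4f}"
        )
    return "\n".join(lines) + "\n"
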
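"""Synthetic ASV dataset generator with planted ground truth.

Emulates the shape of a two-group 16S case-control study: 27 samples per
group, ~976 ASVs, library sizes uniform on 35,925–120,795 reads, a minority
of ASVs carrying planted group effects, and clinical covariates linked to
chosen ASVs at requested Spearman strengths.

The count model is Dirichlet-multinomial: a log-normal baseline composition
is drawn once, the case-group composition multiplies the differential
features by their fold changes and renormalises, and each sample's counts
are a multinomial draw from a Dirichlet-perturbed composition whose
concentration (``overdispersion`` × composition) controls between-sample
variability.  Covariates are generated through a rank-preserving Gaussian
copula so that target Spearman correlations with the realised feature
abundances are hit in expectation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io import (
    RANKS,
    RANK_PREFIXES,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    unclassified_label,
    write_tree,
)

GROUP_CASE = "case"
GROUP_CONTROL = "control"


@dataclass
class CovariateLink:
    """Requested Spearman correlation between one feature and one covariate."""

    feature: str | int  # feature ID, or index into the differential set
    covariate: str
    spearman: float

    def __post_init__(self):
        if abs(self.spearman) >= 1:
            raise ValueError(
                f"covariate link strength must satisfy |rho| < 1, got {self.spearman}"
            )


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the study shape."""

    n_per_group: int = 27
    n_features: int = 976
    depth_range: tuple[int, int] = (35_925, 120_795)
    n_differential: int = 5
    fold_changes: tuple[float, ...] | float = 4.0
    overdispersion: float = 200.0
    baseline_log_sigma: float = 1.5
    covariate_links: tuple[CovariateLink, ...] = ()
    seed: int = 0
    #: differential features are drawn from features whose baseline relative
    #: abundance exceeds this floor, so planted effects are detectable at
    #: realistic sequencing depth.
    differential_abundance_floor: float = 0.001

    def __post_init__(self):
        if self.n_differential > self.n_features:
            raise ValueError("n_differential cannot exceed n_features")
        if self.depth_range[0] > self.depth_range[1]:
            raise ValueError("depth_range min must be <= max")
        folds = self.resolved_fold_changes()
        if any(f <= 0 for f in folds):
            raise ValueError("fold changes must be positive")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")

    def resolved_fold_changes(self) -> tuple[float, ...]:
        if isinstance(self.fold_changes, (int, float)):
            return tuple([float(self.fold_changes)] * self.n_differential)
        if len(self.fold_changes) != self.n_differential:
            raise ValueError("fold_changes length must equal n_differential")
        return tuple(float(f) for f in self.fold_changes)


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`simulate_dataset`."""

    differential_features: list[str]
    fold_changes: dict[str, float]
    baseline_composition: dict[str, float]
    covariate_links: list[dict]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class SyntheticDataset:
    counts: CountTable
    taxonomy: TaxonomyTable
    metadata: SampleMetadata
    tree: TreeNode
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.write_tsv(outdir / "counts.tsv")
        self.taxonomy.write_tsv(outdir / "taxonomy.tsv")
        self.metadata.write_tsv(outdir / "metadata.tsv")
        write_tree(self.tree, outdir / "tree.nwk")
        self.truth.to_json(outdir / "truth.json")


def _random_taxonomy(feature_ids: list[str], rng: np.random.Generator) -> TaxonomyTable:
    """Nest features into genera/families/… with geometric group sizes."""
    n = len(feature_ids)
    genus_of = _geometric_partition(n, mean_size=6.0, rng=rng)
    n_genera = genus_of.max() + 1
    family_of_genus = _geometric_partition(n_genera, mean_size=3.0, rng=rng)
    n_fam = family_of_genus.max() + 1
    order_of_family = _geometric_partition(n_fam, mean_size=2.5, rng=rng)
    n_ord = order_of_family.max() + 1
    class_of_order = _geometric_partition(n_ord, mean_size=2.0, rng=rng)
    n_cls = class_of_order.max() + 1
    phylum_of_class = _geometric_partition(n_cls, mean_size=2.0, rng=rng)

    rows = {}
    for i, fid in enumerate(feature_ids):
        g = genus_of[i]
        f = family_of_genus[g]
        o = order_of_family[f]
        c = class_of_order[o]
        p = phylum_of_class[c]
        rows[fid] = [
            "k__Bacteria",
            f"p__Phylum{p:02d}",
            f"c__Class{c:03d}",
            f"o__Order{o:03d}",
            f"f__Family{f:03d}",
            f"g__Genus{g:04d}",
            unclassified_label("species"),
        ]
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def _geometric_partition(n_items: int, mean_size: float, rng: np.random.Generator) -> np.ndarray:
    """Assign n_items to consecutive groups with Geometric(1/mean) sizes."""
    group = np.empty(n_items, dtype=int)
    g = 0
    i = 0
    p = 1.0 / mean_size
    while i < n_items:
        size = rng.geometric(p)
        group[i : i + size] = g
        i += size
        g += 1
    return group


def _random_tree(feature_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Random bifurcating tree over the features, Exp(0.1) branch lengths."""
    nodes = [TreeNode(name=fid, length=float(rng.exponential(0.1))) for fid in feature_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def _copula_covariate(
    values: np.ndarray, rho_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Covariate with target Spearman ``rho_s`` against ``values``.

    The realised values are converted to normal scores (random tie-break),
    then a correlated Gaussian is drawn at the Pearson level
    2·sin(π·rho_s/6) that a bivariate normal needs to hit the Spearman
    target.
    """
    n = len(values)
    jitter = rng.uniform(0, 1e-9, size=n)
    ranks = stats.rankdata(values + jitter, method="ordinal")
    z = stats.norm.ppf((ranks - 0.5) / n)
    rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
    eps = rng.standard_normal(n)
    return rho_p * z + math.sqrt(1.0 - rho_p**2) * eps


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete synthetic dataset plus its ground-truth record.

    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features
    feature_ids = [f"ASV{i + 1:04d}" for i in range(n_feat)]

    # Baseline composition: log-normal, normalised.
    base = np.exp(rng.normal(0.0, config.baseline_log_sigma, size=n_feat))
    base /= base.sum()

    # Plant fold changes on features abundant enough to be observable.
    folds = config.resolved_fold_changes()
    eligible = np.flatnonzero(base >= config.differential_abundance_floor)
    if config.n_differential > 0 and len(eligible) < config.n_differential:
        # fall back to the most abundant features
        eligible = np.argsort(base)[::-1][: max(config.n_differential, 1)]
    diff_idx = (
        rng.choice(eligible, size=config.n_differential, replace=False)
        if config.n_differential > 0
        else np.array([], dtype=int)
    )
    case_comp = base.copy()
    for idx, fold in zip(diff_idx, folds):
        case_comp[idx] *= fold
    case_comp /= case_comp.sum()

    # Sample counts: Dirichlet-multinomial per sample.
    n_per = config.n_per_group
    sample_ids = [f"CASE{i + 1:03d}" for i in range(n_per)] + [
        f"CTRL{i + 1:03d}" for i in range(n_per)
    ]
    comps = [case_comp] * n_per + [base] * n_per
    lo, hi = config.depth_range
    depths = rng.integers(lo, hi + 1, size=2 * n_per)
    counts = np.zeros((n_feat, 2 * n_per), dtype=np.int64)
    for j, comp in enumerate(comps):
        theta = rng.dirichlet(config.overdispersion * comp)
        counts[:, j] = rng.multinomial(depths[j], theta)
    # Guard the CountTable invariant (positive sample totals) — depths >= 1.
    count_df = pd.DataFrame(counts, index=feature_ids, columns=sample_ids)
    count_table = CountTable(count_df)

    # Metadata: group + filler clinical covariates + linked covariates.
    groups = [GROUP_CASE] * n_per + [GROUP_CONTROL] * n_per
    meta = pd.DataFrame({"group": groups}, index=sample_ids)
    meta["age"] = np.round(rng.normal(55.0, 8.0, size=2 * n_per), 1)
    meta["bmi"] = np.round(rng.normal(23.5, 3.0, size=2 * n_per), 1)

    rel = counts / counts.sum(axis=0, keepdims=True)
    links_out = []
    for link in config.covariate_links:
        if isinstance(link.feature, int):
            if config.n_differential > 0:
                fid = feature_ids[diff_idx[link.feature % len(diff_idx)]]
            else:
                fid = feature_ids[link.feature % n_feat]
        else:
            fid = str(link.feature)
        fi = feature_ids.index(fid)
        meta[link.covariate] = np.round(_copula_covariate(rel[fi], link.spearman, rng), 4)
        links_out.append({"feature": fid, "covariate": link.covariate,
                          "spearman": link.spearman})

    metadata = SampleMetadata(meta, group_col="group")
    taxonomy = _random_taxonomy(feature_ids, rng)
    tree = _random_tree(feature_ids, rng)

    truth = SyntheticTruth(
        differential_features=[feature_ids[i] for i in diff_idx],
        fold_changes={feature_ids[i]: f for i, f in zip(diff_idx, folds)},
        baseline_composition=dict(zip(feature_ids, base.tolist())),
        covariate_links=links_out,
        seed=config.seed,
    )
    return SyntheticDataset(count_table, taxonomy, metadata, tree, truth)


def simulate_null(config: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Dataset with no planted effects: both groups share one composition.

    Used to verify false-positive control of the downstream tests.
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    cfg = SyntheticConfig(
        **{**asdict_shallow(config), "n_differential": 0, "fold_changes": ()}
    )
    return simulate_dataset(cfg)


def asdict_shallow(config: SyntheticConfig) -> dict:
    return {
        "n_per_group": config.n_per_group,
        "n_features": config.n_features,
        "depth_range": config.depth_range,
        "n_differential": config.n_differential,
        "fold_changes": config.fold_changes,
        "overdispersion": config.overdispersion,
        "baseline_log_sigma": config.baseline_log_sigma,
        "covariate_links": config.covariate_links,
        "seed": config.seed,
        "differential_abundance_floor": config.differential_abundance_floor,
    }
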
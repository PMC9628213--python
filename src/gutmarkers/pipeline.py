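"""End-to-end orchestration: one call runs the full study design.

``run_pipeline`` executes the enabled stages in order — alpha diversity,
beta diversity with PERMANOVA/ANOSIM, Venn partition, per-rank group
comparisons, LEfSe, taxon–covariate correlations, the diagnostic marker
model, and metadata-defined subgroup analyses (which reuse the identical
comparison/LEfSe operations on sample subsets) — writing one TSV per stage
plus a JSON manifest with seeds, thresholds, and SHA-256 hashes of every
output.  ``report`` renders a run directory as a markdown summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance, diversity, lefse as lefse_mod, markers as markers_mod
from .io import (
    CountTable,
    SampleMetadata,
    TaxonomyTable,
    align,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)

logger = logging.getLogger(__name__)

MIN_SUBGROUP_SIZE = 3


@dataclass
class SubgroupSpec:
    """Metadata-defined subset contrast (e.g. a severity stage column)."""

    column: str
    levels: list[str] | None = None  # None: use all observed levels
    run_markers: bool = False


@dataclass
class RunConfig:
    counts: str
    metadata: str
    taxonomy: str | None = None
    tree: str | None = None
    group_col: str = "group"
    positive_class: str | None = None
    outdir: str = "results"
    seed: int = 0
    # stage toggles
    run_alpha: bool = True
    run_beta: bool = True
    run_venn: bool = True
    run_compare: bool = True
    run_lefse: bool = True
    run_correlations: bool = True
    run_markers: bool = True
    # stage parameters
    rarefy_depth: int | None = None  # even-depth subsampling before analysis
    beta_metrics: tuple[str, ...] = ("bray_curtis", "jaccard_binary")
    n_permutations: int = 10_000
    compare_ranks: tuple[str, ...] = ("phylum", "genus")
    lefse_alpha: float = 0.05
    lda_threshold: float = 2.5
    p_threshold: float = 0.05
    abundance_threshold: float = 0.001
    test_fraction: float = 1.0 / 3.0
    cv_folds: int = 5
    cv_repeats: int = 5
    n_trees: int = 500
    subgroups: list[SubgroupSpec] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        subs = [SubgroupSpec(**s) for s in raw.pop("subgroups", [])]
        cfg = cls(**raw, subgroups=subs)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def run_pipeline(
    config: RunConfig | str | Path,
    counts: CountTable | None = None,
    metadata: SampleMetadata | None = None,
    taxonomy: TaxonomyTable | None = None,
    tree=None,
) -> dict:
    """Execute the configured stages and return the manifest.

    Data may be passed in-memory (overriding the config paths), which is
    how the examples and tests drive the pipeline.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if counts is None:
        counts = read_count_table(config.counts)
    if metadata is None:
        metadata = read_metadata(config.metadata, group_col=config.group_col)
    if taxonomy is None and config.taxonomy:
        taxonomy = read_taxonomy(config.taxonomy)
    if tree is None and config.tree:
        tree = read_tree(config.tree)

    view = align(counts, metadata, taxonomy, tree)
    counts, metadata, taxonomy, tree = view.counts, view.metadata, view.taxonomy, view.tree
    if config.rarefy_depth is not None:
        counts = diversity.rarefy(counts, config.rarefy_depth, seed=config.seed)
        metadata = metadata.filter_samples(counts.sample_ids)
    groups = metadata.groups
    positive = config.positive_class or sorted(groups.unique())[0]

    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(
                 ["beta", "lefse", "markers", "subgroup"], ss.spawn(4))}

    manifest: dict = {
        "config": {k: v for k, v in asdict(config).items()},
        "seeds": seeds,
        "n_samples": len(counts.sample_ids),
        "n_features": len(counts.feature_ids),
        "dropped_samples": view.dropped_samples,
        "outputs": {},
        "stages": {},
    }
    outputs: dict[str, Path] = {}

    def record(name: str, path: Path):
        outputs[name] = path

    if config.run_alpha:
        alpha = diversity.alpha_diversity(counts)
        path = outdir / "alpha_diversity.tsv"
        _write_tsv(alpha, path, index_label="sample_id")
        record("alpha_diversity", path)

    if config.run_beta:
        rows = []
        for metric in config.beta_metrics:
            dm = diversity.beta_distance(counts, metric, tree=tree)
            perm = diversity.permanova(dm, groups, config.n_permutations,
                                       seed=seeds["beta"])
            ano = diversity.anosim(dm, groups, config.n_permutations,
                                   seed=seeds["beta"])
            ord_res = diversity.pcoa(dm)
            coord_path = outdir / f"pcoa_{metric}.tsv"
            _write_tsv(ord_res.coordinates, coord_path, index_label="sample_id")
            record(f"pcoa_{metric}", coord_path)
            rows.append({"metric": metric,
                         "permanova_F": perm.statistic, "permanova_p": perm.p_value,
                         "anosim_R": ano.statistic, "anosim_p": ano.p_value,
                         "method": perm.method, "n_permutations": perm.n_permutations})
        beta_path = outdir / "beta_tests.tsv"
        _write_tsv(pd.DataFrame(rows).set_index("metric"), beta_path,
                   index_label="metric")
        record("beta_tests", beta_path)

    if config.run_venn:
        venn = abundance.venn_partition(counts, groups)
        path = outdir / "venn.json"
        path.write_text(json.dumps(
            {k: venn[k] for k in ("groups", "shared", "unique", "total_detected")},
            indent=2, sort_keys=True))
        record("venn", path)

    if config.run_compare and taxonomy is not None:
        for rank in config.compare_ranks:
            agg = abundance.aggregate_taxa(counts, taxonomy, rank)
            rel = abundance.relative_abundance(agg)
            cmp_res = abundance.group_compare(rel, groups)
            path = outdir / f"compare_{rank}.tsv"
            _write_tsv(cmp_res, path, index_label="taxon")
            record(f"compare_{rank}", path)

    if config.run_lefse and taxonomy is not None:
        tables = [abundance.aggregate_taxa(counts, taxonomy, r).data
                  for r in ("phylum", "class", "order", "family", "genus")]
        stacked = pd.concat(tables)
        res = lefse_mod.lefse(
            stacked, groups,
            lefse_mod.LefseParams(alpha=config.lefse_alpha,
                                  lda_threshold=config.lda_threshold,
                                  seed=seeds["lefse"]))
        path = outdir / "lefse.tsv"
        _write_tsv(res, path, index_label="feature")
        record("lefse", path)
        rpt = outdir / "lefse_report.tsv"
        rpt.write_text(lefse_mod.lefse_report(res))
        record("lefse_report", rpt)

    if config.run_correlations:
        cov = metadata.covariates().select_dtypes(include=[np.number])
        if cov.shape[1] > 0:
            rel = abundance.relative_abundance(counts)
            # correlate the most prevalent features to keep the map readable
            prevalence = (rel > 0).sum(axis=1)
            top = rel.loc[prevalence.sort_values(ascending=False, kind="mergesort")
                          .index[:50]]
            cor = abundance.spearman_map(top, cov)
            path = outdir / "correlations.tsv"
            _write_tsv(cor, path, index_label=None)
            record("correlations", path)

    if config.run_markers:
        tt = markers_mod.train_test_evaluate(
            counts, groups, positive_class=positive,
            test_fraction=config.test_fraction,
            p_threshold=config.p_threshold,
            abundance_threshold=config.abundance_threshold,
            k=config.cv_folds, n_repeats=config.cv_repeats,
            n_trees=config.n_trees, seed=seeds["markers"],
        )
        _write_tsv(tt.candidates.table, outdir / "candidates.tsv",
                   index_label="feature")
        record("candidates", outdir / "candidates.tsv")
        _write_tsv(tt.selection.cv_curve, outdir / "cv_curve.tsv", index_label=None)
        record("cv_curve", outdir / "cv_curve.tsv")
        mk = tt.selection.importance.loc[tt.markers]
        _write_tsv(mk, outdir / "markers.tsv", index_label="feature")
        record("markers", outdir / "markers.tsv")
        pod = pd.concat([
            tt.train_pod.table.assign(split="train"),
            tt.test_pod.table.assign(split="test"),
        ])
        _write_tsv(pod, outdir / "pod.tsv", index_label="sample_id")
        record("pod", outdir / "pod.tsv")
        roc_rows = pd.DataFrame([
            {"split": "train", "auc": tt.train_roc.auc,
             "ci_low": tt.train_roc.ci_low, "ci_high": tt.train_roc.ci_high,
             "p_value": tt.train_roc.p_value},
            {"split": "test", "auc": tt.test_roc.auc,
             "ci_low": tt.test_roc.ci_low, "ci_high": tt.test_roc.ci_high,
             "p_value": tt.test_roc.p_value},
        ]).set_index("split")
        _write_tsv(roc_rows, outdir / "roc.tsv", index_label="split")
        record("roc", outdir / "roc.tsv")
        manifest["stages"]["markers"] = tt.manifest

    # subgroup analyses: pure metadata filters re-using the main operations
    for sub in config.subgroups:
        if sub.column not in metadata.data.columns:
            raise ValueError(f"subgroup column {sub.column!r} not in metadata")
        col = metadata.data[sub.column].astype(str)
        levels = sub.levels or sorted(col.dropna().unique())
        keep = col.isin([str(l) for l in levels])
        sizes = col[keep].value_counts()
        if (sizes < MIN_SUBGROUP_SIZE).any() or len(sizes) < 2:
            logger.warning("skipping subgroup %s: a level has < %d samples",
                           sub.column, MIN_SUBGROUP_SIZE)
            manifest["stages"][f"subgroup_{sub.column}"] = "skipped: level too small"
            continue
        ids = list(col[keep].index)
        sub_counts = counts.filter_samples(ids)
        sub_groups = col[keep]
        if taxonomy is not None:
            agg = abundance.aggregate_taxa(sub_counts, taxonomy, "genus")
            rel = abundance.relative_abundance(agg)
            cmp_res = abundance.group_compare(rel, sub_groups)
            path = outdir / f"subgroup_{sub.column}_compare.tsv"
            _write_tsv(cmp_res, path, index_label="taxon")
            record(f"subgroup_{sub.column}_compare", path)
            res = lefse_mod.lefse(
                rel, sub_groups,
                lefse_mod.LefseParams(alpha=config.lefse_alpha,
                                      lda_threshold=config.lda_threshold,
                                      seed=seeds["subgroup"]))
            path = outdir / f"subgroup_{sub.column}_lefse.tsv"
            _write_tsv(res, path, index_label="feature")
            record(f"subgroup_{sub.column}_lefse", path)
        if sub.run_markers and len(levels) == 2:
            tt = markers_mod.train_test_evaluate(
                sub_counts, sub_groups, positive_class=str(levels[0]),
                test_fraction=config.test_fraction,
                p_threshold=config.p_threshold,
                abundance_threshold=config.abundance_threshold,
                k=min(config.cv_folds, int(sizes.min())),
                n_repeats=config.cv_repeats,
                n_trees=config.n_trees, seed=seeds["subgroup"],
            )
            manifest["stages"][f"subgroup_{sub.column}_markers"] = tt.manifest

    for name, path in outputs.items():
        manifest["outputs"][name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str))
    return manifest


def report(outdir: str | Path) -> str:
    """Render a completed run directory as a markdown summary."""
    outdir = Path(outdir)
    lines = ["# Run report", ""]
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [f"- samples: {manifest.get('n_samples', 'n/a')}",
                  f"- features: {manifest.get('n_features', 'n/a')}", ""]
    else:
        manifest = {}

    def section(title: str, filename: str, formatter):
        lines.append(f"## {title}")
        path = outdir / filename
        if not path.exists():
            lines.append("_absent_")
            lines.append("")
            return
        formatter(path)
        lines.append("")

    def table_head(path: Path, n: int = 10):
        df = pd.read_csv(path, sep="\t")
        lines.append(df.head(n).to_string(index=False))

    section("Alpha diversity", "alpha_diversity.tsv", table_head)
    section("Community-level tests", "beta_tests.tsv", table_head)

    def venn_fmt(path: Path):
        venn = json.loads(path.read_text())
        lines.append(f"shared: {venn['shared']}; unique: {venn['unique']}; "
                     f"total detected: {venn['total_detected']}")

    section("Venn partition", "venn.json", venn_fmt)

    def lefse_fmt(path: Path):
        df = pd.read_csv(path, sep="\t")
        hits = df[df["pass"] == True]  # noqa: E712
        lines.append(f"{len(hits)} passing features")
        if len(hits):
            lines.append(hits.sort_values("lda_score", ascending=False)
                         .head(10).to_string(index=False))

    section("LEfSe", "lefse.tsv", lefse_fmt)

    def markers_fmt(path: Path):
        df = pd.read_csv(path, sep="\t")
        lines.append(", ".join(df["feature"].astype(str)))

    section("Selected markers", "markers.tsv", markers_fmt)
    section("ROC", "roc.tsv", table_head)
    return "\n".join(lines) + "\n"
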
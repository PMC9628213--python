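"""Core data model and readers/writers for ASV-level microbiome data.

The central objects are a :class:`CountTable` (integer features × samples
matrix), a :class:`TaxonomyTable` (seven-rank lineage per feature), a
:class:`SampleMetadata` table (group labels plus clinical covariates), and a
rooted phylogenetic tree (a :class:`skbio.TreeNode`).  All file formats are
plain TSV except the tree, which is Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Taxonomic ranks from coarse to fine, with their greengenes-style prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = dict(
    zip(RANKS, ("k", "p", "c", "o", "f", "g", "s"))
)


class ParseError(ValueError):
    """Raised when an input file violates the format contract."""


def unclassified_label(rank: str) -> str:
    """Sentinel lineage label for a feature unassigned at ``rank``.

    The sentinel keeps the rank prefix (e.g. ``g__unclassified``) so that
    aggregation at that rank groups all unassigned features together.
    """
    return f"{RANK_PREFIXES[rank]}__unclassified"


class CountTable:
    """Non-negative integer abundance matrix, features as rows.

    Parameters
    ----------
    data:
        DataFrame with feature IDs as index and sample IDs as columns.
        Values must be non-negative integers and every sample total must be
        positive.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature IDs: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs: {dups}")
        arr = data.to_numpy()
        if arr.size == 0:
            raise ParseError("empty count table")
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("non-numeric cell in count table")
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ParseError(
                f"non-integer count at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        totals = arr.sum(axis=0)
        if np.any(totals <= 0):
            bad = [data.columns[i] for i in np.flatnonzero(totals <= 0)]
            raise ParseError(f"samples with zero total counts: {bad}")
        self.data = data.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def matrix(self) -> np.ndarray:
        """Counts as an int64 array, features × samples."""
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def filter_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[:, list(sample_ids)])

    def filter_features(self, feature_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.data.loc[list(feature_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({len(self.feature_ids)} features x {len(self.sample_ids)} samples)"

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountTable":
        """Read a features × samples TSV (first column feature IDs)."""
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"cannot parse count table {path}: {exc}") from exc
        if df.columns.size == 0:
            raise ParseError(f"count table {path} has no sample columns")
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                raise ParseError(f"non-numeric cell in sample column {col!r}")
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id")


read_count_table = CountTable.read_tsv


class TaxonomyTable:
    """Per-feature seven-rank lineage (kingdom … species).

    Missing ranks carry the explicit sentinel returned by
    :func:`unclassified_label`, so genus-level aggregation pools all features
    unassigned at genus under one row per parent lineage.
    """

    def __init__(self, data: pd.DataFrame):
        if list(data.columns) != list(RANKS):
            raise ParseError(f"taxonomy columns must be {list(RANKS)}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature rows in taxonomy: {dups}")
        self.data = data.astype(str)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        try:
            return tuple(self.data.loc[feature_id])
        except KeyError as exc:
            raise KeyError(f"unknown feature {feature_id!r} in taxonomy") from exc

    def filter_features(self, feature_ids: Sequence[str]) -> "TaxonomyTable":
        missing = set(feature_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"features missing from taxonomy: {sorted(missing)}")
        return TaxonomyTable(self.data.loc[list(feature_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonomyTable) and self.data.equals(other.data)

    @classmethod
    def from_lineage_strings(cls, lineages: dict[str, str]) -> "TaxonomyTable":
        """Build from ``feature_id -> 'k__X;p__Y;...'`` strings."""
        rows = {}
        for fid, lin in lineages.items():
            parts = [p.strip() for p in str(lin).split(";") if p.strip()]
            row = []
            for i, rank in enumerate(RANKS):
                if i < len(parts) and parts[i] and parts[i] != f"{RANK_PREFIXES[rank]}__":
                    row.append(parts[i])
                else:
                    row.append(unclassified_label(rank))
            rows[fid] = row
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyTable":
        """Read either a two-column (feature, lineage-string) or 8-column TSV."""
        raw = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
        if raw.index.has_duplicates:
            dups = raw.index[raw.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature rows in taxonomy file: {dups}")
        if raw.shape[1] == 1:
            return cls.from_lineage_strings(raw.iloc[:, 0].to_dict())
        if raw.shape[1] == 7:
            df = raw.copy()
            df.columns = list(RANKS)
            for rank in RANKS:
                blank = df[rank].isna() | (df[rank].str.strip() == "")
                df.loc[blank, rank] = unclassified_label(rank)
            return cls(df)
        raise ParseError(
            f"taxonomy file {path} must have 1 lineage column or 7 rank columns, "
            f"found {raw.shape[1]}"
        )

    def write_tsv(self, path: str | Path) -> None:
        out = self.data.apply(";".join, axis=1).rename("lineage")
        out.to_csv(path, sep="\t", index_label="feature_id")


read_taxonomy = TaxonomyTable.read_tsv


class SampleMetadata:
    """Sample table: one group-label column plus arbitrary covariates."""

    def __init__(self, data: pd.DataFrame, group_col: str = "group"):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample IDs in metadata: {dups}")
        if group_col not in data.columns:
            raise ParseError(f"metadata lacks group column {group_col!r}")
        self.data = data.copy()
        self.group_col = group_col

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data[self.group_col].astype(str)

    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=[self.group_col])

    def filter_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)], self.group_col)

    @classmethod
    def read_tsv(cls, path: str | Path, group_col: str = "group") -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        return cls(df, group_col=group_col)

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


read_metadata = SampleMetadata.read_tsv


def read_tree(path: str | Path) -> TreeNode:
    """Read a Newick tree, midpoint-rooting it if it is unrooted.

    A Newick file whose root has more than two children is treated as
    unrooted (the usual convention) and midpoint-rooted, since UniFrac
    requires a rooted tree.
    """
    tree = TreeNode.read(str(path))
    if len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ParseError(f"negative branch length at node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def check_tree_covers(tree: TreeNode, feature_ids: Iterable[str]) -> None:
    """Raise if any feature is not a leaf of ``tree``."""
    leaves = {t.name for t in tree.tips()}
    missing = sorted(set(feature_ids) - leaves)
    if missing:
        raise KeyError(f"tree is missing leaves for features: {missing[:10]}"
                       + (" ..." if len(missing) > 10 else ""))


@dataclass
class AlignedData:
    """Mutually consistent view over counts, metadata, taxonomy and tree."""

    counts: CountTable
    metadata: SampleMetadata
    taxonomy: TaxonomyTable | None = None
    tree: TreeNode | None = None
    dropped_samples: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)


def align(
    counts: CountTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable | None = None,
    tree: TreeNode | None = None,
) -> AlignedData:
    """Restrict all tables to the samples/features they have in common.

    Samples are intersected between counts and metadata (order follows the
    count table).  If a taxonomy is supplied it must cover every retained
    feature; if a tree is supplied it must contain every retained feature as
    a leaf.  Dropped IDs are recorded on the returned view and logged.
    """
    shared = [s for s in counts.sample_ids if s in set(metadata.sample_ids)]
    if not shared:
        raise ValueError("no shared sample IDs between counts and metadata")
    dropped_samples = sorted(
        (set(counts.sample_ids) | set(metadata.sample_ids)) - set(shared)
    )
    if dropped_samples:
        logger.info("align: dropping samples %s", dropped_samples)
    sub_counts = counts.filter_samples(shared)
    sub_meta = metadata.filter_samples(shared)
    sub_tax = taxonomy.filter_features(sub_counts.feature_ids) if taxonomy else None
    if tree is not None:
        check_tree_covers(tree, sub_counts.feature_ids)
    return AlignedData(
        counts=sub_counts,
        metadata=sub_meta,
        taxonomy=sub_tax,
        tree=tree,
        dropped_samples=dropped_samples,
    )
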
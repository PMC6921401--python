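"""Core data types and I/O for OTU tables, sample metadata, trees and distances.

The formats are the plain-text conventions of amplicon workflows: a
tab-delimited feature table whose first header cell is ``#OTU ID`` (features
as rows, samples as columns, optional trailing ``taxonomy`` column), a
tab-delimited metadata table with one row per sample, Newick trees whose tips
are feature IDs, and square tab-delimited distance matrices.

Sample and feature IDs are treated as opaque, case-sensitive keys; enumerated
labels (``role``, ``environment``) are case-folded on read.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Source environments sampled on the sow and in the birth environment.
SOURCE_ENVIRONMENTS = (
    "milk",
    "vagina",
    "areolar_skin",
    "sow_feces",
    "farrowing_crate",
    "incubator",
)

#: Intestinal segments sampled on the piglet (the sink communities).
SINK_SEGMENTS = ("jejunum", "ileum", "cecum", "colon")

SMALL_INTESTINE = ("jejunum", "ileum")
LARGE_INTESTINE = ("cecum", "colon")

DEFAULT_VOCABULARY = SOURCE_ENVIRONMENTS + SINK_SEGMENTS

REQUIRED_METADATA_COLUMNS = (
    "sample_id",
    "role",
    "environment",
    "host_id",
    "dyad_id",
    "day",
)


class FeatureTable:
    """Integer counts of features (OTUs) per sample.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, features as rows, samples as
        columns. Index holds feature IDs, columns hold sample IDs.
    taxonomy
        Optional map from feature ID to a lineage string.
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: dict[str, str] | None = None):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature IDs: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ParseError("counts must be numeric")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ParseError(
                f"negative count at feature {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ParseError(
                f"non-integer count at feature {counts.index[i]!r}, "
                f"sample {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.taxonomy = dict(taxonomy) if taxonomy else None
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.feature_ids)
            if unknown:
                raise ValidationError(f"taxonomy refers to unknown features: {sorted(unknown)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[sample_id].to_numpy()

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total count: {empty}")
        return self.counts / totals

    def filter_samples(self, sample_ids) -> "FeatureTable":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return FeatureTable(self.counts[keep], self.taxonomy)

    def filter_features(self, feature_ids) -> "FeatureTable":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        tax = {f: t for f, t in (self.taxonomy or {}).items() if f in set(keep)} or None
        return FeatureTable(self.counts.loc[keep], tax)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FeatureTable)
            and self.counts.equals(other.counts)
            and self.taxonomy == other.taxonomy
        )


class SampleMetadata:
    """Per-sample study metadata: role, environment, host, dyad, day.

    ``role`` is ``source`` (maternal body site or birth environment) or
    ``sink`` (piglet intestinal segment). ``dyad_id`` identifies the sow; a
    sink's ``dyad_id`` links the piglet to its dam and is mandatory for sinks.
    """

    def __init__(self, frame: pd.DataFrame, vocabulary=DEFAULT_VOCABULARY):
        frame = frame.copy()
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        if frame["sample_id"].duplicated().any():
            dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample IDs in metadata: {dups}")
        for col in ("role", "environment"):
            frame[col] = frame[col].astype(str).str.strip().str.lower()
        bad_roles = set(frame["role"]) - {"source", "sink"}
        if bad_roles:
            raise ValidationError(f"unknown roles {sorted(bad_roles)}; allowed: source, sink")
        vocab = {v.lower() for v in vocabulary}
        bad_env = set(frame["environment"]) - vocab
        if bad_env:
            raise ValidationError(
                f"unknown environment labels {sorted(bad_env)}; allowed: {sorted(vocab)}"
            )
        dyad = frame["dyad_id"].astype("string")
        empty_dyad = dyad.isna() | (dyad.str.strip() == "")
        sinks_no_dyad = frame.loc[(frame["role"] == "sink") & empty_dyad, "sample_id"]
        if len(sinks_no_dyad):
            raise ValidationError(f"sink samples lacking dyad_id: {sinks_no_dyad.tolist()}")
        frame["dyad_id"] = dyad.where(~empty_dyad, pd.NA)
        try:
            frame["day"] = frame["day"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-integer day value: {exc}") from None
        self.frame = frame.set_index("sample_id", drop=False)
        self.vocabulary = tuple(sorted(vocab))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, sample_ids) -> "SampleMetadata":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleMetadata(self.frame.loc[keep].reset_index(drop=True), self.vocabulary)

    def sources(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "source"]

    def sinks(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "sink"]


@dataclass
class PhyloTree:
    """A rooted tree with non-negative branch lengths whose tips are feature IDs."""

    tree: skbio.TreeNode

    def __post_init__(self):
        names = [t.name for t in self.tree.tips()]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate tip names in tree")
        n_missing = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError(f"negative branch length at node {node.name!r}")
        if n_missing:
            logger.warning("%d branches lacked lengths; set to 0", n_missing)

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue()


@dataclass
class AnalysisBundle:
    """A mutually consistent (table, metadata, tree) triple plus a drop report."""

    table: FeatureTable
    metadata: SampleMetadata
    tree: PhyloTree | None
    dropped_samples: list[str] = field(default_factory=list)
    dropped_features: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(path, samples_as_rows: bool = False) -> FeatureTable:
    """Read a tab-delimited feature table (header cell ``#OTU ID``).

    A trailing column named ``taxonomy`` (case-insensitive) is split off into
    the taxonomy map. ``samples_as_rows`` transposes after reading for
    exports with the opposite orientation.
    """
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        frame = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    except OSError as exc:
        raise ParseError(f"cannot read feature table {path}: {exc}") from None
    if len(header) < 2:
        raise ParseError(f"feature table {path} has fewer than 2 columns")
    if len(header) != len(set(header)):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"duplicate sample IDs in header: {dups}")
    frame = frame.set_index(frame.columns[0])
    taxonomy = None
    if frame.columns[-1].lower() == "taxonomy":
        taxonomy = frame.iloc[:, -1].to_dict()
        frame = frame.iloc[:, :-1]
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric count in {path}: {exc}") from None
    numeric.index.name = None
    if samples_as_rows:
        numeric = numeric.T
    return FeatureTable(numeric, taxonomy)


def write_feature_table(table: FeatureTable, path) -> None:
    out = table.counts.copy()
    out.index.name = "#OTU ID"
    if table.taxonomy is not None:
        out["taxonomy"] = [table.taxonomy.get(f, "") for f in table.feature_ids]
    out.to_csv(path, sep="\t")


def read_metadata(path, vocabulary=DEFAULT_VOCABULARY) -> SampleMetadata:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot read metadata {path}: {exc}") from None
    return SampleMetadata(frame, vocabulary)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


def read_newick(path) -> PhyloTree:
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from None
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(frame.to_numpy(), ids=[str(i) for i in frame.index])


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def align_table_metadata_tree(
    table: FeatureTable,
    metadata: SampleMetadata,
    tree: PhyloTree | None = None,
) -> AnalysisBundle:
    """Restrict table/metadata to shared samples and table features to tree tips.

    Dropped IDs are logged and returned in the bundle so callers can surface
    them; an empty sample intersection is an error.
    """
    shared = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    if not shared:
        raise ValidationError("no samples shared between table and metadata")
    dropped_samples = sorted(
        (set(table.sample_ids) | set(metadata.sample_ids)) - set(shared)
    )
    if dropped_samples:
        logger.warning("dropping %d unmatched samples: %s", len(dropped_samples), dropped_samples)
    table = table.filter_samples(shared)
    metadata = metadata.subset(shared)

    dropped_features: list[str] = []
    if tree is not None:
        tips = set(tree.tip_names)
        missing = [f for f in table.feature_ids if f not in tips]
        if missing:
            if len(missing) == len(table.feature_ids):
                raise ValidationError(
                    f"no table features present as tree tips (e.g. {missing[:3]})"
                )
            logger.warning("dropping %d features absent from tree: %s", len(missing), missing)
            dropped_features = missing
            table = table.filter_features(set(table.feature_ids) - set(missing))
    return AnalysisBundle(table, metadata, tree, dropped_samples, dropped_features)
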
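"""Readers, writers and cross-validation for the formats the pipeline touches.

The central objects are deliberately thin:

* :class:`CommunityTable` -- an integer count matrix (samples x ASVs) with
  ordered identifiers, the unit every downstream metric consumes.
* phylogenies -- :class:`skbio.TreeNode`, read from Newick; only cophenetic
  (patristic) distances are used downstream, so rooting is a convention,
  not a modelling choice.
* sample metadata and per-site environmental tables -- plain
  :class:`pandas.DataFrame` objects validated on read.

All tabular formats are UTF-8 TSV with a header row; writers emit a
deterministic row/column order so that outputs are diffable and round-trip
exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("phyloturn")

__all__ = [
    "FormatError",
    "ValidationError",
    "CommunityTable",
    "read_community_table",
    "write_community_table",
    "read_biom_json",
    "read_tree",
    "write_tree",
    "read_metadata",
    "write_metadata",
    "read_env_table",
    "write_env_table",
    "align_inputs",
]


class FormatError(ValueError):
    """A file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant (duplicates, negatives, ...)."""


# ---------------------------------------------------------------------------
# community table
# ---------------------------------------------------------------------------


@dataclass
class CommunityTable:
    """Read counts for ``len(sample_ids)`` samples over ``len(asv_ids)`` ASVs.

    ``counts`` is a non-negative integer array of shape
    ``(n_samples, n_asvs)``; rows follow ``sample_ids`` and columns follow
    ``asv_ids``.  Identifiers must be unique within their axis.
    """

    sample_ids: list[str]
    asv_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            s, a = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[s]!r}, ASV {self.asv_ids[a]!r}"
            )
        for label, ids in (("sample", self.sample_ids), ("ASV", self.asv_ids)):
            if len(set(ids)) != len(ids):
                dup = next(x for x in ids if ids.count(x) > 1)
                raise ValidationError(f"duplicate {label} identifier {dup!r}")
        self.counts = counts

    # -- conveniences -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalised counts; rows with zero total raise."""
        totals = self.sample_totals()
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts / totals[:, None]

    def select_samples(self, sample_ids: list[str]) -> "CommunityTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CommunityTable(list(sample_ids), list(self.asv_ids), self.counts[idx])

    def select_asvs(self, asv_ids: list[str]) -> "CommunityTable":
        idx = [self.asv_ids.index(a) for a in asv_ids]
        return CommunityTable(list(self.sample_ids), list(asv_ids), self.counts[:, idx])

    def to_dataframe(self, orientation: str = "asvs_as_rows") -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)
        if orientation == "asvs_as_rows":
            return df.T
        if orientation == "samples_as_rows":
            return df
        raise ValueError(f"unknown orientation {orientation!r}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CommunityTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_community_table(path, orientation: str = "asvs_as_rows") -> CommunityTable:
    """Read a TSV count table into canonical samples x ASVs orientation.

    ``orientation`` declares what the *file's rows* are: ``"asvs_as_rows"``
    (the common amplicon-table dialect, the default) or
    ``"samples_as_rows"``.  Non-integer or negative cells raise a
    :class:`FormatError` naming the offending cell.
    """
    if orientation not in ("asvs_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty table")
    values = np.empty(df.shape, dtype=np.int64)
    for i, row_id in enumerate(df.index):
        for j, col_id in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                v = int(str(cell))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {cell!r} at row {row_id!r}, column {col_id!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at row {row_id!r}, column {col_id!r}"
                )
            values[i, j] = v
    if orientation == "asvs_as_rows":
        asv_ids, sample_ids, values = list(df.index), list(df.columns), values.T
    else:
        sample_ids, asv_ids = list(df.index), list(df.columns)
    try:
        return CommunityTable(sample_ids, asv_ids, values)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_community_table(table: CommunityTable, path, orientation: str = "asvs_as_rows") -> None:
    df = table.to_dataframe(orientation)
    df.index.name = "#ASV_ID" if orientation == "asvs_as_rows" else "#Sample_ID"
    df.to_csv(path, sep="\t")


def read_biom_json(path) -> CommunityTable:
    """Read a BIOM 1.0 (JSON) table; rows are observations (ASVs)."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        n_r, n_c = doc["shape"]
        mat_type = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from None
    if (n_r, n_c) != (len(asv_ids), len(sample_ids)):
        raise FormatError(f"{path}: shape field disagrees with rows/columns")
    counts = np.zeros((n_r, n_c))
    if mat_type == "sparse":
        for r, c, v in data:
            counts[int(r), int(c)] = v
    elif mat_type == "dense":
        counts[:] = np.asarray(data)
    else:
        raise FormatError(f"{path}: unknown matrix_type {mat_type!r}")
    return CommunityTable(sample_ids, asv_ids, counts.T)


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


def read_tree(path) -> TreeNode:
    """Read a Newick tree with branch lengths; returns a rooted tree.

    Unrooted input (root with more than two children) is midpoint-rooted:
    patristic distances, the only tree quantity used downstream, are
    rooting-invariant, so any deterministic convention suffices.  Missing
    branch lengths or duplicate tip labels raise.
    """
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"{path}: could not parse Newick ({exc})") from None
    return _validate_tree(tree, source=str(path))


def _validate_tree(tree: TreeNode, source: str = "tree") -> TreeNode:
    tips = [t.name for t in tree.tips()]
    if len(tips) < 2:
        raise ValidationError(f"{source}: fewer than 2 tips")
    if any(t is None for t in tips):
        raise ValidationError(f"{source}: unnamed tip")
    if len(set(tips)) != len(tips):
        dup = next(x for x in tips if tips.count(x) > 1)
        raise ValidationError(f"{source}: duplicate tip label {dup!r}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(f"{source}: missing branch length on an edge")
        if node.length < 0:
            raise ValidationError(f"{source}: negative branch length {node.length}")
    if len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# metadata / environment
# ---------------------------------------------------------------------------

METADATA_KEY_COLUMNS = ("site", "substrate", "time", "replicate")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata keyed by ``sample_id``.

    Requires a ``sample_id`` column plus the design keys ``site``,
    ``substrate``, ``time`` and ``replicate``; an optional pair of planar
    ``x``/``y`` coordinate columns is passed through for distance-decay
    analyses.  The joint key (site, substrate, time, replicate) must be
    unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df, source=str(path))


def validate_metadata(df: pd.DataFrame, source: str = "metadata") -> pd.DataFrame:
    if "sample_id" not in df.columns:
        raise FormatError(f"{source}: missing 'sample_id' column")
    missing = [c for c in METADATA_KEY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{source}: duplicate sample_id {dup!r}")
    key = df[list(METADATA_KEY_COLUMNS)].astype(str).agg("|".join, axis=1)
    if key.duplicated().any():
        raise ValidationError(
            f"{source}: (site, substrate, time, replicate) not jointly unique"
        )
    df = df.set_index("sample_id", drop=False)
    for coord in ("x", "y"):
        if coord in df.columns:
            df[coord] = df[coord].astype(float)
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_env_table(path) -> pd.DataFrame:
    """Read per-site environmental variables (rows = sites, numeric columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_env_table(df, source=str(path))


def validate_env_table(df: pd.DataFrame, source: str = "env table") -> pd.DataFrame:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"{source}: duplicate site identifier {dup!r}")
    df = df.astype(float)
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValidationError(f"{source}: missing values in variable {col!r}")
    df.index = df.index.astype(str)
    return df


def write_env_table(env: pd.DataFrame, path) -> None:
    out = env.copy()
    out.index.name = "site"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_inputs(
    table: CommunityTable,
    tree: TreeNode | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[CommunityTable, TreeNode | None, pd.DataFrame | None]:
    """Intersect the ASV and sample namespaces of table, tree and metadata.

    ASVs are restricted to ``table ∩ tree tips`` (tree sheared accordingly)
    and samples to ``table ∩ metadata``; dropped counts are logged.  An
    empty intersection on either axis raises.  The operation is idempotent.
    """
    asv_ids = list(table.asv_ids)
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        kept_asvs = [a for a in asv_ids if a in tip_names]
        if not kept_asvs:
            raise ValidationError("no ASVs shared between table and tree")
        dropped_table = len(asv_ids) - len(kept_asvs)
        dropped_tips = len(tip_names) - len(kept_asvs)
        if dropped_table or dropped_tips:
            logger.info(
                "align_inputs: dropped %d table ASVs absent from tree, "
                "%d tree tips absent from table",
                dropped_table,
                dropped_tips,
            )
        if dropped_table:
            table = table.select_asvs(kept_asvs)
        if dropped_tips:
            tree = tree.shear(kept_asvs)
            tree.prune()
    if meta is not None:
        meta_samples = set(meta["sample_id"].astype(str))
        kept_samples = [s for s in table.sample_ids if s in meta_samples]
        if not kept_samples:
            raise ValidationError("no samples shared between table and metadata")
        dropped_samples = table.n_samples - len(kept_samples)
        dropped_meta = len(meta_samples) - len(kept_samples)
        if dropped_samples or dropped_meta:
            logger.info(
                "align_inputs: dropped %d table samples absent from metadata, "
                "%d metadata rows absent from table",
                dropped_samples,
                dropped_meta,
            )
        if dropped_samples:
            table = table.select_samples(kept_samples)
        if dropped_meta:
            meta = meta[meta["sample_id"].isin(kept_samples)]
    return table, tree, meta
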
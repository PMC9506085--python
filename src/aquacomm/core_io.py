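"""Input readers, validation and table-level preprocessing.

The working representation is deliberately light: an OTU table is a pandas
DataFrame of non-negative integer counts with taxa as rows and samples as
columns; the phylogeny is a rooted ``skbio.TreeNode`` whose tips cover the
table's taxa; metadata and environmental factors are per-sample DataFrames
keyed by ``sample_id``.

Preprocessing implements the two table-level steps common in amplicon
surveys: removal of ultra-rare taxa (total abundance below a fractional
threshold of the grand total) and rarefaction — subsampling every sample
without replacement to a common depth so that library size does not drive
diversity estimates.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from aquacomm._exceptions import AlignmentError, TableParseError

ENV_FACTORS = (
    "temperature",
    "pH",
    "DO",
    "ammonia",
    "nitrite",
    "nitrate",
    "TN",
    "TP",
)

METADATA_COLUMNS = ("group", "stage", "pond")


def load_otu_table(path, transpose: bool = False) -> pd.DataFrame:
    """Read a TSV OTU count table (first column taxon ids, header sample ids).

    Set ``transpose=True`` for tables stored samples-by-taxa.
    """
    try:
        table = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"cannot parse OTU table {path}: {exc}") from exc
    if transpose:
        table = table.T
    _check_numeric(table, what="OTU table")
    if (table.values < 0).any():
        raise TableParseError("OTU table contains negative counts")
    validate_otu_table(table)
    return table.astype(np.int64, errors="ignore")


def load_tree(path) -> TreeNode:
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise TableParseError(f"malformed newick in {path}: {exc}") from exc
    return tree


def load_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise TableParseError(f"metadata missing columns: {missing}")
    return md


def load_env(path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", index_col="sample_id", comment="#")
    _check_numeric(env, what="environment table")
    return env


def _check_numeric(df: pd.DataFrame, what: str) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise TableParseError(
                f"{what}: non-numeric cell at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna().argmax()]
            raise TableParseError(f"{what}: missing value at row {row!r}, column {col!r}")


def validate_otu_table(table: pd.DataFrame) -> None:
    if table.index.duplicated().any():
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise TableParseError(f"duplicate taxon ids: {dupes}")
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise TableParseError(f"duplicate sample ids: {dupes}")
    if table.shape[0] < 1 or table.shape[1] < 2:
        raise TableParseError("OTU table needs at least 1 taxon and 2 samples")


def align_inputs(
    table: pd.DataFrame,
    tree: TreeNode,
    metadata: pd.DataFrame,
    env: pd.DataFrame,
) -> None:
    """Cross-validate identifiers; raise AlignmentError naming offenders."""
    tips = {t.name for t in tree.tips()}
    missing_taxa = [t for t in table.index if t not in tips]
    if missing_taxa:
        raise AlignmentError(f"taxa absent from the tree: {missing_taxa[:10]}")
    samples = set(table.columns)
    for name, other in (("metadata", set(metadata.index)), ("environment", set(env.index))):
        if other != samples:
            off = sorted(samples.symmetric_difference(other))
            raise AlignmentError(f"sample ids of OTU table and {name} differ: {off[:10]}")


def load_inputs(table_path, tree_path, metadata_path, env_path):
    """Load and mutually validate the four study inputs."""
    table = load_otu_table(table_path)
    tree = load_tree(tree_path)
    metadata = load_metadata(metadata_path)
    env = load_env(env_path)
    align_inputs(table, tree, metadata, env)
    return table, tree, metadata, env


def filter_rare(table: pd.DataFrame, threshold_fraction: float = 1e-5) -> pd.DataFrame:
    """Drop taxa whose total count is strictly below a fraction of all reads.

    The default 1e-5 (0.001 %) is the conventional "singleton" cutoff for
    amplicon surveys.  A taxon sitting exactly at the threshold is retained
    (strict ``<``).  Idempotent: filtering a filtered table is a no-op.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError(f"threshold_fraction must be in [0, 1), got {threshold_fraction}")
    grand_total = table.values.sum()
    if grand_total == 0:
        return table.copy()
    # strict "<" removal: ties at the threshold survive
    keep = ~(table.sum(axis=1) < threshold_fraction * grand_total)
    return table.loc[keep].copy()


def rarefy(
    table: pd.DataFrame,
    depth: int | None = None,
    seed: int | None = None,
    drop_empty: bool = False,
) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth`` defaults to the smallest column sum.  Rows are never dropped
    silently; pass ``drop_empty=True`` to remove taxa that end up all-zero.
    """
    sums = table.sum(axis=0)
    if depth is None:
        depth = int(sums.min())
    for sample, total in sums.items():
        if depth > total:
            raise ValueError(
                f"rarefaction depth {depth} exceeds total {total} of sample {sample!r}"
            )
    rng = np.random.default_rng(seed)
    counts = table.to_numpy(dtype=np.int64)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    result = pd.DataFrame(out, index=table.index, columns=table.columns)
    if drop_empty:
        result = result.loc[result.sum(axis=1) > 0]
    return result


def preprocess(
    table: pd.DataFrame,
    threshold_fraction: float = 1e-5,
    depth: int | None = None,
    seed: int | None = None,
    rarefy_first: bool = False,
) -> pd.DataFrame:
    """Singleton filter then rarefaction (order switchable)."""
    if rarefy_first:
        return filter_rare(rarefy(table, depth=depth, seed=seed), threshold_fraction)
    return rarefy(filter_rare(table, threshold_fraction), depth=depth, seed=seed)


def write_otu_table(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.to_csv(fh, sep="\t", index_label="taxon_id")


def write_table(df: pd.DataFrame, path, index_label="sample_id", header_comment=None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalized table (each sample sums to 1)."""
    sums = table.sum(axis=0)
    if (sums == 0).any():
        zero = sums.index[sums == 0].tolist()
        raise ValueError(f"all-zero samples: {zero}")
    return table / sums
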
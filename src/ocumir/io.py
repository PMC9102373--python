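"""Readers and writers for the tabular formats the pipeline touches.

Canonical dialect is tab-delimited text; comma-delimited input is accepted on
read via sniffing.  CT tables are samples-as-rows by default; the orientation
is never guessed — callers flip it explicitly with ``orientation``.

Clustering results are exported in the Cluster 3.0 / Java TreeView de-facto
standard: a CDT file whose row order follows the dendrogram leaf order and a
GTR (or ATR) file listing the n-1 merge nodes with correlation heights.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusteringResult

__all__ = [
    "ParseError",
    "UNDETECTED_TOKEN",
    "read_ct_table",
    "write_ct_table",
    "read_annotation",
    "write_annotation",
    "write_de_table",
    "read_marker_table",
    "write_marker_table",
    "write_cdt_gtr",
    "read_gtr",
]

#: Instrument token for wells that never crossed the fluorescence threshold.
UNDETECTED_TOKEN = "Undetermined"


class ParseError(ValueError):
    """Malformed input table; the message names the offending row/column."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def read_ct_table(path, orientation: str = "samples_as_rows") -> pd.DataFrame:
    """Read a CT table into a samples x assays DataFrame with NaN for undetected.

    The first column holds row ids.  Cells must be numeric, empty, or the
    literal token ``Undetermined``; anything else raises :class:`ParseError`
    naming the row and column.  Duplicate ids on either axis are rejected.
    """
    if orientation not in ("samples_as_rows", "assays_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_delimiter(path)
    # Check header duplicates on the raw line: pandas would silently mangle
    # repeated column names before we could see them.
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = {c for c in header if header.count(c) > 1}
    if dup_cols:
        raise ParseError(f"duplicate column id(s) in {path.name}: "
                         + ", ".join(sorted(dup_cols)))
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)

    for axis, ids in (("row", raw.index), ("column", raw.columns)):
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ParseError(f"duplicate {axis} id(s) in {path.name}: "
                             + ", ".join(map(str, dup.unique())))

    values = np.empty(raw.shape)
    for j, col in enumerate(raw.columns):
        for i, row in enumerate(raw.index):
            cell = raw.iat[i, j].strip()
            if cell == "" or cell == UNDETECTED_TOKEN:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric cell {cell!r} at row {row!r}, "
                    f"column {col!r}"
                ) from None

    ct = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if orientation == "assays_as_rows":
        ct = ct.T
    ct.index.name = "sample_id"
    return ct


def write_ct_table(ct: pd.DataFrame, path) -> None:
    """Write a CT table (samples as rows); NaN serializes as ``Undetermined``."""
    out = ct.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=UNDETECTED_TOKEN, float_format="%.6g")


def read_annotation(path) -> pd.DataFrame:
    """Read a sample annotation table (``sample_id``, ``group``, outcome flags)."""
    path = Path(path)
    annot = pd.read_csv(path, sep=_sniff_delimiter(path))
    for col in ("sample_id", "group"):
        if col not in annot.columns:
            raise ParseError(f"{path.name}: missing required column {col!r}")
    if annot["sample_id"].duplicated().any():
        dup = annot.loc[annot["sample_id"].duplicated(), "sample_id"]
        raise ParseError(f"{path.name}: duplicate sample id(s): "
                         + ", ".join(map(str, dup.unique())))
    for flag in ("metastasis", "recurrence"):
        if flag in annot.columns:
            annot[flag] = annot[flag].astype(bool)
    return annot


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def check_annotation_covers(ct: pd.DataFrame, annot: pd.DataFrame) -> None:
    """Every sample in the CT matrix must have an annotation row."""
    missing = set(ct.index) - set(annot["sample_id"])
    if missing:
        raise ValueError("samples without annotation: "
                         + ", ".join(sorted(map(str, missing))))


def write_de_table(table: pd.DataFrame, path) -> None:
    """Write a differential-expression result table with significance stars.

    Star convention: * for p <= 0.05, ** for p <= 0.01, *** for p <= 0.001.
    """
    from .diffexpr import significance_stars

    out = table.copy()
    out["significance"] = [significance_stars(p) for p in out["p_value"]]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_marker_table(path) -> pd.DataFrame:
    """Read a samples x markers absolute-expression table (positive values)."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0).astype(float)
    if (table.dropna() <= 0).any().any():
        raise ParseError(f"{path.name}: absolute expression must be > 0")
    table.index.name = "sample_id"
    return table


def write_marker_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# Cluster 3.0 / TreeView export
# ---------------------------------------------------------------------------

def _leaf_gid(result: "ClusteringResult", axis_prefix: str) -> dict[str, str]:
    # TreeView leaf ids are GENE{i}X / ARRY{i}X keyed by input order.
    return {item: f"{axis_prefix}{i}X" for i, item in enumerate(result.items)}


def write_cdt_gtr(result: "ClusteringResult", expr: pd.DataFrame, path_stem,
                  tree_axis: str = "rows") -> tuple[Path, Path]:
    """Export a clustering over ``expr`` rows (or columns) as CDT + GTR/ATR.

    The CDT row (or column) order follows the dendrogram leaf order; the tree
    file lists the n-1 merges bottom-up with heights converted to correlations
    (1 - distance), the scale TreeView displays.  Missing expression values
    serialize as empty cells.
    """
    if tree_axis not in ("rows", "columns"):
        raise ValueError(f"tree_axis must be 'rows' or 'columns', got {tree_axis!r}")
    stem = Path(path_stem)
    matrix = expr if tree_axis == "rows" else expr.T
    if set(result.items) != set(matrix.index):
        raise ValueError("clustering leaves do not match expression ids")

    prefix = "GENE" if tree_axis == "rows" else "ARRY"
    gid = _leaf_gid(result, prefix)
    # Merge children are item ids (leaves) or "NODE{j}" labels from earlier
    # merges; both map onto TreeView's GENE/ARRY/NODE...X naming.
    node_name: dict[str, str] = dict(gid)

    tree_path = stem.with_suffix(".gtr" if tree_axis == "rows" else ".atr")
    with open(tree_path, "w") as fh:
        for k, (a, b, height) in enumerate(result.merges, start=1):
            name = f"NODE{k}X"
            fh.write(f"{name}\t{node_name[a]}\t{node_name[b]}\t{1.0 - height:.6f}\n")
            node_name[f"NODE{k}"] = name

    cdt_path = stem.with_suffix(".cdt")
    ordered = matrix.loc[result.leaf_order]
    with open(cdt_path, "w") as fh:
        cols = "\t".join(map(str, ordered.columns))
        fh.write(f"GID\t{prefix}\tNAME\tGWEIGHT\t{cols}\n")
        fh.write("EWEIGHT\t\t\t" + "\t1" * ordered.shape[1] + "\n")
        for item in result.leaf_order:
            row = ordered.loc[item]
            cells = "\t".join("" if pd.isna(v) else f"{v:.6g}" for v in row)
            fh.write(f"{gid[item]}\t{item}\t{item}\t1\t{cells}\n")
    return cdt_path, tree_path


def read_gtr(path) -> list[tuple[str, str, str, float]]:
    """Parse a GTR/ATR file into (node, child_a, child_b, correlation) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            node, a, b, corr = line.rstrip("\n").split("\t")
            rows.append((node, a, b, float(corr)))
    return rows
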
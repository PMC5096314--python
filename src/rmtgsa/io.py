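"""File-based input and output.

Data matrices travel as tab-delimited text with a header row of gene
identifiers and a first column of sample identifiers; gene set collections
use the MSigDB GMT format (one set per line: name, description, member
genes).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DataMatrix, GeneSetCollection

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_pvalue_table",
]

#: default GMT size filter: retain sets with 5..200 members
GMT_MIN_SIZE = 5
GMT_MAX_SIZE = 200


def read_matrix(path: "str | Path", genes_in_rows: bool = False) -> DataMatrix:
    """Read a delimited data matrix; validates shape and missingness.

    With ``genes_in_rows`` the file is transposed on load (genes as rows,
    samples as columns).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if genes_in_rows:
        frame = frame.T
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no gene columns found")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at sample "
            f"{frame.index[i]!r}, gene {frame.columns[j]!r}"
        )
    return DataMatrix.from_frame(numeric)


def write_matrix(matrix: DataMatrix, path: "str | Path") -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_gmt(
    path: "str | Path",
    gene_ids: list[str] | None = None,
    min_size: int = GMT_MIN_SIZE,
    max_size: int = GMT_MAX_SIZE,
) -> GeneSetCollection:
    """Read a GMT gene set file into a membership matrix.

    If *gene_ids* (the companion data matrix's columns) is given, sets are
    restricted to those genes; otherwise the gene universe is the union of
    all genes named in the file, in order of first appearance.  Sets whose
    post-restriction size falls outside [min_size, max_size] are dropped.
    """
    names: list[str] = []
    raw: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need set name, description "
                    "and at least one gene"
                )
            name, genes = fields[0], [f for f in fields[2:] if f]
            if name in raw:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            names.append(name)
            raw[name] = genes

    if gene_ids is None:
        seen: dict[str, None] = {}
        for name in names:
            for gene in raw[name]:
                seen.setdefault(gene, None)
        gene_ids = list(seen)
    index = {gene: j for j, gene in enumerate(gene_ids)}

    kept: dict[str, np.ndarray] = {}
    for name in names:
        idx = sorted({index[g] for g in raw[name] if g in index})
        if min_size <= len(idx) <= max_size:
            kept[name] = np.asarray(idx, dtype=int)
    if not kept:
        raise ValueError(
            f"{path}: no gene sets with between {min_size} and {max_size} "
            "members after restriction to the data matrix genes"
        )
    collection = GeneSetCollection.from_index_sets(kept, p=len(gene_ids))
    collection.gene_ids = gene_ids  # type: ignore[attr-defined]
    return collection


def write_gmt(
    collection: GeneSetCollection, gene_ids: list[str], path: "str | Path"
) -> None:
    with open(path, "w") as fh:
        for set_id in collection.set_ids:
            genes = [gene_ids[j] for j in collection.indices(set_id)]
            fh.write("\t".join([set_id, "na", *genes]) + "\n")


def read_pvalue_table(path: "str | Path") -> pd.Series:
    """Two-column (set_id, p-value) tab-delimited file as a Series."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["set_id", "pvalue"])
    if frame["set_id"].duplicated().any():
        dupes = frame.loc[frame["set_id"].duplicated(), "set_id"].tolist()
        raise ValueError(f"{path}: duplicate set ids {dupes}")
    vals = pd.to_numeric(frame["pvalue"], errors="coerce")
    if vals.isna().any():
        bad = frame.loc[vals.isna(), "set_id"].iloc[0]
        raise ValueError(f"{path}: non-numeric p-value for set {bad!r}")
    return pd.Series(vals.to_numpy(), index=frame["set_id"].astype(str).tolist())
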
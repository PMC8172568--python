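"""Readers and writers for the standard formats the pipeline touches.

Count matrices travel as 10x-style MatrixMarket triplets (matrix.mtx +
genes.tsv + barcodes.tsv, genes in rows, cells in columns, 1-based indices
in the file, 0-based in memory). Gene-set collections travel as GMT. Typed
result tables travel as TSV with an explicit schema.
"""

from __future__ import annotations

import io as _stdio
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SchemaError",
    "CountMatrix",
    "GeneSetCollection",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]


class FormatError(ValueError):
    """Malformed input file (bad header, out-of-range index, bad value)."""


class SchemaError(ValueError):
    """Table does not conform to the declared column schema."""


@dataclass
class CountMatrix:
    """Genes x cells UMI count matrix with row/column labels.

    ``X`` is a scipy CSR matrix of non-negative integers; ``gene_ids`` and
    ``barcodes`` label rows and columns respectively and must be unique.
    """

    X: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.X.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError(
                f"label/matrix shape mismatch: matrix {self.X.shape}, "
                f"{len(self.gene_ids)} genes, {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("gene IDs are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("cell barcodes are not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative count entries")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a new CountMatrix restricted to masked genes/cells."""
        X = self.X
        genes, cells = self.gene_ids, self.barcodes
        if gene_mask is not None:
            gene_mask = np.asarray(gene_mask)
            X = X[gene_mask, :]
            genes = genes[gene_mask]
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask)
            X = X[:, cell_mask]
            cells = cells[cell_mask]
        return CountMatrix(X=sp.csr_matrix(X), gene_ids=genes, barcodes=cells)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict = field(default_factory=dict)  # name -> (description, [genes])

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self):
        return list(self.sets)

    def genes(self, name: str):
        return list(self.sets[name][1])

    def description(self, name: str) -> str:
        return self.sets[name][0]


def _open_maybe_gzip(path, mode="rt"):
    import gzip

    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_mtx_bundle(matrix_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style MatrixMarket triplet into a :class:`CountMatrix`.

    The matrix must be in coordinate format with an integer field (a real
    field is accepted when every stored value is integral). Entries absent
    from the file are zero. Out-of-range indices, negative values and
    label/dimension mismatches raise :class:`FormatError`.
    """
    with _open_maybe_gzip(matrix_path) as fh:
        text = fh.read()
    header = text.splitlines()[0] if text else ""
    if not header.startswith("%%MatrixMarket matrix coordinate"):
        raise FormatError(f"not a coordinate MatrixMarket file: {header!r}")
    try:
        M = scipy.io.mmread(_stdio.StringIO(text))
    except Exception as exc:  # scipy raises ValueError on bad indices
        raise FormatError(f"malformed MatrixMarket file: {exc}") from exc
    M = sp.coo_matrix(M)
    if M.nnz:
        if M.data.min() < 0:
            raise FormatError("negative entries in count matrix")
        if not np.allclose(M.data, np.round(M.data)):
            raise FormatError("non-integral entries in count matrix")
    genes = _read_label_column(genes_path)
    barcodes = _read_label_column(barcodes_path)
    if M.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix shape {M.shape} does not match {len(genes)} genes "
            f"x {len(barcodes)} barcodes"
        )
    X = sp.csr_matrix((M.data.astype(np.int64), (M.row, M.col)), shape=M.shape)
    X.sum_duplicates()
    return CountMatrix(X=X, gene_ids=genes, barcodes=barcodes)


def _read_label_column(path) -> np.ndarray:
    with _open_maybe_gzip(path) as fh:
        labels = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return np.asarray(labels, dtype=object)


def write_mtx_bundle(matrix: CountMatrix, out_dir, prefix="") -> dict:
    """Write a CountMatrix as matrix.mtx / genes.tsv / barcodes.tsv.

    Entries are emitted in deterministic row-major order. Returns the paths
    written, keyed by role.
    """
    os.makedirs(out_dir, exist_ok=True)
    mtx_path = os.path.join(out_dir, prefix + "matrix.mtx")
    genes_path = os.path.join(out_dir, prefix + "genes.tsv")
    barcodes_path = os.path.join(out_dir, prefix + "barcodes.tsv")
    X = sp.coo_matrix(matrix.X)  # from CSR -> row-major ordered triplets
    with open(mtx_path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{X.shape[0]} {X.shape[1]} {X.nnz}\n")
        for i, j, v in zip(X.row, X.col, X.data):
            fh.write(f"{i + 1} {j + 1} {int(v)}\n")
    with open(genes_path, "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(barcodes_path, "w") as fh:
        for b in matrix.barcodes:
            fh.write(f"{b}\n")
    return {"matrix": mtx_path, "genes": genes_path, "barcodes": barcodes_path}


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB gene TAB gene...

    Duplicate genes within a set are dropped (order preserved) with a
    warning; a duplicated set name or a line with fewer than three fields is
    a :class:`FormatError`.
    """
    sets: dict = {}
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen = set()
            deduped = []
            for g in genes:
                if g in seen:
                    continue
                seen.add(g)
                deduped.append(g)
            if len(deduped) < len(genes):
                logger.warning(
                    "gene set %r: %d duplicate gene(s) dropped",
                    name,
                    len(genes) - len(deduped),
                )
            if not deduped:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


# float columns round-trip exactly at 17 significant digits
_FLOAT_FMT = "%.17g"


def write_table(df: pd.DataFrame, path, schema: dict | None = None) -> None:
    """Write a typed table as TSV with header; floats at 17 sig. digits."""
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns on write: {missing}")
        df = df[list(schema)]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read a TSV with header into typed columns.

    ``schema`` maps column name -> dtype (numpy dtype or ``str``/``int``/
    ``float``). Missing required columns or uncoercible values raise
    :class:`SchemaError`. Extra columns are preserved untyped.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=object)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header") from exc
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, dtype in schema.items():
        try:
            df[col] = df[col].astype(dtype)
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path}: column {col!r} not coercible to {dtype}: {exc}"
            ) from exc
    return df
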
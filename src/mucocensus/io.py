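"""Count-matrix container and readers/writers.

The pipeline's central object is a genes x cells UMI matrix. Two on-disk
layouts are supported: the 10x Genomics triplet directory (``matrix.mtx`` in
MatrixMarket coordinate format plus ``features.tsv`` and ``barcodes.tsv``)
and a dense TSV with gene ids as the first column and barcodes as the header.
"""
from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

MITO_PREFIX = "MT-"

LAYER_TAGS = ("raw", "normalized", "lognorm")


@dataclasses.dataclass
class CountMatrix:
    """Genes x cells expression matrix with gene/cell annotation.

    Parameters
    ----------
    values : ndarray or sparse matrix, shape (n_genes, n_cells)
        Raw UMI counts (non-negative integers) or normalized values.
    gene_ids : array of unique gene identifiers.
    barcodes : array of unique cell barcodes.
    is_mito : boolean array flagging mitochondrial genes. If omitted it is
        derived from the ``MT-`` prefix rule (case-insensitive).
    layer_tag : one of ``"raw"``, ``"normalized"``, ``"lognorm"``.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    is_mito: np.ndarray | None = None
    layer_tag: str = "raw"

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = np.asarray(self.values.todense())
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"{len(self.barcodes)} barcodes for {n_cells} matrix columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if len(set(self.barcodes)) != n_cells:
            raise ValueError("barcodes are not unique")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer tag {self.layer_tag!r}")
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be non-negative")
        if self.layer_tag == "raw":
            if self.values.size and not np.allclose(
                self.values, np.round(self.values)
            ):
                raise ValueError("raw layer must be integer-valued")
        if self.is_mito is None:
            self.is_mito = detect_mito(self.gene_ids)
        self.is_mito = np.asarray(self.is_mito, dtype=bool)
        if len(self.is_mito) != n_genes:
            raise ValueError("is_mito length does not match gene count")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CountMatrix":
        return CountMatrix(
            self.values.copy(),
            self.gene_ids.copy(),
            self.barcodes.copy(),
            self.is_mito.copy(),
            self.layer_tag,
        )

    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            self.values[:, index],
            self.gene_ids,
            self.barcodes[index],
            self.is_mito,
            self.layer_tag,
        )

    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            self.values[index, :],
            self.gene_ids[index],
            self.barcodes,
            self.is_mito[index],
            self.layer_tag,
        )

    def log1p(self) -> "CountMatrix":
        """Natural-log(1 + x) layer."""
        out = self.copy()
        out.values = np.log1p(out.values.astype(float))
        out.layer_tag = "lognorm"
        return out

    def gene_index(self, gene_id: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene_id)
        if hits.size == 0:
            raise KeyError(f"gene {gene_id!r} not in matrix")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.barcodes
        )


def detect_mito(gene_ids) -> np.ndarray:
    """``MT-`` prefix rule, case-insensitive."""
    return np.array(
        [str(g).upper().startswith(MITO_PREFIX) for g in gene_ids], dtype=bool
    )


def _find(directory: Path, candidates) -> Path:
    for name in candidates:
        path = directory / name
        if path.exists():
            return path
    raise FileNotFoundError(
        f"none of {candidates} found in {directory}"
    )


def read_10x_triplet(directory) -> CountMatrix:
    """Read a 10x triplet directory (matrix.mtx + features + barcodes).

    Genes x cells orientation is enforced: if the MTX is cells x genes it is
    transposed, detected by matching dimensions against the features file.
    Mitochondrial genes are flagged from the symbol column (second column of
    the features file when present, else the id column).
    """
    directory = Path(directory)
    mtx_path = _find(directory, ["matrix.mtx"])
    feat_path = _find(directory, ["features.tsv", "genes.tsv"])
    bc_path = _find(directory, ["barcodes.tsv"])

    mat = sp.coo_matrix(mmread(mtx_path))
    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].values
    n_feat, n_bc = len(features), len(barcodes)

    if mat.shape == (n_feat, n_bc):
        pass
    elif mat.shape == (n_bc, n_feat):
        mat = mat.T
    else:
        if n_feat not in mat.shape:
            raise ValueError(
                f"{feat_path.name}: {n_feat} features do not match matrix "
                f"dimensions {mat.shape}"
            )
        raise ValueError(
            f"{bc_path.name}: {n_bc} barcodes do not match matrix "
            f"dimensions {mat.shape}"
        )

    gene_ids = features[0].values
    symbols = features[1].values if features.shape[1] >= 2 else gene_ids
    return CountMatrix(
        values=mat,
        gene_ids=gene_ids,
        barcodes=barcodes,
        is_mito=detect_mito(symbols),
        layer_tag="raw",
    )


def write_10x_triplet(matrix: CountMatrix, directory) -> None:
    """Write ``matrix.mtx`` (integer coordinate), ``features.tsv`` and
    ``barcodes.tsv``; round-trips bit-exactly through :func:`read_10x_triplet`.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("refusing to write an empty matrix")
    for g in matrix.gene_ids:
        if not str(g):
            raise ValueError("empty gene name in matrix")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(np.asarray(matrix.values, dtype=np.int64))
    mmwrite(directory / "matrix.mtx", coo, field="integer",
            symmetry="general")
    with open(directory / "features.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in matrix.barcodes:
            fh.write(f"{b}\n")


def read_dense_tsv(path) -> CountMatrix:
    """Dense TSV: header row of barcodes, first column of gene ids."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicated gene id {dup!r}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"{path.name}: duplicated barcode {dup!r}")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad.values][0]
            raise ValueError(
                f"{path.name}: non-numeric value at gene {row!r}, "
                f"cell {col!r}"
            )
        frame[col] = converted
    values = frame.to_numpy(dtype=float)
    layer = "raw" if np.allclose(values, np.round(values)) else "normalized"
    if layer == "raw":
        values = np.round(values).astype(np.int64)
    return CountMatrix(
        values=values,
        gene_ids=frame.index.to_numpy(dtype=object),
        barcodes=frame.columns.to_numpy(dtype=object),
        layer_tag=layer,
    )


def write_dense_tsv(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def write_tables(tables: dict, directory) -> None:
    """Write every result table (QC, labels, markers, scores...) as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(table)
        table.to_csv(directory / f"{name}.tsv", sep="\t")
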
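"""Sparse UMI count matrix and cell annotation I/O.

On-disk contract is the standard 10x-style triple: a Matrix Market
coordinate integer file (genes as rows, cells as columns; indices 1-based
on disk, 0-based in memory) plus one-symbol-per-line gene and barcode
text files.  Cell annotations are a TSV with header
``barcode  crude_type  subtype  timepoint``.  All files may be gzipped.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from lrxtalk._errors import DataError

logger = logging.getLogger(__name__)


def _open_text(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def deduplicate_names(names: list[str]) -> list[str]:
    """Disambiguate duplicate symbols by suffixing ``.1``, ``.2``, ... in file order."""
    counts: dict[str, int] = {}
    out: list[str] = []
    for name in names:
        n = counts.get(name, 0)
        out.append(name if n == 0 else f"{name}.{n}")
        counts[name] = n + 1
    return out


@dataclass
class ExpressionMatrix:
    """Sparse genes x cells matrix of non-negative integer UMI counts."""

    counts: sp.csr_matrix
    gene_names: np.ndarray
    cell_barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_names) != n_genes:
            raise DataError(
                f"gene name count {len(self.gene_names)} != matrix rows {n_genes}"
            )
        if len(self.cell_barcodes) != n_cells:
            raise DataError(
                f"barcode count {len(self.cell_barcodes)} != matrix columns {n_cells}"
            )
        if len(set(self.cell_barcodes)) != n_cells:
            raise DataError("cell barcodes are not unique")
        if len(set(self.gene_names)) != n_genes:
            raise DataError("gene names are not unique (deduplicate before construction)")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise DataError("negative counts in expression matrix")
            if not np.allclose(data, np.round(data)):
                raise DataError("non-integer counts in expression matrix")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}

    def subset(self, gene_mask=None, cell_mask=None) -> "ExpressionMatrix":
        counts = self.counts
        genes = self.gene_names
        cells = self.cell_barcodes
        if gene_mask is not None:
            counts = counts[gene_mask, :]
            genes = genes[gene_mask]
        if cell_mask is not None:
            counts = counts[:, cell_mask]
            cells = cells[cell_mask]
        return ExpressionMatrix(sp.csr_matrix(counts), genes, cells)


@dataclass
class CellAnnotation:
    """Per-cell crude type / subtype / timepoint labels.

    Stored as a DataFrame indexed by barcode with columns ``crude_type``,
    ``subtype`` (empty string when absent), ``timepoint``.  Each subtype
    label must nest within exactly one crude type.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"crude_type", "subtype", "timepoint"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise DataError("duplicate barcodes in annotation")
        if (self.table["crude_type"] == "").any():
            raise DataError("every cell must have a crude_type")
        if (self.table["timepoint"] == "").any():
            raise DataError("every cell must have a timepoint")
        sub = self.table[self.table["subtype"] != ""]
        parents = sub.groupby("subtype")["crude_type"].nunique()
        bad = parents[parents > 1]
        if len(bad):
            raise DataError(
                f"subtype(s) nested under multiple crude types: {sorted(bad.index)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=object)

    @property
    def timepoints(self) -> list[str]:
        return sorted(self.table["timepoint"].unique())

    @property
    def crude_types(self) -> list[str]:
        return sorted(self.table["crude_type"].unique())

    def subtype_to_crude(self) -> dict[str, str]:
        sub = self.table[self.table["subtype"] != ""]
        return dict(
            sub.groupby("subtype")["crude_type"].first()
        )

    def subset(self, barcodes) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(barcodes)].copy())

    def write(self, path: str | Path) -> None:
        out = self.table.reset_index()
        out.columns = ["barcode"] + list(out.columns[1:])
        out.to_csv(path, sep="\t", index=False)


def read_count_matrix(
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> ExpressionMatrix:
    """Read a 10x-style Matrix Market triple into an :class:`ExpressionMatrix`.

    Duplicate gene symbols are disambiguated deterministically by
    suffixing ``.1``, ``.2``, ... in file order; counts are never altered.

    Raises
    ------
    DataError
        Dimension mismatch between the Matrix Market header and the name
        files, or negative / non-integer entries.
    """
    mtx_path, genes_path, barcodes_path = map(Path, (mtx_path, genes_path, barcodes_path))
    for p in (mtx_path, genes_path, barcodes_path):
        if not p.exists():
            raise DataError(f"file not found: {p}")
    with _open_text(mtx_path, "rb" if mtx_path.suffix == ".gz" else "r") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    genes = _read_lines(genes_path)
    barcodes = _read_lines(barcodes_path)
    if len(genes) != mat.shape[0]:
        raise DataError(
            f"genes file has {len(genes)} entries but matrix header says {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise DataError(
            f"barcodes file has {len(barcodes)} entries but matrix header says "
            f"{mat.shape[1]} columns"
        )
    genes = deduplicate_names(genes)
    return ExpressionMatrix(mat, np.array(genes, dtype=object), np.array(barcodes, dtype=object))


def write_count_matrix(
    matrix: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the on-disk triple (coordinate integer .mtx plus name files)."""
    coo = sp.coo_matrix(matrix.counts)
    scipy.io.mmwrite(str(mtx_path), coo, field="integer")
    Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.gene_names))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in matrix.cell_barcodes))


def read_cell_annotations(path: str | Path, matrix: ExpressionMatrix) -> CellAnnotation:
    """Read the annotation TSV and restrict it to barcodes present in ``matrix``.

    Matrix cells without an annotation are reported (warning with count)
    and excluded from downstream aggregation; annotation rows for
    barcodes absent from the matrix are dropped silently.

    Raises
    ------
    DataError
        No overlapping barcodes, or a subtype appearing under two crude
        types.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "barcode" not in df.columns:
        raise DataError("annotation TSV must have a 'barcode' column")
    if "subtype" not in df.columns:
        df["subtype"] = ""
    df = df.set_index("barcode")

    matrix_barcodes = set(matrix.cell_barcodes)
    present = df.index.isin(matrix_barcodes)
    df = df[present]
    if df.empty:
        raise DataError("no annotated barcodes overlap the expression matrix")
    n_unannotated = matrix.n_cells - len(df)
    if n_unannotated:
        logger.warning(
            "%d matrix cell(s) have no annotation and are excluded from aggregation",
            n_unannotated,
        )
    return CellAnnotation(df[["crude_type", "subtype", "timepoint"]].copy())


def filter_cells_genes(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Single-pass quality filter: gene pass, then cell pass.

    Genes detected (count > 0) in fewer than ``min_cells_per_gene`` cells
    are removed first; then cells expressing fewer than
    ``min_genes_per_cell`` of the *retained* genes are removed.  Each pass
    runs exactly once (no iteration), so the result is deterministic and
    monotone in both thresholds.

    Raises
    ------
    DataError
        All genes or all cells removed.
    """
    if min_cells_per_gene < 0 or min_genes_per_cell < 0:
        raise DataError("filter thresholds must be >= 0")
    detected = matrix.counts.copy()
    detected.data = (detected.data > 0).astype(np.int64)
    cells_per_gene = np.asarray(detected.sum(axis=1)).ravel()
    gene_mask = cells_per_gene >= min_cells_per_gene
    if not gene_mask.any():
        raise DataError("all genes removed by min_cells_per_gene filter")
    genes_per_cell = np.asarray(detected[gene_mask, :].sum(axis=0)).ravel()
    cell_mask = genes_per_cell >= min_genes_per_cell
    if not cell_mask.any():
        raise DataError("all cells removed by min_genes_per_cell filter")
    filtered = matrix.subset(gene_mask=gene_mask, cell_mask=cell_mask)
    keep = [b for b in filtered.cell_barcodes if b in set(annotation.table.index)]
    if not keep:
        raise DataError("no annotated cells survive filtering")
    return filtered, annotation.subset(keep)
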
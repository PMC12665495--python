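"""Pseudobulk aggregation and sum-normalization.

Single-cell counts are collapsed to per-cell-type mean expression within
one timepoint.  Means are taken on *raw* UMI counts; the only
normalization applied is the matrix-sum rule: divide every entry by the
grand total of the matrix and multiply by a scale constant (default
100,000).  Subtype-level means can be recombined to crude-type means by
cell-count weighting, which is algebraically identical to averaging the
crude type directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from lrxtalk._errors import DataError
from lrxtalk.lr_resource import LRPairTable
from lrxtalk.sc_io import CellAnnotation, ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_SCALE = 100_000.0


@dataclass
class GroupExpression:
    """Genes x groups matrix of mean expression for one timepoint."""

    values: np.ndarray
    gene_names: np.ndarray
    group_labels: np.ndarray
    timepoint: str
    normalized: bool = False
    scale_constant: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        if self.values.shape != (len(self.gene_names), len(self.group_labels)):
            raise DataError("GroupExpression shape does not match labels")
        if np.any(self.values < 0):
            raise DataError("GroupExpression values must be non-negative")
        if self.normalized:
            total = self.values.sum()
            if not np.isclose(total, self.scale_constant, rtol=1e-6):
                raise DataError(
                    f"normalized flag set but grand total {total} != {self.scale_constant}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.group_labels)

    def write(self, path: str | Path) -> None:
        """TSV (genes x groups) plus a ``.meta.tsv`` sidecar with metadata."""
        path = Path(path)
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t")
        meta = pd.DataFrame(
            {
                "key": ["timepoint", "normalized", "scale_constant"],
                "value": [self.timepoint, str(self.normalized), repr(self.scale_constant)],
            }
        )
        meta.to_csv(path.with_suffix(path.suffix + ".meta.tsv"), sep="\t", index=False)

    def gene_vector(self, gene: str) -> np.ndarray:
        """Expression of ``gene`` across groups; zeros if the gene is absent."""
        idx = np.flatnonzero(self.gene_names == gene)
        if idx.size == 0:
            return np.zeros(len(self.group_labels))
        return self.values[idx[0], :].copy()


def mean_by_group(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    level: str,
    timepoint: str,
) -> GroupExpression:
    """Arithmetic mean of raw UMI counts per group at one timepoint.

    ``level`` is ``"crude"`` or ``"subtype"``.  Groups with zero cells at
    the timepoint are omitted (not zero-filled); group order is sorted
    for determinism.

    Raises
    ------
    DataError
        Unknown level or timepoint, or no cells at the timepoint.
    """
    if level not in ("crude", "subtype"):
        raise DataError(f"unknown aggregation level {level!r}")
    col = "crude_type" if level == "crude" else "subtype"
    tab = annotation.table
    at_tp = tab[tab["timepoint"] == timepoint]
    if at_tp.empty:
        raise DataError(f"no cells at timepoint {timepoint!r}")
    if level == "subtype":
        at_tp = at_tp[at_tp["subtype"] != ""]
        if at_tp.empty:
            raise DataError(f"no subtype-annotated cells at timepoint {timepoint!r}")

    barcode_to_col = {b: i for i, b in enumerate(matrix.cell_barcodes)}
    groups = sorted(at_tp[col].unique())
    values = np.zeros((matrix.n_genes, len(groups)))
    for j, g in enumerate(groups):
        barcodes = at_tp.index[at_tp[col] == g]
        cols = [barcode_to_col[b] for b in barcodes if b in barcode_to_col]
        if not cols:
            raise DataError(f"group {g!r} has no cells present in the matrix")
        sub = matrix.counts[:, cols]
        values[:, j] = np.asarray(sub.sum(axis=1)).ravel() / len(cols)
    return GroupExpression(
        values=values,
        gene_names=matrix.gene_names,
        group_labels=np.array(groups, dtype=object),
        timepoint=timepoint,
        normalized=False,
    )


def group_cell_counts(
    annotation: CellAnnotation, level: str, timepoint: str
) -> dict[str, int]:
    """Number of cells per group at a timepoint (helper for weighting)."""
    col = "crude_type" if level == "crude" else "subtype"
    tab = annotation.table
    at_tp = tab[tab["timepoint"] == timepoint]
    if col == "subtype":
        at_tp = at_tp[at_tp["subtype"] != ""]
    return at_tp.groupby(col).size().to_dict()


def weighted_mean_over_subtypes(
    subtype_expr: GroupExpression,
    subtype_counts: Mapping[str, int],
    subtype_to_crude: Mapping[str, str],
) -> GroupExpression:
    """Cell-count-weighted average of subtype means up to crude types.

    For each crude type c the output is
    sum_s(count_s * mean_s) / sum_s(count_s) over its subtypes s, which
    equals the direct crude-level mean over the same cells exactly.

    Raises
    ------
    DataError
        A subtype missing from the map or counts, non-positive counts,
        or zero total weight for a crude type.
    """
    crude_sums: dict[str, np.ndarray] = {}
    crude_weights: dict[str, float] = {}
    for j, sub in enumerate(subtype_expr.group_labels):
        if sub not in subtype_to_crude:
            raise DataError(f"subtype {sub!r} missing from subtype_to_crude map")
        if sub not in subtype_counts:
            raise DataError(f"subtype {sub!r} missing from subtype_counts")
        w = float(subtype_counts[sub])
        if w <= 0:
            raise DataError(f"subtype {sub!r} has non-positive cell count {w}")
        crude = subtype_to_crude[sub]
        if crude not in crude_sums:
            crude_sums[crude] = np.zeros(len(subtype_expr.gene_names))
            crude_weights[crude] = 0.0
        crude_sums[crude] += w * subtype_expr.values[:, j]
        crude_weights[crude] += w
    crude_labels = sorted(crude_sums)
    values = np.column_stack(
        [crude_sums[c] / crude_weights[c] for c in crude_labels]
    )
    return GroupExpression(
        values=values,
        gene_names=subtype_expr.gene_names,
        group_labels=np.array(crude_labels, dtype=object),
        timepoint=subtype_expr.timepoint,
        normalized=False,
    )


def normalize_total(
    expr: GroupExpression, scale_constant: float = DEFAULT_SCALE
) -> GroupExpression:
    """Scale by the matrix grand total so all entries sum to ``scale_constant``.

    Scale-invariant (multiplying the input by a constant changes nothing)
    and idempotent up to the constant.

    Raises
    ------
    DataError
        All-zero matrix.
    """
    total = expr.values.sum()
    if total <= 0:
        raise DataError("cannot normalize an all-zero expression matrix")
    return replace(
        expr,
        values=expr.values / total * scale_constant,
        normalized=True,
        scale_constant=scale_constant,
    )


def slice_genes(expr: GroupExpression, genes: list[str]) -> tuple[GroupExpression, list[str]]:
    """Row-subset ``expr`` to ``genes`` in the given order.

    Genes absent from the matrix get an all-zero row and are returned in
    the second element so run reports can list them.
    """
    index = {g: i for i, g in enumerate(expr.gene_names)}
    values = np.zeros((len(genes), len(expr.group_labels)))
    missing: list[str] = []
    for r, g in enumerate(genes):
        i = index.get(g)
        if i is None:
            missing.append(g)
        else:
            values[r, :] = expr.values[i, :]
    if missing:
        logger.warning("%d gene(s) absent from expression matrix: %s", len(missing), missing)
    out = GroupExpression(
        values=values,
        gene_names=np.array(genes, dtype=object),
        group_labels=expr.group_labels.copy(),
        timepoint=expr.timepoint,
        normalized=False,
        scale_constant=expr.scale_constant,
    )
    return out, missing


def prepare_lr_expression(
    expr: GroupExpression,
    pairs: LRPairTable,
    normalize_scope: str = "per-slice",
    scale_constant: float = DEFAULT_SCALE,
) -> tuple[GroupExpression, GroupExpression, list[str]]:
    """Slice ligand and receptor gene rows and apply sum-normalization.

    With ``normalize_scope="per-slice"`` (default) the ligand submatrix
    and the receptor submatrix are sliced first and each scaled by its
    own grand total; with ``"whole-matrix"`` the full matrix is
    normalized once and then sliced (slices then keep the whole-matrix
    scaling and are flagged normalized).

    Returns (ligand_expr, receptor_expr, missing_genes).
    """
    if normalize_scope not in ("per-slice", "whole-matrix"):
        raise DataError(f"unknown normalize_scope {normalize_scope!r}")
    lig_genes = sorted(set(pairs.ligands))
    rec_genes = sorted(set(pairs.receptors))
    if normalize_scope == "per-slice":
        lig_expr, miss_l = slice_genes(expr, lig_genes)
        rec_expr, miss_r = slice_genes(expr, rec_genes)
        lig_expr = normalize_total(lig_expr, scale_constant)
        rec_expr = normalize_total(rec_expr, scale_constant)
    else:
        whole = normalize_total(expr, scale_constant)
        lig_expr, miss_l = slice_genes(whole, lig_genes)
        rec_expr, miss_r = slice_genes(whole, rec_genes)
        # slices inherit the whole-matrix scaling; mark them usable downstream
        lig_expr.normalized = True
        rec_expr.normalized = True
    missing = sorted(set(miss_l) | set(miss_r))
    return lig_expr, rec_expr, missing
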
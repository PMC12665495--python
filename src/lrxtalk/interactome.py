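"""Outer-product ligand-receptor interaction scores and their summaries.

For each LR pair p, the ligand column vector L_p (normalized mean ligand
expression per cell type) and the receptor row vector R_p (normalized
mean receptor expression per cell type) define a cell-type adjacency
matrix A_p = L_p x R_p.  The product is non-interchangeable: rows are
ligand-expressing cell types, columns receptor-expressing cell types.
Every A_p is rank-1 by construction; summaries (totals, per-cell-type
shares, percent change, top-k rankings, log fold changes, circos edge
lists) are defined on the per-pair tensors or their sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lrxtalk._errors import DataError
from lrxtalk.aggregate import GroupExpression
from lrxtalk.lr_resource import LRPairTable

PROPORTION_MODES = ("both-sides", "ligand", "receptor")


@dataclass
class InteractionTensor:
    """Per-pair cell-type x cell-type score matrices for one timepoint.

    ``scores`` has shape (n_pairs, n_types, n_types); ``missing_pairs``
    flags pairs whose ligand or receptor gene was absent from the
    expression data (those score 0 everywhere).
    """

    scores: np.ndarray
    cell_type_labels: np.ndarray
    pair_list: LRPairTable
    timepoint: str
    missing_pairs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
        n = len(self.cell_type_labels)
        if self.scores.shape != (len(self.pair_list), n, n):
            raise DataError("InteractionTensor score shape mismatch")
        if np.any(self.scores < 0):
            raise DataError("interaction scores must be non-negative")

    def type_index(self, label: str) -> int:
        idx = np.flatnonzero(self.cell_type_labels == label)
        if idx.size == 0:
            raise DataError(f"unknown cell type label {label!r}")
        return int(idx[0])

    def pair_scores_at(self, ligand_type: str, receptor_type: str) -> pd.Series:
        """Per-pair scores at one (ligand type, receptor type) entry."""
        i = self.type_index(ligand_type)
        j = self.type_index(receptor_type)
        labels = [p.label for p in self.pair_list]
        return pd.Series(self.scores[:, i, j], index=labels, name="score")

    def restrict_pairs(self, sub_table: LRPairTable) -> "InteractionTensor":
        """Tensor restricted to a pair sub-table (e.g. a receptor family)."""
        keys = {(p.ligand, p.receptor) for p in sub_table}
        mask = np.array(
            [(p.ligand, p.receptor) in keys for p in self.pair_list], dtype=bool
        )
        kept = [p for p in self.pair_list if (p.ligand, p.receptor) in keys]
        return InteractionTensor(
            scores=self.scores[mask],
            cell_type_labels=self.cell_type_labels.copy(),
            pair_list=LRPairTable(kept, self.pair_list.source_name),
            timepoint=self.timepoint,
            missing_pairs=[m for m in self.missing_pairs if m in {p.label for p in kept}],
        )


@dataclass
class InteractionSummary:
    """Cell-type x cell-type total interactions (sum over pairs)."""

    total_matrix: np.ndarray
    cell_type_labels: np.ndarray
    timepoint: str

    def __post_init__(self) -> None:
        self.total_matrix = np.asarray(self.total_matrix, dtype=float)
        self.cell_type_labels = np.asarray(self.cell_type_labels, dtype=object)
        n = len(self.cell_type_labels)
        if self.total_matrix.shape != (n, n):
            raise DataError("InteractionSummary shape mismatch")
        if np.any(self.total_matrix < 0):
            raise DataError("total interactions must be non-negative")

    @property
    def grand_total(self) -> float:
        return float(self.total_matrix.sum())

    def entry(self, ligand_type: str, receptor_type: str) -> float:
        i = _index_of(self.cell_type_labels, ligand_type)
        j = _index_of(self.cell_type_labels, receptor_type)
        return float(self.total_matrix[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.total_matrix,
            index=self.cell_type_labels,
            columns=self.cell_type_labels,
        )


def _index_of(labels: np.ndarray, label: str) -> int:
    idx = np.flatnonzero(labels == label)
    if idx.size == 0:
        raise DataError(f"unknown cell type label {label!r}")
    return int(idx[0])


def interaction_scores(
    ligand_expr: GroupExpression,
    receptor_expr: GroupExpression,
    pairs: LRPairTable,
) -> InteractionTensor:
    """Score every LR pair as the outer product A_p = L_p x R_p.

    Both inputs must be normalized and share group labels and timepoint.
    A pair whose ligand or receptor gene is absent from its expression
    matrix scores zero everywhere and is flagged in ``missing_pairs``.
    """
    if not (ligand_expr.normalized and receptor_expr.normalized):
        raise DataError("interaction_scores requires normalized expression inputs")
    if list(ligand_expr.group_labels) != list(receptor_expr.group_labels):
        raise DataError("ligand and receptor expressions have mismatched group labels")
    if ligand_expr.timepoint != receptor_expr.timepoint:
        raise DataError("ligand and receptor expressions are from different timepoints")

    n_types = len(ligand_expr.group_labels)
    lig_index = {g: i for i, g in enumerate(ligand_expr.gene_names)}
    rec_index = {g: i for i, g in enumerate(receptor_expr.gene_names)}
    L = np.zeros((len(pairs), n_types))
    R = np.zeros((len(pairs), n_types))
    missing: list[str] = []
    for k, p in enumerate(pairs):
        li = lig_index.get(p.ligand)
        ri = rec_index.get(p.receptor)
        if li is not None:
            L[k, :] = ligand_expr.values[li, :]
        if ri is not None:
            R[k, :] = receptor_expr.values[ri, :]
        if li is None or ri is None:
            missing.append(p.label)
    scores = np.einsum("ki,kj->kij", L, R)
    return InteractionTensor(
        scores=scores,
        cell_type_labels=ligand_expr.group_labels.copy(),
        pair_list=pairs,
        timepoint=ligand_expr.timepoint,
        missing_pairs=missing,
    )


def total_interaction_matrix(tensor: InteractionTensor) -> InteractionSummary:
    """Sum the per-pair adjacency matrices into the total-interaction heatmap."""
    if len(tensor.pair_list) == 0:
        raise DataError("empty interaction tensor")
    return InteractionSummary(
        total_matrix=tensor.scores.sum(axis=0),
        cell_type_labels=tensor.cell_type_labels.copy(),
        timepoint=tensor.timepoint,
    )


def participation_proportions(
    summary: InteractionSummary, mode: str = "both-sides"
) -> pd.Series:
    """Per-cell-type share of total interactions.

    ``both-sides`` (default) counts each interaction once at its ligand
    end and once at its receptor end:
    (rowsum_i + colsum_i) / (2 * grand total).  ``ligand`` uses row sums
    over the grand total, ``receptor`` column sums.  Proportions always
    sum to 1.
    """
    if mode not in PROPORTION_MODES:
        raise DataError(f"unknown proportion mode {mode!r}")
    total = summary.grand_total
    if total <= 0:
        raise DataError("zero grand total; proportions undefined")
    rows = summary.total_matrix.sum(axis=1)
    cols = summary.total_matrix.sum(axis=0)
    if mode == "both-sides":
        values = (rows + cols) / (2.0 * total)
    elif mode == "ligand":
        values = rows / total
    else:
        values = cols / total
    return pd.Series(values, index=summary.cell_type_labels, name="proportion")


def percent_change(
    summary_t: InteractionSummary,
    summary_ref: InteractionSummary,
    ligand_type: str,
    receptor_type: str,
) -> float:
    """Signed percent change of one (ligand type, receptor type) total.

    100 * (x_t - x_ref) / x_ref; the reference entry must be positive.
    """
    x_ref = summary_ref.entry(ligand_type, receptor_type)
    if x_ref <= 0:
        raise DataError(
            f"reference entry ({ligand_type},{receptor_type}) is zero; "
            "percent change undefined"
        )
    x_t = summary_t.entry(ligand_type, receptor_type)
    return 100.0 * (x_t - x_ref) / x_ref


def top_k_pairs(
    tensor: InteractionTensor,
    ligand_type: str,
    receptor_type: str,
    k: int = 10,
) -> pd.DataFrame:
    """Strongest k pairs at one (ligand type, receptor type) entry.

    Sorted by score descending; ties broken by (ligand gene, receptor
    gene) lexicographic ascending.  Returns columns
    ``ligand, receptor, score``.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    i = tensor.type_index(ligand_type)
    j = tensor.type_index(receptor_type)
    rows = [
        (p.ligand, p.receptor, float(tensor.scores[idx, i, j]))
        for idx, p in enumerate(tensor.pair_list)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows[:k], columns=["ligand", "receptor", "score"])


def pair_log_fold_change(
    tensor_t: InteractionTensor,
    tensor_ref: InteractionTensor,
    ligand_type: str,
    receptor_type: str,
    pseudocount: float | None = None,
) -> pd.Series:
    """Per-pair log2 fold change of one entry between two timepoints.

    log2((A_p,t + eps) / (A_p,ref + eps)); pairs at zero in both
    timepoints are omitted.  The default pseudocount is 1e-6 times the
    mean positive score over both tensors at the chosen entry; pass 0
    only when no reported pair has a zero on either side.
    """
    s_t = tensor_t.pair_scores_at(ligand_type, receptor_type)
    s_ref = tensor_ref.pair_scores_at(ligand_type, receptor_type)
    if list(s_t.index) != list(s_ref.index):
        raise DataError("tensors have different pair lists")
    both = np.concatenate([s_t.to_numpy(), s_ref.to_numpy()])
    nonzero = (s_t > 0) | (s_ref > 0)
    if pseudocount is None:
        positive = both[both > 0]
        pseudocount = 1e-6 * positive.mean() if positive.size else 1.0
    if pseudocount < 0:
        raise DataError("pseudocount must be non-negative")
    if pseudocount == 0:
        zero_one_side = ((s_t == 0) ^ (s_ref == 0)) & nonzero
        if zero_one_side.any():
            raise DataError(
                "pseudocount must be positive when a pair is zero at one timepoint"
            )
    kept = s_t.index[nonzero]
    lfc = np.log2((s_t[kept] + pseudocount) / (s_ref[kept] + pseudocount))
    lfc.name = "log2_fold_change"
    return lfc


def export_circos_edges(
    summary: InteractionSummary,
    path: str | Path,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Write a chord-diagram edge list TSV (source, target, weight).

    Source is the ligand-expressing type, target the receptor-expressing
    type.  Rows are ordered (source, target) lexicographic so output is
    byte-identical across runs; the sum of written weights equals the
    grand total when ``include_zero`` is set (and still does otherwise,
    zero edges contributing nothing).
    """
    labels = sorted(summary.cell_type_labels)
    rows = []
    for src in labels:
        for tgt in labels:
            w = summary.entry(src, tgt)
            if w > 0 or include_zero:
                rows.append((src, tgt, w))
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df
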
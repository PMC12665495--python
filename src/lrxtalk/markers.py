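"""Marker-gene screen: per-gene two-sided Wilcoxon rank-sum with Bonferroni.

The screen compares raw UMI counts of one cell group against a reference
group, gene by gene.  For small groups (both sizes <= 8) the exact
permutation distribution of the rank-sum statistic is enumerated, which
is correct under ties; larger groups use the tie-corrected normal
approximation with continuity correction.  Passing genes (Bonferroni-
adjusted p below alpha) are ranked by raw p and truncated to a top-n
list intended for downstream enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from lrxtalk._errors import DataError
from lrxtalk.sc_io import CellAnnotation, ExpressionMatrix

EXACT_MAX_GROUP = 8


def wilcoxon_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    Exact permutation enumeration when both groups have <= 8
    observations (valid with ties); otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks under ties
    w_obs = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        return _exact_two_sided_p(ranks, n1, w_obs, mu)
    return _normal_two_sided_p(ranks, n1, n2, w_obs, mu)


def _exact_two_sided_p(ranks: np.ndarray, n1: int, w_obs: float, mu: float) -> float:
    n = len(ranks)
    dev_obs = abs(w_obs - mu)
    hits = 0
    total = comb(n, n1)
    for idx in combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def _normal_two_sided_p(
    ranks: np.ndarray, n1: int, n2: int, w_obs: float, mu: float
) -> float:
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    dev = abs(w_obs - mu)
    z = max(dev - 0.5, 0.0) / sqrt(var)  # continuity correction
    return erfc(z / sqrt(2.0))


@dataclass
class MarkerResult:
    """Ranked marker-screen output.

    ``table`` columns: gene, p, p_bonferroni, direction (sign of
    target-minus-reference mean difference), rank.  Sorted by raw p
    ascending, ties by gene symbol; Bonferroni denominator is the number
    of genes actually tested (recorded in ``n_genes_tested``).
    """

    table: pd.DataFrame
    n_genes_tested: int
    target_group: str
    reference_group: str
    alpha: float

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def select_marker_genes(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    target_group: str,
    reference_group: str,
    alpha: float = 0.05,
    top_n: int = 150,
    level: str = "auto",
) -> MarkerResult:
    """Screen genes discriminating ``target_group`` from ``reference_group``.

    Groups may be crude types or subtypes (``level="auto"`` matches
    either column).  Genes detected in at least one cell of the union
    are tested with the two-sided Wilcoxon rank-sum on raw counts;
    Bonferroni correction uses the number of genes tested; genes with
    adjusted p below ``alpha`` are kept and the list truncated to
    ``top_n`` by raw p.

    Raises
    ------
    DataError
        A group with fewer than 2 cells, or no detected genes.
    """
    cells_a = _group_barcodes(annotation, target_group, level)
    cells_b = _group_barcodes(annotation, reference_group, level)
    if len(cells_a) < 2 or len(cells_b) < 2:
        raise DataError("both groups need at least 2 cells")
    barcode_to_col = {b: i for i, b in enumerate(matrix.cell_barcodes)}
    cols_a = [barcode_to_col[b] for b in cells_a if b in barcode_to_col]
    cols_b = [barcode_to_col[b] for b in cells_b if b in barcode_to_col]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise DataError("both groups need at least 2 cells present in the matrix")

    a = np.asarray(matrix.counts[:, cols_a].todense(), dtype=float)
    b = np.asarray(matrix.counts[:, cols_b].todense(), dtype=float)
    detected = (a.sum(axis=1) + b.sum(axis=1)) > 0
    genes = np.flatnonzero(detected)
    if genes.size == 0:
        raise DataError("no genes detected in the union of the two groups")
    n_tested = int(genes.size)

    records = []
    for g in genes:
        p = wilcoxon_rank_sum_p(a[g], b[g])
        diff = a[g].mean() - b[g].mean()
        records.append(
            (str(matrix.gene_names[g]), p, min(1.0, p * n_tested), int(np.sign(diff)))
        )
    df = pd.DataFrame(records, columns=["gene", "p", "p_bonferroni", "direction"])
    df = df[df["p_bonferroni"] < alpha]
    df = df.sort_values(["p", "gene"], kind="mergesort").head(top_n).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return MarkerResult(
        table=df,
        n_genes_tested=n_tested,
        target_group=target_group,
        reference_group=reference_group,
        alpha=alpha,
    )


def _group_barcodes(annotation: CellAnnotation, group: str, level: str) -> list[str]:
    tab = annotation.table
    if level == "crude":
        mask = tab["crude_type"] == group
    elif level == "subtype":
        mask = tab["subtype"] == group
    elif level == "auto":
        mask = (tab["crude_type"] == group) | (tab["subtype"] == group)
    else:
        raise DataError(f"unknown level {level!r}")
    return list(tab.index[mask])
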
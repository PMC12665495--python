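# lrxtalk

Ligand–receptor interactome scoring for multi-timepoint single-cell UMI
data, built for studies of directed cell–cell communication — the
motivating application is non-cardiomyocyte crosstalk (endothelial
cells, fibroblasts, smooth muscle, blood and neural cells) across the
progression of pressure-overload heart failure, where fibroblast→
endothelial signaling through scavenger receptors such as Scarb1 is of
particular interest.

## The method

For each timepoint, raw UMI counts are averaged per cell type (subtype
means recombined by cell-count weighting, which equals the direct
crude-type mean exactly). The ligand-gene and receptor-gene submatrices
are sliced from the raw means and each sum-normalized: every entry is
divided by the matrix grand total and multiplied by 100,000. For a
ligand–receptor pair *p* with normalized ligand expression **L** (a
column vector over cell types) and receptor expression **R** (a row
vector over cell types), the pair's adjacency matrix is the outer
product

&nbsp;&nbsp;&nbsp;&nbsp;**A** = **L** × **R**&nbsp;&nbsp;(non-interchangeable),

so `A[i, j]` scores signaling from ligand-expressing type *i* to
receptor-expressing type *j*, and every `A` is rank-1 by construction.
Summaries over the per-pair tensors give the standard readouts:
per-cell-type interaction shares, total-interaction heatmaps, percent
change of a focal entry between timepoints (e.g. FB→EC from healthy to
failure), top-*k* pair rankings, per-pair log₂ fold changes, receptor-
family totals, and chord-diagram edge lists.

Companion modules provide the echocardiographic Teichholz formulas
(EDV = 7.0/(2.4 + LVDd)·LVDd³, LVEF = 100·(EDV − ESV)/EDV), the
perivascular (A_F/abπ) and interstitial (A_F/A_FoV) fibrosis ratios, a
two-sided Wilcoxon rank-sum marker screen with Bonferroni correction
(exact enumeration for small groups), and a seeded negative-binomial
synthetic-data generator with planted ligand–receptor programs so every
stage is testable without any download.

## Worked example

Generate a synthetic three-timepoint study (2,000 cells per timepoint,
200 genes, five cell types) with one planted program — Thbs1→Scarb1
elevated 8-fold in fibroblasts/endothelial cells at 12 weeks — then
score it:

```python
from lrxtalk import (default_config, generate_dataset, mean_by_group,
                     weighted_mean_over_subtypes, prepare_lr_expression,
                     interaction_scores, total_interaction_matrix,
                     top_k_pairs, percent_change)
from lrxtalk.aggregate import group_cell_counts

cfg = default_config(seed=0)
matrix, ann, truth = generate_dataset(cfg)

def score(tp):
    sub = mean_by_group(matrix, ann, "subtype", tp)
    crude = weighted_mean_over_subtypes(
        sub, group_cell_counts(ann, "subtype", tp), ann.subtype_to_crude())
    lig, rec, _ = prepare_lr_expression(crude, cfg.pairs)
    return interaction_scores(lig, rec, cfg.pairs)

t12, t0 = score("12w"), score("0w")
print(top_k_pairs(t12, "FB", "EC", 3))
print(percent_change(total_interaction_matrix(t12),
                     total_interaction_matrix(t0), "FB", "EC"))
```

which prints

```
  ligand receptor         score
0  Thbs1   Scarb1  1.194261e+08
1   Apoe   Scarb1  1.498177e+07
2  Thbs1     Cd36  1.232830e+07
257.24599768693554
```

The planted pair ranks first among all pairs at the fibroblast→
endothelial entry at 12 weeks (its baseline rank at 0 weeks is 10 of
12), and the total FB→EC interaction rises by +257% from the healthy to
the failing timepoint. Scores are products of two sum-normalized
expression values (each matrix summing to 100,000), so their absolute
magnitude is only meaningful relative to other entries of the same run.

The same workflow is available from the shell:

```sh
lrxtalk synth --seed 0 --out data/
lrxtalk run --config pipeline.cfg          # full pipeline + run report
lrxtalk top --mtx data/matrix.mtx --genes data/genes.tsv \
    --barcodes data/barcodes.tsv --annot data/annotations.tsv \
    --pairs data/lr_pairs.tsv --timepoint 12w \
    --ligand-type FB --receptor-type EC -k 10
```

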
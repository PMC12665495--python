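# Methods

## Interaction model

The score of a ligand–receptor pair *p* between a ligand-expressing
cell type *i* and a receptor-expressing cell type *j* at one timepoint
is

    A_p[i, j] = L_p[i] · R_p[j]

where `L_p` and `R_p` are the sum-normalized mean expression of the
pair's ligand and receptor genes across cell types. The product is
directional (ligand side on rows, receptor side on columns) and each
`A_p` is rank-1 by construction, which the tests verify through the
cross-ratio identity `A[i,j]·A[k,l] = A[i,l]·A[k,j]` on positive
entries. The model has no significance machinery: it is a descriptive
score whose value lies in comparisons — across cell-type pairs, across
timepoints, and across pairs at a fixed entry. Permutation-based
empirical p-values (CellPhoneDB-style) are deliberately out of scope.

### Aggregation

Means are taken on raw UMI counts, not log-normalized values; the only
normalization in the scoring path is the matrix-sum rule below.
Aggregation runs at subtype level and is recombined to crude types by
cell-count weighting, Σ_s(n_s·mean_s)/Σ_s n_s — an exact algebraic
identity with the direct crude-level mean over the same cells, asserted
to 1e-10 relative in the tests. Groups with no cells at a timepoint are
omitted rather than zero-filled, since a zero mean is a statement about
expression, not absence of data.

### Normalization

`normalize_total` divides every entry by the matrix grand total and
multiplies by the scale constant (default 100,000), making scores
invariant to global sequencing depth; tests confirm that multiplying
every raw count by a constant leaves proportions, percent changes, and
log fold changes unchanged. Two scopes are supported because the
slicing/normalization order is a genuinely open choice: the default
`per-slice` scales the ligand submatrix and the receptor submatrix each
by its own total (so both sum to 100,000); `whole-matrix` normalizes
the full gene × cell-type matrix once and then slices. Rankings within
one timepoint are identical under both; absolute magnitudes differ.

### Summaries

- **Total interactions**: Σ_p A_p, the cell type × cell type heatmap.
- **Participation proportions**: default `both-sides` counts each unit
  of interaction weight once at its ligand end and once at its receptor
  end, (rowsumᵢ + colsumᵢ)/(2·total); `ligand` and `receptor` modes use
  one-sided sums. All three sum to 1 exactly.
- **Percent change**: 100·(x_t − x_ref)/x_ref on one focal entry;
  undefined (error) when the reference entry is zero.
- **Top-k ranking**: descending score, ties broken lexicographically by
  (ligand, receptor) so outputs are byte-stable.
- **Log fold change**: log₂((A_t + ε)/(A_ref + ε)) per pair at a focal
  entry. Base 2 is the field convention. The default pseudocount is
  1e-6 × the mean positive score at that entry — small enough not to
  compress real fold changes, large enough to keep zeros finite; pairs
  zero at both timepoints are omitted. The pseudocount used is recorded
  in the pipeline run report.
- **Family totals**: restriction of the pair table by receptor
  membership (e.g. scavenger receptors Scarb1/Cd36); totals over a
  family and its complement add exactly to the full totals.

Crude-type level is the default for all summaries; subtype-level
tensors are available by aggregating at `level="subtype"`.

## Quality filtering

`filter_cells_genes` applies a single pass each of a gene filter
(detected in ≥ 3 cells by default) then a cell filter (≥ 200 detected
genes by default, counted over the retained genes). Single-pass
filtering is deterministic and monotone in both thresholds; iterating
to a fixed point is intentionally not done.

## LR resource handling

Published LR-pair resources are typically human; `symbol_case=
"mouse-title-case"` converts symbols to the mouse Title-case
convention. This mapping is approximate (it cannot resolve non-trivial
orthology), so pairs whose genes are absent from the expression matrix
are never dropped silently: they score zero, are flagged on the tensor,
and are listed in the run report. Duplicate (ligand, receptor) rows are
collapsed to the first occurrence so no pair is double-counted.

## Marker screen

Per-gene two-sided Wilcoxon rank-sum on raw counts between two cell
groups, Bonferroni-corrected over the genes actually tested (detected
in ≥ 1 cell of the union; the denominator is recorded in the result).
For groups of ≤ 8 cells each, the exact permutation distribution of the
rank-sum statistic is enumerated over all C(n, n₁) assignments using
midranks, which is correct under ties; larger groups use the normal
approximation with tie correction and a 0.5 continuity correction,
which agrees with the exact value to within 0.02 at the boundary size.
Passing genes (adjusted p < α, default 0.05) are ranked by raw p (ties
by symbol) and truncated to the top 150 by default, the size of list
conventionally passed to downstream enrichment tools.

## Cardiac metrics

Teichholz volumes V(D) = 7.0/(2.4 + D)·D³ from M-mode diameters (mm →
µl), LVEF = 100·(EDV − ESV)/EDV. LVEF is bounded in [0, 100] for
physiologic inputs (0 ≤ LVDs ≤ LVDd); non-physiologic inputs are
warned about but never clamped, so out-of-range outputs remain visible
for audit. Fibrosis ratios: perivascular A_F/(a·b·π) with a, b the
vessel **semi**-axes (the normalizer is then exactly the ellipse area;
`full_axis=True` accepts full axes and halves them), interstitial
A_F/A_FoV ∈ [0, 1]. Both are dimensionless and invariant under a common
unit change.

## Synthetic data generator

The generator emulates the study design the scoring pipeline assumes:
timepoints 0w/2w/12w; crude types EC, FB, SMC, BC, NC with 1–3 nested
subtypes each; 2,000 cells per timepoint; 200 genes (the bundled
12-pair LR resource's 19 genes first, filler genes after); cell-type
mixtures shifting across timepoints with an EC peak at 2w (endothelial
expansion during hypertrophy) and an FB rise toward 12w.

Counts are gamma–Poisson (negative binomial): per-gene baseline means
are log-normal (median 0.5 UMI, log-sd 0.6), modulated by per-(gene,
crude type) log-normal factors (log-sd 0.3), with per-gene dispersion
φ = 0.5 giving Var = µ + φµ². A planted program multiplies its ligand
gene's mean in the ligand cell type and its receptor gene's mean in the
receptor cell type by a per-timepoint fold; the default program is
Thbs1→Scarb1, FB→EC, 8-fold at 12w only. Structure (baselines, factors)
is drawn from a dedicated stream of the seed; each timepoint samples
from its own spawned stream, so adding a timepoint never perturbs
earlier draws, and an optional `sampling_seed` varies sampling noise
under a fixed expression program for Monte-Carlo checks.

The default spreads are set by an identifiability argument: the planted
program confers a log-score advantage of log 64 ≈ 4.16 at its entry,
while the log difference between two pairs' baseline score products has
sd 2√(σ_b² + σ_t²) ≈ 1.34 — a ≈ 3σ margin per competing pair, so the
planted pair is recoverable as top-1 in ≥ 95% of replicates. The
residual failures come almost entirely from pairs sharing a planted
gene (Thbs1→Cd36 inherits the ligand-side elevation; Apoe→Scarb1 the
receptor side), which face only a single 8-fold margin. Larger spreads
would make top-1 recovery impossible for any method, since a planted
elevation cannot dominate a pair whose baseline product is orders of
magnitude higher.

`expected_scores` propagates the analytic E[count] per (gene, type)
through the same slicing/normalization/outer-product arithmetic,
yielding the oracle for recovery tests. Because normalization is a
ratio, the propagated value is a ratio of expectations, not the
expectation of the ratio; at the default cell counts the resulting bias
is a few percent, which the Monte-Carlo tests allow for explicitly, and
rank order is unaffected.

Deliberately not modeled: ambient RNA, doublets, batch effects, library-
size variation between cells, spatial structure, and pseudotime. The
generator shows that the pipeline computes its quantities correctly and
recovers planted directional programs above negative-binomial sampling
noise — not that the scores are biologically identifiable in any real
tissue.

## Pipeline and determinism

`run_pipeline` composes read → filter → aggregate (subtype-weighted) →
normalize → score → summaries → export and writes seven TSV outputs
plus a JSON run report (input SHA-256 digests, parameters, zero-filled
LR genes, stage timings, output manifest with digests). All TSV outputs
are byte-identical across reruns on identical inputs; the report's
timing fields are the only non-deterministic output. Errors propagate
with the failing stage's name attached; the CLI maps configuration
errors to exit code 2 and data errors to 3.

## Problem sizes in the test suite

Unit tests run on matrices of tens of genes and hundreds of cells,
where brute-force oracles (per-cell loops, triple-loop score sums,
252-assignment Wilcoxon enumerations) are exact and fast. The
end-to-end recovery check runs the full default design (3 × 2,000 cells
× 200 genes) over 100 seeded replicates. The acceptance script repeats
that recovery computation from scratch with seeds derived from its
`--seed` argument.
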
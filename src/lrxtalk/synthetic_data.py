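"""Seeded synthetic multi-timepoint single-cell UMI datasets.

The generator emulates the experimental design the interactome analysis
assumes: three timepoints of a pressure-overload time course (healthy at
0w, adaptive hypertrophy at 2w, failure at 12w), five crude cell types
(EC, FB, SMC, BC, NC) with nested subtypes, overdispersed UMI counts,
cell-population shifts across timepoints (EC expansion during
hypertrophy), and *planted* ligand-receptor programs: a chosen ligand
gene elevated by a fold factor in its ligand cell type, and the receptor
likewise in its receptor cell type, per timepoint.

Counts are gamma-Poisson (negative binomial): for cell c of crude type t,
count(g) ~ Poisson(Gamma(shape=1/phi_g, scale=mu_gt * phi_g)), so
E[count] = mu_gt and Var = mu_gt + phi_g * mu_gt^2.  Per-gene baseline
means and per-(gene, cell type) factors are drawn once from a dedicated
structure stream; each timepoint samples from its own spawned stream so
adding a timepoint never perturbs earlier draws.

Ground truth (planted pair identities, analytic expected score
rankings, per-cell labels) is emitted alongside for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from lrxtalk._errors import ConfigError
from lrxtalk.aggregate import GroupExpression, prepare_lr_expression
from lrxtalk.interactome import InteractionTensor, interaction_scores
from lrxtalk.lr_resource import LRPair, LRPairTable
from lrxtalk.sc_io import CellAnnotation, ExpressionMatrix, write_count_matrix

DEFAULT_TIMEPOINTS = ("0w", "2w", "12w")

# crude-type mixture per timepoint; EC share peaks during the
# hypertrophic phase, mirroring endothelial expansion under pressure
# overload, and FB share rises toward failure
DEFAULT_PROPORTIONS: dict[str, dict[str, float]] = {
    "0w": {"EC": 0.30, "FB": 0.25, "BC": 0.20, "SMC": 0.15, "NC": 0.10},
    "2w": {"EC": 0.40, "FB": 0.25, "BC": 0.15, "SMC": 0.12, "NC": 0.08},
    "12w": {"EC": 0.35, "FB": 0.28, "BC": 0.15, "SMC": 0.13, "NC": 0.09},
}

DEFAULT_SUBTYPES: dict[str, dict[str, float]] = {
    "EC": {"CEC": 0.6, "AEC": 0.25, "LEC": 0.15},
    "FB": {"FB1": 0.5, "FB2": 0.3, "FB3": 0.2},
    "SMC": {"SMC1": 0.7, "SMC2": 0.3},
    "BC": {"Mac": 0.6, "Tc": 0.4},
    "NC": {"NC1": 1.0},
}


def default_lr_pairs() -> LRPairTable:
    """Small bundled LR resource covering the scavenger receptor family
    (Scarb1, Cd36) plus common cardiac signaling axes."""
    rows = [
        ("Thbs1", "Scarb1", "scavenger"),
        ("Apoe", "Scarb1", "scavenger"),
        ("Thbs1", "Cd36", "scavenger"),
        ("Apoe", "Ldlr", ""),
        ("Dll4", "Notch1", "notch"),
        ("Jag1", "Notch1", "notch"),
        ("Vegfa", "Kdr", "vegf"),
        ("Vegfa", "Flt1", "vegf"),
        ("Pdgfb", "Pdgfrb", ""),
        ("Tgfb1", "Tgfbr2", ""),
        ("Igf1", "Igf1r", ""),
        ("Fn1", "Itgb1", ""),
    ]
    return LRPairTable(
        [LRPair(l, r, f or None) for l, r, f in rows], source_name="bundled-lr-pairs"
    )


@dataclass(frozen=True)
class PlantedProgram:
    """One planted LR expression program.

    The ligand gene's mean is multiplied by ``fold_elevation[tp]`` in
    the ligand cell type (crude level), and the receptor gene's mean
    likewise in the receptor cell type.  Folds must be >= 1; timepoints
    absent from the mapping default to fold 1.
    """

    ligand_gene: str
    receptor_gene: str
    ligand_cell_type: str
    receptor_cell_type: str
    fold_elevation: Mapping[str, float] = field(default_factory=dict)

    @property
    def pair_label(self) -> str:
        return f"{self.ligand_gene}-{self.receptor_gene}"

    def fold_at(self, timepoint: str) -> float:
        return float(self.fold_elevation.get(timepoint, 1.0))


@dataclass
class SynthConfig:
    """Full description of a synthetic dataset; deterministic given ``seed``."""

    seed: int = 0
    # when set, count sampling uses this seed while the per-gene structure
    # (baselines, type factors) stays tied to `seed`; lets Monte-Carlo
    # replicates vary sampling noise under one fixed expression program
    sampling_seed: int | None = None
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    type_proportions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROPORTIONS.items()}
    )
    subtypes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUBTYPES.items()}
    )
    n_cells_per_timepoint: int = 2000
    n_genes: int = 200
    baseline_log_mean: float = np.log(0.5)
    # spreads chosen so a planted 8-fold program (log advantage ~4.16 on
    # the score product) stays identifiable: competitor log-product
    # differences have sd 2*sqrt(sigma_b^2 + sigma_t^2) ~= 1.34, a ~3 sigma
    # margin per competing pair
    baseline_log_sigma: float = 0.6
    type_factor_sigma: float = 0.3
    dispersion: float = 0.5
    planted_programs: tuple[PlantedProgram, ...] = ()
    pairs: LRPairTable = field(default_factory=default_lr_pairs)
    exact_proportions: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_timepoint < 1:
            raise ConfigError("n_genes and n_cells_per_timepoint must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for tp in self.timepoints:
            if tp not in self.type_proportions:
                raise ConfigError(f"no cell-type proportions for timepoint {tp!r}")
            props = self.type_proportions[tp]
            if set(props) != set(self.subtypes):
                raise ConfigError(f"proportions at {tp!r} do not cover all cell types")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ConfigError(f"proportions at {tp!r} do not sum to 1")
        names = set(self.gene_names())
        for prog in self.planted_programs:
            for g in (prog.ligand_gene, prog.receptor_gene):
                if g not in names:
                    raise ConfigError(f"planted gene {g!r} not among generated genes")
            for t in (prog.ligand_cell_type, prog.receptor_cell_type):
                if t not in self.subtypes:
                    raise ConfigError(f"planted cell type {t!r} unknown")
            for tp, fold in prog.fold_elevation.items():
                if fold < 1:
                    raise ConfigError("fold_elevation must be >= 1")
                if tp not in self.timepoints:
                    raise ConfigError(f"fold_elevation references unknown timepoint {tp!r}")

    @property
    def crude_types(self) -> list[str]:
        return sorted(self.subtypes)

    def gene_names(self) -> list[str]:
        """LR-resource genes first (pair order), filler genes after."""
        names: list[str] = []
        for p in self.pairs:
            for g in (p.ligand, p.receptor):
                if g not in names:
                    names.append(g)
        if len(names) > self.n_genes:
            raise ConfigError("n_genes too small to hold all LR-resource genes")
        names += [f"Gene{i:04d}" for i in range(len(names), self.n_genes)]
        return names


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The study-design defaults with one planted FB->EC program:
    Thbs1 -> Scarb1 elevated 8-fold at 12 weeks only."""
    planted = (
        PlantedProgram(
            ligand_gene="Thbs1",
            receptor_gene="Scarb1",
            ligand_cell_type="FB",
            receptor_cell_type="EC",
            fold_elevation={"12w": 8.0},
        ),
    )
    return SynthConfig(seed=seed, planted_programs=planted, **overrides)


@dataclass
class GroundTruth:
    """Planted pair identities, analytic score rankings, per-cell labels."""

    planted: list[PlantedProgram]
    expected_rank: dict[str, dict[str, int]]  # pair label -> timepoint -> 1-based rank
    cell_labels: pd.DataFrame
    pairs: LRPairTable

    def to_json(self) -> str:
        payload = {
            "planted": [
                {
                    "ligand_gene": p.ligand_gene,
                    "receptor_gene": p.receptor_gene,
                    "ligand_cell_type": p.ligand_cell_type,
                    "receptor_cell_type": p.receptor_cell_type,
                    "fold_elevation": dict(p.fold_elevation),
                }
                for p in self.planted
            ],
            "expected_rank": self.expected_rank,
            "n_cells": int(len(self.cell_labels)),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _structure(config: SynthConfig, ss: np.random.SeedSequence):
    """Per-gene baselines and per-(gene, crude type) factors, drawn once."""
    rng = np.random.default_rng(ss)
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, config.n_genes)
    factors = rng.lognormal(
        0.0, config.type_factor_sigma, size=(config.n_genes, len(config.crude_types))
    )
    return baseline, factors


def _expected_means(config: SynthConfig, timepoint: str) -> np.ndarray:
    """Analytic E[count] per (gene, crude type) at one timepoint."""
    ss = np.random.SeedSequence(config.seed)
    structure_ss = ss.spawn(1)[0]
    baseline, factors = _structure(config, structure_ss)
    gene_idx = {g: i for i, g in enumerate(config.gene_names())}
    type_idx = {t: j for j, t in enumerate(config.crude_types)}
    means = baseline[:, None] * factors
    means = means.copy()
    for prog in config.planted_programs:
        fold = prog.fold_at(timepoint)
        if fold != 1.0:
            means[gene_idx[prog.ligand_gene], type_idx[prog.ligand_cell_type]] *= fold
            means[gene_idx[prog.receptor_gene], type_idx[prog.receptor_cell_type]] *= fold
    return means


def _largest_remainder(n: int, probs: np.ndarray) -> np.ndarray:
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, GroundTruth]:
    """Sample a complete dataset: counts, annotations, ground truth.

    Deterministic given ``config.seed``; each timepoint uses its own
    spawned random stream.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.timepoints))
    if config.sampling_seed is None:
        tp_streams = children[1:]
    else:
        tp_streams = np.random.SeedSequence(config.sampling_seed).spawn(
            len(config.timepoints)
        )
    genes = config.gene_names()
    gene_idx = {g: i for i, g in enumerate(genes)}
    crude_types = config.crude_types
    type_idx = {t: j for j, t in enumerate(crude_types)}
    baseline, factors = _structure(config, children[0])

    phi = config.dispersion
    shape = 1.0 / phi

    blocks: list[np.ndarray] = []
    ann_records: list[tuple[str, str, str, str]] = []
    for tp, child in zip(config.timepoints, tp_streams):
        rng = np.random.default_rng(child)
        probs = np.array([config.type_proportions[tp][t] for t in crude_types])
        if config.exact_proportions:
            n_per_type = _largest_remainder(config.n_cells_per_timepoint, probs)
        else:
            n_per_type = rng.multinomial(config.n_cells_per_timepoint, probs)
        for t, n_t in zip(crude_types, n_per_type):
            if n_t == 0:
                continue
            sub_labels = sorted(config.subtypes[t])
            weights = np.array([config.subtypes[t][s] for s in sub_labels], dtype=float)
            weights /= weights.sum()
            if config.exact_proportions:
                n_per_sub = _largest_remainder(int(n_t), weights)
            else:
                n_per_sub = rng.multinomial(int(n_t), weights)
            mean_t = baseline * factors[:, type_idx[t]]
            for prog in config.planted_programs:
                fold = prog.fold_at(tp)
                if fold == 1.0:
                    continue
                if prog.ligand_cell_type == t:
                    mean_t = mean_t.copy()
                    mean_t[gene_idx[prog.ligand_gene]] *= fold
                if prog.receptor_cell_type == t:
                    mean_t = mean_t.copy()
                    mean_t[gene_idx[prog.receptor_gene]] *= fold
            for s, n_s in zip(sub_labels, n_per_sub):
                if n_s == 0:
                    continue
                lam = rng.gamma(shape, mean_t * phi, size=(int(n_s), config.n_genes))
                counts = rng.poisson(lam)
                blocks.append(counts)
                start = len(ann_records)
                for i in range(int(n_s)):
                    ann_records.append((f"{tp}_C{start + i:05d}", t, s, tp))

    counts = np.vstack(blocks).T  # genes x cells
    barcodes = np.array([r[0] for r in ann_records], dtype=object)
    matrix = ExpressionMatrix(
        sp.csr_matrix(counts), np.array(genes, dtype=object), barcodes
    )
    ann = pd.DataFrame(
        {
            "crude_type": [r[1] for r in ann_records],
            "subtype": [r[2] for r in ann_records],
            "timepoint": [r[3] for r in ann_records],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    annotation = CellAnnotation(ann)
    truth = _ground_truth(config, annotation)
    return matrix, annotation, truth


def expected_scores(
    config: SynthConfig, normalize_scope: str = "per-slice"
) -> dict[str, InteractionTensor]:
    """Analytic expected interaction tensors per timepoint.

    Expected per-(gene, crude type) means are propagated through the
    same slicing / sum-normalization / outer-product arithmetic the
    pipeline applies to sampled data, giving the oracle for recovery
    tests (exact up to the ratio-of-expectations approximation of the
    normalization step).
    """
    out: dict[str, InteractionTensor] = {}
    for tp in config.timepoints:
        means = _expected_means(config, tp)
        expr = GroupExpression(
            values=means,
            gene_names=np.array(config.gene_names(), dtype=object),
            group_labels=np.array(config.crude_types, dtype=object),
            timepoint=tp,
        )
        lig, rec, _ = prepare_lr_expression(expr, config.pairs, normalize_scope)
        out[tp] = interaction_scores(lig, rec, config.pairs)
    return out


def _ground_truth(config: SynthConfig, annotation: CellAnnotation) -> GroundTruth:
    tensors = expected_scores(config)
    expected_rank: dict[str, dict[str, int]] = {}
    for prog in config.planted_programs:
        ranks: dict[str, int] = {}
        for tp, tensor in tensors.items():
            scores = tensor.pair_scores_at(prog.ligand_cell_type, prog.receptor_cell_type)
            order = scores.sort_values(ascending=False, kind="mergesort")
            ranks[tp] = int(order.index.get_loc(prog.pair_label)) + 1
        expected_rank[prog.pair_label] = ranks
    return GroundTruth(
        planted=list(config.planted_programs),
        expected_rank=expected_rank,
        cell_labels=annotation.table.copy(),
        pairs=config.pairs,
    )


def write_dataset(
    config: SynthConfig, out_dir: str | Path
) -> tuple[ExpressionMatrix, CellAnnotation, GroundTruth]:
    """Generate and write the on-disk fixture set.

    Emits ``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``,
    ``annotations.tsv``, ``lr_pairs.tsv``, and ``ground_truth.json``;
    byte-identical across runs with the same config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix, annotation, truth = generate_dataset(config)
    write_count_matrix(
        matrix,
        out_dir / "matrix.mtx",
        out_dir / "genes.tsv",
        out_dir / "barcodes.tsv",
    )
    annotation.write(out_dir / "annotations.tsv")
    config.pairs.write(out_dir / "lr_pairs.tsv")
    (out_dir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return matrix, annotation, truth
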
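"""End-to-end driver: read -> filter -> aggregate -> normalize -> score -> export.

One call reproduces the full interaction workflow on any conforming
dataset (matrix triple + annotation TSV + LR pair TSV): subtype-level
means are cell-count-weight averaged to crude types per timepoint,
sum-normalized, scored as outer products, and summarized.  Outputs are
seven TSV tables plus a JSON run report with input digests, parameters,
dropped genes, stage timings, and an output manifest; all TSV outputs
are deterministic given identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from lrxtalk._errors import ConfigError, DataError, LRxTalkError
from lrxtalk.aggregate import (
    group_cell_counts,
    mean_by_group,
    prepare_lr_expression,
    weighted_mean_over_subtypes,
)
from lrxtalk.interactome import (
    export_circos_edges,
    interaction_scores,
    pair_log_fold_change,
    participation_proportions,
    percent_change,
    top_k_pairs,
    total_interaction_matrix,
)
from lrxtalk.lr_resource import load_lr_pairs, restrict_to_family
from lrxtalk.sc_io import filter_cells_genes, read_cell_annotations, read_count_matrix

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "totals.tsv",
    "proportions.tsv",
    "top_pairs.tsv",
    "percent_change.tsv",
    "log_fold_change.tsv",
    "circos_edges.tsv",
    "family_totals.tsv",
)


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    mtx: str
    genes: str
    barcodes: str
    annotations: str
    pairs: str
    out_dir: str
    ref_timepoint: str = "0w"
    alt_timepoint: str = "12w"
    ligand_type: str = "FB"
    receptor_type: str = "EC"
    k: int = 10
    normalize_scope: str = "per-slice"
    proportion_mode: str = "both-sides"
    pseudocount: float | None = None
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    symbol_case: str = "as-is"

    REQUIRED = ("mtx", "genes", "barcodes", "annotations", "pairs", "out_dir")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat ``key = value`` text config (one pair per line,
        ``#`` comments allowed)."""
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw: dict[str, str] = {}
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            raw[key] = value
        missing = [k for k in cls.REQUIRED if k not in raw]
        if missing:
            raise ConfigError(f"config missing required keys: {', '.join(missing)}")
        kwargs: dict = dict(raw)
        for int_key in ("k", "min_cells_per_gene", "min_genes_per_cell"):
            if int_key in kwargs:
                kwargs[int_key] = int(kwargs[int_key])
        if "pseudocount" in kwargs:
            kwargs["pseudocount"] = (
                None if kwargs["pseudocount"] in ("", "auto") else float(kwargs["pseudocount"])
            )
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    input_digests: dict[str, str]
    parameters: dict
    dropped_genes: dict[str, list[str]]
    timings: dict[str, float]
    manifest: dict[str, str]
    out_dir: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_digests": self.input_digests,
                "parameters": self.parameters,
                "dropped_genes": self.dropped_genes,
                "timings_seconds": self.timings,
                "manifest": self.manifest,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self) -> Path:
        path = Path(self.out_dir) / "run_report.json"
        path.write_text(self.to_json() + "\n")
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Stage:
    """Attach the failing stage's name to propagated errors."""

    def __init__(self, name: str, timings: dict[str, float]):
        self.name = name
        self.timings = timings

    def __enter__(self):
        self._t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.timings[self.name] = round(time.perf_counter() - self._t0, 6)
        if exc is not None and isinstance(exc, LRxTalkError) and not getattr(
            exc, "_stage_tagged", False
        ):
            exc.args = (f"[{self.name}] {exc.args[0] if exc.args else ''}",)
            exc._stage_tagged = True
        return False


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full interaction workflow and write all outputs.

    Aggregation is subtype-level means recombined by cell-count
    weighting (identical to direct crude-level means); scoring and
    summaries run at crude-type level.  Deterministic given inputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    dropped: dict[str, list[str]] = {}

    with _Stage("load_lr_pairs", timings):
        pairs = load_lr_pairs(config.pairs, symbol_case=config.symbol_case)

    with _Stage("read_counts", timings):
        matrix = read_count_matrix(config.mtx, config.genes, config.barcodes)
        annotation = read_cell_annotations(config.annotations, matrix)

    with _Stage("filter", timings):
        matrix, annotation = filter_cells_genes(
            matrix,
            annotation,
            min_cells_per_gene=config.min_cells_per_gene,
            min_genes_per_cell=config.min_genes_per_cell,
        )
        dropped["lr_genes_absent_after_filter"] = pairs.missing_genes(matrix.gene_names)

    timepoints = annotation.timepoints
    for tp in (config.ref_timepoint, config.alt_timepoint):
        if tp not in timepoints:
            raise DataError(f"[aggregate] timepoint {tp!r} absent from annotation")

    tensors = {}
    summaries = {}
    with _Stage("aggregate_and_score", timings):
        for tp in timepoints:
            sub_expr = mean_by_group(matrix, annotation, level="subtype", timepoint=tp)
            counts = group_cell_counts(annotation, "subtype", tp)
            crude_expr = weighted_mean_over_subtypes(
                sub_expr, counts, annotation.subtype_to_crude()
            )
            lig, rec, missing = prepare_lr_expression(
                crude_expr, pairs, normalize_scope=config.normalize_scope
            )
            dropped.setdefault("lr_genes_zero_filled", sorted(set(missing)))
            tensors[tp] = interaction_scores(lig, rec, pairs)
            summaries[tp] = total_interaction_matrix(tensors[tp])

    with _Stage("summaries", timings):
        totals_rows = []
        for tp in timepoints:
            df = summaries[tp].to_frame()
            for lt in df.index:
                for rt in df.columns:
                    totals_rows.append((tp, lt, rt, df.loc[lt, rt]))
        totals = pd.DataFrame(
            totals_rows, columns=["timepoint", "ligand_type", "receptor_type", "total"]
        )
        totals.to_csv(out_dir / "totals.tsv", sep="\t", index=False, float_format="%.10g")

        prop_rows = []
        for tp in timepoints:
            props = participation_proportions(summaries[tp], mode=config.proportion_mode)
            for ct, v in props.items():
                prop_rows.append((tp, ct, v))
        pd.DataFrame(prop_rows, columns=["timepoint", "cell_type", "proportion"]).to_csv(
            out_dir / "proportions.tsv", sep="\t", index=False, float_format="%.10g"
        )

        top_rows = []
        for tp in timepoints:
            top = top_k_pairs(tensors[tp], config.ligand_type, config.receptor_type, config.k)
            top.insert(0, "timepoint", tp)
            top_rows.append(top)
        pd.concat(top_rows, ignore_index=True).to_csv(
            out_dir / "top_pairs.tsv", sep="\t", index=False, float_format="%.10g"
        )

        pc_rows = []
        for tp in timepoints:
            if tp == config.ref_timepoint:
                continue
            pc = percent_change(
                summaries[tp],
                summaries[config.ref_timepoint],
                config.ligand_type,
                config.receptor_type,
            )
            pc_rows.append((tp, config.ref_timepoint, config.ligand_type, config.receptor_type, pc))
        pd.DataFrame(
            pc_rows,
            columns=["timepoint", "reference", "ligand_type", "receptor_type", "percent_change"],
        ).to_csv(out_dir / "percent_change.tsv", sep="\t", index=False, float_format="%.10g")

        lfc = pair_log_fold_change(
            tensors[config.alt_timepoint],
            tensors[config.ref_timepoint],
            config.ligand_type,
            config.receptor_type,
            pseudocount=config.pseudocount,
        )
        lfc_df = lfc.rename_axis("pair").reset_index()
        lfc_df.insert(0, "reference", config.ref_timepoint)
        lfc_df.insert(0, "timepoint", config.alt_timepoint)
        lfc_df.to_csv(
            out_dir / "log_fold_change.tsv", sep="\t", index=False, float_format="%.10g"
        )

        export_circos_edges(
            summaries[config.alt_timepoint], out_dir / "circos_edges.tsv"
        )

        families = sorted({p.family for p in pairs if p.family})
        fam_rows = []
        for fam in families:
            fam_receptors = {p.receptor for p in pairs if p.family == fam}
            fam_table = restrict_to_family(pairs, fam_receptors)
            for tp in timepoints:
                fam_summary = total_interaction_matrix(tensors[tp].restrict_pairs(fam_table))
                df = fam_summary.to_frame()
                for lt in df.index:
                    for rt in df.columns:
                        fam_rows.append((fam, tp, lt, rt, df.loc[lt, rt]))
        pd.DataFrame(
            fam_rows,
            columns=["family", "timepoint", "ligand_type", "receptor_type", "total"],
        ).to_csv(out_dir / "family_totals.tsv", sep="\t", index=False, float_format="%.10g")

    with _Stage("report", timings):
        manifest = {name: _sha256(out_dir / name) for name in OUTPUT_FILES}
        report = RunReport(
            input_digests={
                name: _sha256(Path(getattr(config, name)))
                for name in ("mtx", "genes", "barcodes", "annotations", "pairs")
            },
            parameters={
                "ref_timepoint": config.ref_timepoint,
                "alt_timepoint": config.alt_timepoint,
                "ligand_type": config.ligand_type,
                "receptor_type": config.receptor_type,
                "k": config.k,
                "normalize_scope": config.normalize_scope,
                "proportion_mode": config.proportion_mode,
                "pseudocount": config.pseudocount,
                "min_cells_per_gene": config.min_cells_per_gene,
                "min_genes_per_cell": config.min_genes_per_cell,
                "symbol_case": config.symbol_case,
            },
            dropped_genes=dropped,
            timings=timings,
            manifest=manifest,
            out_dir=str(out_dir),
        )
    report.write()
    return report
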
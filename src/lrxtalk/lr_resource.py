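"""Ligand-receptor pair resource: loading, validation, and family subsetting.

An LR pair is an *ordered* gene pair: the first gene encodes the ligand,
the second its receptor.  Direction is ligand-expressing cell type ->
receptor-expressing cell type and is never swapped.  Published resources
are typically human; a title-case conversion is provided to map human
symbols (THBS1) onto the mouse convention (Thbs1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from lrxtalk._errors import DataError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("ligand", "receptor")


@dataclass(frozen=True)
class LRPair:
    """One directed ligand -> receptor gene pair."""

    ligand: str
    receptor: str
    family: str | None = None

    @property
    def label(self) -> str:
        return f"{self.ligand}-{self.receptor}"


@dataclass
class LRPairTable:
    """Ordered, deduplicated collection of ligand -> receptor pairs.

    Parameters
    ----------
    pairs
        Pairs in load order; duplicates (same ligand and receptor) must
        already be collapsed.
    source_name
        Free-text provenance label for run reports.
    """

    pairs: list[LRPair]
    source_name: str = "unnamed"

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for p in self.pairs:
            if not p.ligand or not p.receptor:
                raise DataError("ligand and receptor symbols must be non-empty")
            key = (p.ligand, p.receptor)
            if key in seen:
                raise DataError(f"duplicate pair {key} in LRPairTable")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def ligands(self) -> list[str]:
        return [p.ligand for p in self.pairs]

    @property
    def receptors(self) -> list[str]:
        return [p.receptor for p in self.pairs]

    def genes(self) -> set[str]:
        """All gene symbols appearing on either side."""
        return set(self.ligands) | set(self.receptors)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": self.ligands,
                "receptor": self.receptors,
                "family": [p.family if p.family is not None else "" for p in self.pairs],
            }
        )

    def write(self, path: str | Path) -> None:
        """Write the table back as TSV in the same dialect it is read from."""
        self.to_frame().to_csv(path, sep="\t", index=False)

    def missing_genes(self, available: Iterable[str]) -> list[str]:
        """Genes referenced by pairs but absent from ``available``, sorted.

        Missing genes contribute zero expression downstream; surfacing them
        makes an incomplete human->mouse symbol mapping visible.
        """
        avail = set(available)
        missing = sorted(g for g in self.genes() if g not in avail)
        if missing:
            logger.warning(
                "%d LR gene(s) absent from expression data: %s",
                len(missing),
                ", ".join(missing),
            )
        return missing


def _title_case(symbol: str) -> str:
    """Human ALL-CAPS symbol -> mouse Title-case (THBS1 -> Thbs1)."""
    return symbol[:1].upper() + symbol[1:].lower()


def load_lr_pairs(
    path: str | Path,
    symbol_case: str = "as-is",
) -> LRPairTable:
    """Load a ligand-receptor pair table from TSV.

    The file must have a header row with columns ``ligand`` and
    ``receptor``; a ``family`` column is optional.  Rows with a missing
    ligand or receptor are dropped (count logged); duplicate
    (ligand, receptor) rows are collapsed keeping the first occurrence so
    no pair is double-counted in score sums.

    Parameters
    ----------
    path
        TSV file, UTF-8, header row.
    symbol_case
        ``"as-is"`` keeps symbols verbatim; ``"mouse-title-case"``
        converts each symbol to Title-case (first letter upper, rest
        lower), the usual way human LR resources are mapped onto mouse
        gene symbols.

    Raises
    ------
    DataError
        Missing file, missing required columns, or an empty table after
        filtering.
    """
    if symbol_case not in ("as-is", "mouse-title-case"):
        raise DataError(f"unknown symbol_case {symbol_case!r}")
    path = Path(path)
    if not path.exists():
        raise DataError(f"LR pair file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"missing required columns: {', '.join(missing_cols)}")

    has_family = "family" in df.columns
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    for row in df.itertuples(index=False):
        lig = str(getattr(row, "ligand")).strip()
        rec = str(getattr(row, "receptor")).strip()
        if not lig or not rec or lig.lower() == "nan" or rec.lower() == "nan":
            n_dropped += 1
            continue
        if symbol_case == "mouse-title-case":
            lig, rec = _title_case(lig), _title_case(rec)
        key = (lig, rec)
        if key in seen:
            continue
        seen.add(key)
        fam = str(getattr(row, "family")).strip() if has_family else ""
        pairs.append(LRPair(lig, rec, fam or None))
    if n_dropped:
        logger.warning("dropped %d row(s) with missing ligand or receptor", n_dropped)
    if not pairs:
        raise DataError(f"no valid LR pairs in {path}")
    return LRPairTable(pairs=pairs, source_name=path.name)


def restrict_to_family(table: LRPairTable, receptor_genes: set[str]) -> LRPairTable:
    """Sub-table of pairs whose receptor belongs to ``receptor_genes``.

    Used to total interactions over a receptor family (e.g. the scavenger
    receptors Scarb1/Cd36).  Pair order is preserved; an empty result is
    allowed and logged.
    """
    if not receptor_genes:
        raise DataError("receptor_genes must be non-empty")
    kept = [p for p in table.pairs if p.receptor in receptor_genes]
    if not kept:
        logger.warning(
            "family restriction %s matched no pairs in %s",
            sorted(receptor_genes),
            table.source_name,
        )
    return LRPairTable(pairs=kept, source_name=table.source_name)
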
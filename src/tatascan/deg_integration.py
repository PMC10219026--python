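"""Domestic-vs-wild differential-expression tables and hub-gene concordance.

Ingests per-gene DEG tables (which species pair, which tissue, which gene,
and whether the gene is up- or down-regulated in the domestic animal),
maps animal DEGs to human hub genes through a homology table, and counts,
per disease process, how many mapped DEGs change expression in a direction
whose human health effect is 'worsen' versus 'relief'.  Up-in-domestic is
the reference direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .phylostratigraphy import GeneAnnotation
from .selection_stats import CountSplit
from .snp_comparator import PROCESSES

logger = logging.getLogger(__name__)

UP = "up_in_domestic"
DOWN = "down_in_domestic"


@dataclass(frozen=True)
class DegRecord:
    domestic: str
    wild: str
    tissue: str
    gene: str
    direction: str
    ref: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise ValueError(f"direction must be {UP!r} or {DOWN!r}")
        if self.domestic == self.wild:
            raise ValueError("domestic and wild taxa must differ")


def load_deg_tables(
    paths: Sequence[str | Path],
) -> tuple[list[DegRecord], pd.DataFrame]:
    """Load per-gene DEG TSVs (``domestic wild tissue gene direction ref``).

    Duplicated (comparison, gene) rows are dropped with a warning.  Returns
    the records plus per-comparison N_DEG counts computed from the rows.
    """
    records: list[DegRecord] = []
    seen: set[tuple] = set()
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        required = {"domestic", "wild", "tissue", "gene", "direction"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: DEG TSV must have columns {sorted(required)}")
        for row in df.itertuples(index=False):
            key = (row.domestic, row.wild, row.tissue, row.gene)
            if key in seen:
                logger.warning("duplicate DEG row %s; dropped", key)
                continue
            seen.add(key)
            records.append(
                DegRecord(
                    domestic=row.domestic,
                    wild=row.wild,
                    tissue=row.tissue,
                    gene=row.gene,
                    direction=row.direction,
                    ref=getattr(row, "ref", "") or "",
                )
            )
    counts = per_comparison_counts(records)
    return records, counts


def per_comparison_counts(records: Sequence[DegRecord]) -> pd.DataFrame:
    """N_DEG per (domestic, wild, tissue) comparison."""
    if not records:
        return pd.DataFrame(columns=["domestic", "wild", "tissue", "n_deg"])
    df = pd.DataFrame([r.__dict__ for r in records])
    return (
        df.groupby(["domestic", "wild", "tissue"], sort=False)
        .size()
        .rename("n_deg")
        .reset_index()
    )


def load_comparison_counts(path: str | Path) -> pd.DataFrame:
    """Load a pre-aggregated comparison-count table
    (``domestic wild tissue n_deg ref``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "n_deg" not in df.columns:
        raise ValueError("count table must have an n_deg column")
    return df


def domestic_wild_comparison_table() -> pd.DataFrame:
    """The published 18-comparison count table shipped with the package."""
    path = resources.files("tatascan").joinpath("data", "domestic_wild_comparisons.tsv")
    return load_comparison_counts(str(path))


def load_homology(path: str | Path) -> dict[str, str]:
    """Animal-gene -> human-gene map (TSV ``animal_gene  human_gene``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return dict(zip(df["animal_gene"], df["human_gene"]))


@dataclass
class ConcordanceReport:
    counts: dict[str, CountSplit]
    n_mapped: int
    n_unmapped: int
    n_unannotated: int


def concordance_counts(
    degs: Sequence[DegRecord],
    homology: Mapping[str, str],
    annotations: Mapping[str, GeneAnnotation],
    *,
    per_occurrence: bool = True,
) -> ConcordanceReport:
    """Classify each mapped DEG by the health effect of the same-direction
    expression change of its human homolog; count worsen vs relief per
    process.

    With ``per_occurrence`` (default) a hub gene matched in several
    species/tissue comparisons counts once per occurrence; otherwise once
    per (human gene, direction).
    """
    counts = {p: [0, 0] for p in PROCESSES}  # [worsen, relief]
    n_mapped = n_unmapped = n_unannotated = 0
    seen_unique: set[tuple[str, str]] = set()
    for rec in degs:
        human = homology.get(rec.gene)
        if human is None:
            n_unmapped += 1
            continue
        ann = annotations.get(human)
        if ann is None:
            n_unannotated += 1
            continue
        if not per_occurrence:
            key = (human, rec.direction)
            if key in seen_unique:
                continue
            seen_unique.add(key)
        n_mapped += 1
        effect_map = ann.effect_over if rec.direction == UP else ann.effect_under
        for p in PROCESSES:
            effect = effect_map.get(p)
            if effect == "worsen":
                counts[p][0] += 1
            elif effect == "relief":
                counts[p][1] += 1
    return ConcordanceReport(
        counts={
            p: CountSplit(label=p, k_a=w, k_b=r) for p, (w, r) in counts.items()
        },
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        n_unannotated=n_unannotated,
    )
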
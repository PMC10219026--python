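"""Gene-age (phylostratigraphic) scale, gene-set partitioning and summaries.

Houses the 29-rank phylostratigraphic age index (PAI) scale — the rank of
the most recent common ancestor in whose genome a gene's sequence is still
detectable — the Venn partition of the three process gene sets, and
per-region PAI summaries.  PAI values are inputs (computed upstream by
BLAST-based orthology tools), never derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from . import selection_stats as stats
from .snp_comparator import PROCESSES

#: BLAST-based molecular-evolution rank scale, rank 0 (oldest) .. 28 (youngest)
PAI_SCALE: tuple[str, ...] = (
    "Cellular organisms", "Eukaryota", "Opisthokonta", "Metazoa", "Eumetazoa",
    "Bilateria", "Deuterostomia", "Chordata", "Craniata", "Vertebrata",
    "Gnathostomata", "Teleostomi", "Euteleostomi", "Sarcopterygii",
    "Dipnotetrapodomorpha", "Tetrapoda", "Amniota", "Mammalia", "Theria",
    "Eutheria", "Euarchontoglires", "Primates", "Haplorrhini", "Simiiformes",
    "Catarrhini", "Hominoidea", "Hominidae", "Homininae", "Homo",
)

assert len(PAI_SCALE) == 29 and len(set(PAI_SCALE)) == 29

#: Venn region keys, by process-membership signature
REGIONS = ("A_only", "B_only", "C_only", "AB", "AC", "BC", "ABC")

EFFECT_CODES = {"W": "worsen", "R": "relief", "-": None}
_CODE_OF = {v: k for k, v in EFFECT_CODES.items()}


@dataclass(frozen=True)
class GeneAnnotation:
    """Process membership, PAI rank and per-process health-effect maps.

    ``effect_under``/``effect_over`` map each process to the health effect
    ('worsen' or 'relief') of the gene's under-/over-expression.
    """

    gene_symbol: str
    membership: frozenset[str]
    pai: Optional[int] = None
    effect_under: Mapping[str, str] = field(default_factory=dict)
    effect_over: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.membership:
            raise ValueError(f"{self.gene_symbol}: membership must be non-empty")
        unknown = set(self.membership) - set(PROCESSES)
        if unknown:
            raise ValueError(f"{self.gene_symbol}: unknown processes {sorted(unknown)}")
        if self.pai is not None and not 0 <= self.pai < len(PAI_SCALE):
            raise ValueError(f"{self.gene_symbol}: PAI {self.pai} outside the scale")


def _effects_to_code(effects: Mapping[str, str]) -> str:
    return "".join(_CODE_OF.get(effects.get(p), "-") for p in PROCESSES)


def _code_to_effects(code: str) -> dict[str, str]:
    return {
        p: EFFECT_CODES[c]
        for p, c in zip(PROCESSES, code)
        if EFFECT_CODES.get(c) is not None
    }


def read_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Read the annotation TSV: ``gene  atherogenesis  atherosclerosis
    atheroprotection  pai  effect_under  effect_over``.

    Membership columns are 0/1; effect columns are three-letter codes over
    {W, R, -} in process order (e.g. ``RRR`` = relief for all three).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    out = {}
    for row in df.itertuples(index=False):
        membership = frozenset(p for p in PROCESSES if int(getattr(row, p)) == 1)
        pai = None if row.pai in ("", "NA", None) or pd.isna(row.pai) else int(row.pai)
        out[row.gene] = GeneAnnotation(
            gene_symbol=row.gene,
            membership=membership,
            pai=pai,
            effect_under=_code_to_effects(str(row.effect_under)),
            effect_over=_code_to_effects(str(row.effect_over)),
        )
    return out


def write_annotations(annotations: Mapping[str, GeneAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations.values():
        rows.append(
            {
                "gene": ann.gene_symbol,
                **{p: int(p in ann.membership) for p in PROCESSES},
                "pai": "" if ann.pai is None else ann.pai,
                "effect_under": _effects_to_code(ann.effect_under),
                "effect_over": _effects_to_code(ann.effect_over),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def venn_partition(
    genes_a: Iterable[str], genes_b: Iterable[str], genes_c: Iterable[str]
) -> dict[str, frozenset[str]]:
    """Partition three gene sets into the 7 disjoint Venn regions.

    Regions are keyed A_only, B_only, C_only, AB, AC, BC, ABC; they are
    pairwise disjoint and their union is the union of the inputs.
    """
    a, b, c = set(genes_a), set(genes_b), set(genes_c)
    regions = {
        "ABC": a & b & c,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "A_only": a - b - c,
        "B_only": b - a - c,
        "C_only": c - a - b,
    }
    out = {k: frozenset(regions[k]) for k in REGIONS}
    # partition invariants, cheap enough to assert on every call
    union = frozenset().union(*out.values())
    assert union == a | b | c
    assert sum(len(v) for v in out.values()) == len(union)
    return out


def annotations_to_sets(
    annotations: Mapping[str, GeneAnnotation]
) -> tuple[set[str], set[str], set[str]]:
    """The three process gene sets implied by an annotation table."""
    sets: tuple[set[str], ...] = (set(), set(), set())
    for ann in annotations.values():
        for i, p in enumerate(PROCESSES):
            if p in ann.membership:
                sets[i].add(ann.gene_symbol)
    return sets


@dataclass(frozen=True)
class RegionSummary:
    mean_pai: float
    sem_pai: float
    n: int
    n_missing: int


def region_pai_summary(
    region_genes: Iterable[str], annotations: Mapping[str, GeneAnnotation]
) -> RegionSummary:
    """Mean +/- SEM of the PAI over a region's genes; genes with no PAI are
    counted and excluded from the summary."""
    genes = sorted(region_genes)
    if not genes:
        raise ValueError("empty region")
    values = [
        annotations[g].pai for g in genes if g in annotations and annotations[g].pai is not None
    ]
    n_missing = len(genes) - len(values)
    if not values:
        raise ValueError("all PAIs missing in region")
    mean, sem = stats.mean_sem(values)
    return RegionSummary(mean_pai=mean, sem_pai=sem, n=len(values), n_missing=n_missing)


def compare_regions(
    region_x: Iterable[str],
    region_y: Iterable[str],
    annotations: Mapping[str, GeneAnnotation],
    *,
    alternative: str = "two-sided",
) -> dict[str, stats.TestResult]:
    """Compare two regions' PAI distributions: nonparametric Mann-Whitney U
    and the parametric z on means with SEMs, both reported with method tags."""
    x = [annotations[g].pai for g in sorted(region_x)
         if g in annotations and annotations[g].pai is not None]
    y = [annotations[g].pai for g in sorted(region_y)
         if g in annotations and annotations[g].pai is not None]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both regions need at least 2 annotated genes")
    mx, sx = stats.mean_sem(x)
    my, sy = stats.mean_sem(y)
    out = {"mannwhitney": stats.mannwhitney_u(x, y, alternative=alternative)}
    if sx > 0 and sy > 0:
        out["mean_z"] = stats.mean_z_test(mx, sx, my, sy)
    else:
        out["mean_z"] = stats.TestResult(
            statistic=0.0, p_raw=1.0, m=1, method="mean-z/degenerate"
        )
    return out
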
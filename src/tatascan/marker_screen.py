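"""Per-gene SNP screening over promoters and marker tallies.

Runs one allele comparison per (promoter transcript, SNP) pair, keeps the
significant comparisons as candidate markers, and tallies direction and
health-effect counts.  The counting unit is the transcript-level
comparison: a SNP falling in the promoters of several transcripts of its
gene contributes one comparison per transcript.  A unique-rsID tally is
emitted alongside, since both readings of "how many markers" are of
interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .selection_stats import CountSplit
from .sequence_io import PromoterSequence, SequenceError, SnpVariant, apply_variant
from .snp_comparator import (
    DEFICIENCY,
    EXCESS,
    NONSIGNIFICANT,
    PROCESSES,
    CandidateMarker,
    annotate_health,
    fisher_z_compare,
)
from .tbp_affinity import ModelCoefficients, TataPwm, estimate_affinity

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    markers: list[CandidateMarker]
    n_comparisons: int
    n_skipped: int
    comparison_log: list[dict] = field(default_factory=list)

    @property
    def n_unique_rsids(self) -> int:
        return len({m.variant.rsid for m in self.markers})


def _resolve(
    snp: SnpVariant, promoters: Sequence[PromoterSequence]
) -> list[PromoterSequence]:
    """Promoters a SNP applies to: its transcript if named, else every
    transcript of its gene, else (single-promoter runs only) that promoter."""
    if snp.transcript_id:
        return [p for p in promoters if p.transcript_id == snp.transcript_id]
    if snp.gene_symbol:
        return [p for p in promoters if p.gene_symbol == snp.gene_symbol]
    if len(promoters) == 1:
        return list(promoters)
    return []


def screen(
    promoters: Sequence[PromoterSequence],
    snps: Sequence[SnpVariant],
    pwm: Optional[TataPwm] = None,
    coef: Optional[ModelCoefficients] = None,
    alpha: float = 0.05,
    *,
    annotations: Optional[Mapping[str, "GeneAnnotation"]] = None,  # noqa: F821
    strict: bool = False,
    bonferroni_alpha: bool = False,
    keep_log: bool = False,
) -> ScreenResult:
    """Scan all SNPs over all resolvable promoters.

    Per comparison: the ancestral estimate (cached per promoter), the
    minor-allele estimate after substitution, and the Fisher Z test at
    ``alpha`` (optionally Bonferroni-corrected across the number of
    comparisons when ``bonferroni_alpha`` is set — a sensitivity mode; the
    default applies the raw per-SNP alpha, with multiplicity handled in the
    downstream summaries).  Unresolvable SNPs and reference mismatches are
    skipped with a warning, or raised in strict mode.
    """
    pairs: list[tuple[PromoterSequence, SnpVariant]] = []
    n_skipped = 0
    for snp in sorted(snps, key=lambda v: (v.rsid, v.position, v.alt)):
        targets = _resolve(snp, promoters)
        if not targets:
            if strict:
                raise SequenceError(f"{snp.rsid}: no promoter resolves this SNP")
            logger.warning("%s: no promoter resolves this SNP; skipped", snp.rsid)
            n_skipped += 1
            continue
        for p in targets:
            try:
                p.tss_to_index(snp.position)
                ok = p.base_at(snp.position) == snp.ref
            except SequenceError:
                ok = False
            if not ok:
                if strict:
                    raise SequenceError(
                        f"{snp.rsid}: not applicable to {p.transcript_id}"
                    )
                logger.warning("%s: not applicable to %s; skipped", snp.rsid, p.transcript_id)
                n_skipped += 1
                continue
            pairs.append((p, snp))

    effective_alpha = alpha / len(pairs) if (bonferroni_alpha and pairs) else alpha
    ancestral_cache: dict[str, object] = {}
    markers: list[CandidateMarker] = []
    log: list[dict] = []
    for p, snp in pairs:
        if p.transcript_id not in ancestral_cache:
            ancestral_cache[p.transcript_id] = estimate_affinity(p, pwm, coef)
        est_a = ancestral_cache[p.transcript_id]
        est_b = estimate_affinity(apply_variant(p, snp), pwm, coef)
        cmp = fisher_z_compare(est_a, est_b, alpha=effective_alpha)
        if keep_log:
            log.append(
                {
                    "rsid": snp.rsid,
                    "transcript": p.transcript_id,
                    "gene": p.gene_symbol,
                    "z": cmp.z,
                    "p": cmp.p,
                    "direction": cmp.direction,
                }
            )
        if cmp.direction == NONSIGNIFICANT:
            continue
        marker = CandidateMarker(
            variant=snp,
            gene_symbol=p.gene_symbol,
            transcript_id=p.transcript_id,
            ancestral=est_a,
            minor=est_b,
            comparison=cmp,
        )
        if annotations is not None:
            marker = annotate_health(marker, annotations)
        markers.append(marker)
    return ScreenResult(
        markers=markers,
        n_comparisons=len(pairs),
        n_skipped=n_skipped,
        comparison_log=log,
    )


def tally_directions(markers: Sequence[CandidateMarker]) -> CountSplit:
    """Count transcript-level comparisons by affinity direction:
    k_a = affinity increases (excess), k_b = affinity decreases (deficiency)."""
    k_inc = sum(1 for m in markers if m.comparison.direction == EXCESS)
    k_dec = sum(1 for m in markers if m.comparison.direction == DEFICIENCY)
    return CountSplit(label="affinity_increase_vs_decrease", k_a=k_inc, k_b=k_dec)


def tally_health(markers: Sequence[CandidateMarker]) -> dict[str, CountSplit]:
    """Per-process (worsen, relief) counts; a marker contributes to every
    process for which it has a defined effect."""
    out = {}
    for process in PROCESSES:
        worsen = sum(1 for m in markers if m.health_effects.get(process) == "worsen")
        relief = sum(1 for m in markers if m.health_effects.get(process) == "relief")
        out[process] = CountSplit(label=process, k_a=worsen, k_b=relief)
    return out


def screen_summary(result: ScreenResult) -> dict:
    """Per-gene totals in the layout of the per-stage summary table."""
    per_gene: dict[str, dict] = {}
    for m in result.markers:
        g = per_gene.setdefault(
            m.gene_symbol,
            {"transcripts": set(), "markers": 0, "increase": 0, "decrease": 0},
        )
        g["transcripts"].add(m.transcript_id)
        g["markers"] += 1
        g["increase" if m.comparison.direction == EXCESS else "decrease"] += 1
    split = tally_directions(result.markers)
    return {
        "n_comparisons": result.n_comparisons,
        "n_skipped": result.n_skipped,
        "n_markers_per_transcript": len(result.markers),
        "n_markers_unique_rsid": result.n_unique_rsids,
        "direction_split": {"increase": split.k_a, "decrease": split.k_b},
        "per_gene": {
            g: {**d, "transcripts": sorted(d["transcripts"])}
            for g, d in sorted(per_gene.items())
        },
    }
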
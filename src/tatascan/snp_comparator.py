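"""Allele comparison and expression-effect classification.

Compares the ancestral- and minor-allele affinity estimates of a promoter
SNP with a Fisher Z statistic on the ln(Kd) scale and translates the
outcome into a predicted expression change and its health effects.

Standard errors published on the nM scale are propagated to ln-units by
the delta method, se_ln = SE_nM / Kd_nM.  A significant Kd increase for
the minor allele (affinity deficiency) predicts underexpression of the
downstream gene; a significant decrease (affinity excess) predicts
overexpression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from scipy import stats as sps

from .sequence_io import SnpVariant
from .tbp_affinity import AffinityEstimate

logger = logging.getLogger(__name__)

PROCESSES = ("atherogenesis", "atherosclerosis", "atheroprotection")

DEFICIENCY = "deficiency"
EXCESS = "excess"
NONSIGNIFICANT = "nonsignificant"


@dataclass(frozen=True)
class ComparisonResult:
    z: float
    p: float
    delta_ln_kd: float  # ln(Kd_minor) - ln(Kd_ancestral)
    alpha: float
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if self.p > self.alpha:
            d = NONSIGNIFICANT
        elif self.delta_ln_kd > 0:
            d = DEFICIENCY
        else:
            d = EXCESS
        object.__setattr__(self, "direction", d)


def fisher_z_compare(
    a: AffinityEstimate, b: AffinityEstimate, alpha: float = 0.05
) -> ComparisonResult:
    """Fisher Z comparison of two affinity estimates (a = ancestral allele).

    z = |ln Kd_b - ln Kd_a| / sqrt(se_ln_a^2 + se_ln_b^2), with a two-sided
    normal tail probability.
    """
    for est in (a, b):
        if est.se_ln <= 0 or not math.isfinite(est.minus_ln_kd):
            raise ValueError("estimates must be finite with positive SE")
    delta = a.minus_ln_kd - b.minus_ln_kd  # = ln(Kd_b) - ln(Kd_a)
    z = abs(delta) / math.hypot(a.se_ln, b.se_ln)
    p = max(float(2 * sps.norm.sf(z)), 5e-324)
    return ComparisonResult(z=z, p=p, delta_ln_kd=delta, alpha=alpha)


def compare_kd(
    kd_a_nM: float, se_a_nM: float, kd_b_nM: float, se_b_nM: float, alpha: float = 0.05
) -> ComparisonResult:
    """Fisher Z comparison straight from published Kd +/- SE pairs in nM."""
    return fisher_z_compare(
        AffinityEstimate.from_nM(kd_a_nM, se_a_nM),
        AffinityEstimate.from_nM(kd_b_nM, se_b_nM),
        alpha=alpha,
    )


UNDEREXPRESSION = "underexpression"
OVEREXPRESSION = "overexpression"


def classify_expression(direction: str) -> str:
    """Map an affinity-change direction to the predicted expression call.

    Lower TBP affinity (higher Kd, direction 'deficiency') lowers the
    gene's expression; higher affinity raises it.
    """
    if direction == DEFICIENCY:
        return UNDEREXPRESSION
    if direction == EXCESS:
        return OVEREXPRESSION
    if direction == NONSIGNIFICANT:
        return "none"
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class CandidateMarker:
    """A significant allele comparison joined to gene and health annotation."""

    variant: SnpVariant
    gene_symbol: str
    transcript_id: str
    ancestral: AffinityEstimate
    minor: AffinityEstimate
    comparison: ComparisonResult
    health_effects: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.comparison.direction == NONSIGNIFICANT:
            raise ValueError("only significant comparisons become candidate markers")

    @property
    def expression_call(self) -> str:
        return classify_expression(self.comparison.direction)


def annotate_health(
    marker: CandidateMarker,
    annotations: Mapping[str, "GeneAnnotation"],  # noqa: F821 (phylostratigraphy)
) -> CandidateMarker:
    """Fill the marker's per-process health-effect map from the annotation
    table and its expression call.  An unannotated gene yields a marker with
    empty effects and a logged warning."""
    ann = annotations.get(marker.gene_symbol)
    if ann is None:
        logger.warning(
            "gene %s not in annotation table; marker %s emitted without health effects",
            marker.gene_symbol,
            marker.variant.rsid,
        )
        return replace(marker, health_effects={})
    call = marker.expression_call
    effect_map = ann.effect_under if call == UNDEREXPRESSION else ann.effect_over
    return replace(marker, health_effects=dict(effect_map))
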
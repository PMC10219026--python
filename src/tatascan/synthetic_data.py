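"""Seeded synthetic inputs with known ground truth.

Generates promoter FASTA/metadata, SNP tables, gene annotations and
domestic/wild DEG tables in exactly the formats the pipeline consumes,
with the planted truth recorded alongside, so every stage is testable
without any database access.  One global seed; each sub-generator draws
from its own stream (split by a stable label), so adding a generator does
not perturb existing fixtures.

Defaults emulate the study conditions: a 1067-gene annotation universe
partitioned into the published Venn region sizes, 16 hub genes with
90-nt promoters for ~7 protein-coding transcripts each, ~45 SNPs per
promoter, and a 26-record hub-matched DEG table.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phylostratigraphy import GeneAnnotation, write_annotations
from .sequence_io import PromoterSequence, SnpVariant, write_snps_tsv
from .snp_comparator import PROCESSES
from .tbp_affinity import BASES, ModelCoefficients, TataPwm, default_pwm

#: Ground-truth model coefficients of the simulated world, used by the
#: parameter-recovery experiments: the generator plants PWM-score effects,
#: so the truth model weights the stop (site-recognition) term
#: substantially.  The intercept places a consensus-box promoter near the
#: low-nM Kd range of published TATA-box estimates (~2 nM) and a boxless
#: promoter around tens of nM.
SIM_TRUTH_COEFFICIENTS = ModelCoefficients(
    intercept=16.5,
    w_slide=-1.0,
    w_stop=0.4,
    w_bend=0.15,
    provenance="synthetic-truth",
)

# stable stream labels (never renumber)
_STREAMS = {"promoters": 11, "snps": 22, "annotations": 33, "degs": 44}

#: membership signature per Venn region key
_REGION_MEMBERSHIP = {
    "ABC": ("atherogenesis", "atherosclerosis", "atheroprotection"),
    "AB": ("atherogenesis", "atherosclerosis"),
    "AC": ("atherogenesis", "atheroprotection"),
    "BC": ("atherosclerosis", "atheroprotection"),
    "A_only": ("atherogenesis",),
    "B_only": ("atherosclerosis",),
    "C_only": ("atheroprotection",),
}

#: generation order for annotation genes (hub region first, so hub gene ids
#: are stable regardless of the other region sizes)
_REGION_ORDER = ("ABC", "AB", "AC", "BC", "A_only", "B_only", "C_only")

DEFAULT_REGION_SIZES = {
    "ABC": 16, "AB": 106, "AC": 0, "BC": 21,
    "A_only": 58, "B_only": 856, "C_only": 10,
}

DEFAULT_PAI_MEANS = {
    "ABC": 4.0, "AB": 6.0, "AC": 8.0, "BC": 8.0,
    "A_only": 10.0, "B_only": 14.0, "C_only": 12.0,
}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic study universe.

    ``tata_strength`` is the fraction of box positions forced to the PWM
    consensus base (1.0 embeds the exact argmax string); ``direction_bias``
    is the fraction of in-box SNPs substituting toward the consensus
    (planted affinity increase) rather than away from it.
    """

    seed: int = 0
    n_genes: int = 1067
    region_sizes: dict = field(default_factory=lambda: dict(DEFAULT_REGION_SIZES))
    pai_region_means: dict = field(default_factory=lambda: dict(DEFAULT_PAI_MEANS))
    pai_sd: float = 3.0
    n_hub_genes: int = 16
    transcripts_per_gene: int = 7
    promoter_length: int = 90
    background: tuple = (0.295, 0.205, 0.205, 0.295)  # A C G T, ~41% GC
    tata_fraction: float = 0.25
    tata_strength: float = 0.8
    snps_per_promoter: int = 45
    in_box_fraction: float = 15 / 90
    direction_bias: float = 0.68
    n_deg_records: int = 26
    deg_concordance: float = 24 / 26

    def __post_init__(self) -> None:
        for name in ("tata_fraction", "tata_strength", "in_box_fraction",
                     "direction_bias", "deg_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise SimConfigError("background composition must sum to 1")
        if set(self.region_sizes) - set(_REGION_MEMBERSHIP):
            raise SimConfigError("unknown Venn region key in region_sizes")
        if sum(self.region_sizes.values()) > self.n_genes:
            raise SimConfigError("region sizes sum to more than n_genes")
        if self.n_hub_genes > self.region_sizes.get("ABC", 0):
            raise SimConfigError("n_hub_genes exceeds the triple-region size")
        if self.snps_per_promoter > self.promoter_length:
            raise SimConfigError("snps_per_promoter exceeds available positions")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _gene_ids(cfg: SimConfig) -> dict[str, list[str]]:
    """Deterministic gene symbols per region, hub region first."""
    out, counter = {}, 0
    for region in _REGION_ORDER:
        size = cfg.region_sizes.get(region, 0)
        out[region] = [f"G{counter + i + 1:04d}" for i in range(size)]
        counter += size
    return out


def gen_promoters(
    cfg: SimConfig, pwm: Optional[TataPwm] = None
) -> tuple[list[PromoterSequence], pd.DataFrame]:
    """Background promoters with PWM-consensus boxes embedded in a seeded
    subset of transcripts; returns the promoters and the truth table
    (transcript, has_box, box_start index, strength, box sequence).

    ``box_start`` records the *operative* site: the highest-affinity window
    under the simulation truth model after embedding.  Strength dropout can
    shift the best alignment a few bases off the nominal embedding offset
    (the consensus is internally repetitive), and planted SNP labels are
    only meaningful at the operative site.
    """
    from .tbp_affinity import best_site

    pwm = pwm or default_pwm()
    if pwm.width > cfg.promoter_length:
        raise SimConfigError("TATA box longer than the promoter")
    rng = cfg.rng("promoters")
    hub_genes = _gene_ids(cfg)["ABC"][: cfg.n_hub_genes]
    promoters, truth = [], []
    consensus_idx = pwm.weights.argmax(axis=1)
    for gene in hub_genes:
        for t in range(cfg.transcripts_per_gene):
            transcript = f"{gene}-T{t + 1:02d}"
            has_box = bool(rng.random() < cfg.tata_fraction)
            box_start, box_seq, promoter = -1, "", None
            for _attempt in range(50):
                seq = rng.choice(list(BASES), size=cfg.promoter_length, p=cfg.background)
                if has_box:
                    embed_at = int(rng.integers(0, cfg.promoter_length - pwm.width + 1))
                    for j in range(pwm.width):
                        if rng.random() < cfg.tata_strength:
                            seq[embed_at + j] = BASES[consensus_idx[j]]
                        # else: keep the background base (strength 0 = no box signal)
                promoter = PromoterSequence(
                    gene_symbol=gene, transcript_id=transcript, sequence="".join(seq)
                )
                if not has_box:
                    break
                # the embedded box must be the unique strong site: its combined
                # site value has to lead every non-overlapping window by a
                # margin, else planted SNP effects are confounded by a
                # competing background site; re-draw if not.
                box_start, _, _ = best_site(promoter, pwm, SIM_TRUTH_COEFFICIENTS)
                box_seq = promoter.sequence[box_start : box_start + pwm.width]
                if _site_prominence(promoter, box_start, pwm) >= _MIN_PROMINENCE:
                    break
            promoters.append(promoter)
            truth.append(
                {
                    "transcript": transcript,
                    "gene": gene,
                    "has_box": has_box,
                    "box_start": box_start,
                    "strength": cfg.tata_strength if has_box else 0.0,
                    "box_seq": box_seq,
                }
            )
    return promoters, pd.DataFrame(truth)


#: minimal lead (in -ln Kd units under the truth model) of the embedded
#: box's combined site value over every non-overlapping window, so the box
#: is unambiguously the operative site of its promoter
_MIN_PROMINENCE = 1.0


def _site_prominence(promoter: PromoterSequence, site: int, pwm: TataPwm) -> float:
    """Combined-value lead of the site window over all non-overlapping
    windows, under the simulation truth model."""
    from .tbp_affinity import window_profiles

    c = SIM_TRUTH_COEFFICIENTS
    scores, bends, valid = window_profiles(promoter, pwm)
    value = np.where(valid, c.w_stop * scores + c.w_bend * bends, -np.inf)
    overlap = np.zeros(len(value), dtype=bool)
    lo, hi = max(0, site - pwm.width + 1), min(len(value), site + pwm.width)
    overlap[lo:hi] = True
    others = value[~overlap]
    return float(value[site] - others.max()) if others.size else np.inf


#: PWM rows are "high-information" (eligible for planted in-box effects)
#: when the score range within the row exceeds this many ln-units; planted
#: substitutions move between the consensus and the worst base so the
#: planted score change is at least this large and its sign unambiguous
_INFORMATIVE_RANGE = 2.0


def gen_snps(
    promoters: Sequence[PromoterSequence],
    truth: pd.DataFrame,
    cfg: SimConfig,
    pwm: Optional[TataPwm] = None,
) -> tuple[list[PromoterSequence], list[SnpVariant], pd.DataFrame]:
    """SNP set with per-SNP expected affinity-change direction labels.

    Each boxed promoter receives at most one planted effect SNP at a
    high-information box position (probability ``min(1, in_box_fraction *
    snps_per_promoter)``, so the configured in-box share is preserved);
    with probability ``direction_bias`` the plant moves toward the
    consensus (ancestral allele set to the row's weakest base, minor
    allele the consensus base: expected ``excess``), otherwise away from
    it (ancestral set to the consensus base, minor the weakest base:
    expected ``deficiency``).  Setting the ancestral allele keeps both
    directions always plantable and the planted score change large and
    sign-unambiguous.  All remaining SNPs are out-of-box background
    substitutions labelled ``neutral``.

    Because planting may rewrite the ancestral base at the planted
    position, the (possibly adjusted) promoters are returned alongside the
    SNPs and the label table.
    """
    pwm = pwm or default_pwm()
    rng = cfg.rng("snps")
    if cfg.snps_per_promoter > cfg.promoter_length:
        raise SimConfigError("snps_per_promoter exceeds available positions")
    info_rows = np.where(np.ptp(pwm.weights, axis=1) >= _INFORMATIVE_RANGE)[0]
    truth_by_t = truth.set_index("transcript").to_dict("index")
    p_plant = min(1.0, cfg.in_box_fraction * cfg.snps_per_promoter)
    out_promoters, snps, labels, counter = [], [], [], 0
    for p in promoters:
        t = truth_by_t[p.transcript_id]
        box_lo = int(t["box_start"]) if t["has_box"] else -1
        seq = p.sequence
        used: set[int] = set()
        n_neutral = cfg.snps_per_promoter

        if t["has_box"] and rng.random() < p_plant:
            j = int(info_rows[rng.integers(0, len(info_rows))])
            i = box_lo + j
            row = pwm.weights[j]
            go_toward = rng.random() < cfg.direction_bias
            if go_toward:
                ref_i, alt_i = int(row.argmin()), int(row.argmax())
                expected = "excess"
            else:
                ref_i, alt_i = int(row.argmax()), int(row.argmin())
                expected = "deficiency"
            seq = seq[:i] + BASES[ref_i] + seq[i + 1 :]
            used.add(i)
            n_neutral -= 1
            counter += 1
            snps.append(
                SnpVariant(
                    rsid=f"rsS{counter:06d}",
                    position=i - p.length,
                    ref=BASES[ref_i],
                    alt=BASES[alt_i],
                    transcript_id=p.transcript_id,
                    gene_symbol=p.gene_symbol,
                )
            )
            labels.append(
                {
                    "rsid": snps[-1].rsid,
                    "transcript": p.transcript_id,
                    "position": snps[-1].position,
                    "ref": snps[-1].ref,
                    "alt": snps[-1].alt,
                    "in_box": True,
                    "expected": expected,
                }
            )

        out_positions = [
            i for i in range(p.length)
            if not (t["has_box"] and box_lo <= i < box_lo + pwm.width)
        ]
        for _ in range(n_neutral):
            pool = [k for k in out_positions if k not in used]
            if not pool:
                pool = [k for k in range(p.length) if k not in used]
                if not pool:
                    raise SimConfigError("SNP density exceeds available positions")
            i = int(pool[rng.integers(0, len(pool))])
            used.add(i)
            ref_i = BASES.index(seq[i])
            alt_i = int(rng.choice([k for k in range(4) if k != ref_i]))
            counter += 1
            snps.append(
                SnpVariant(
                    rsid=f"rsS{counter:06d}",
                    position=i - p.length,
                    ref=BASES[ref_i],
                    alt=BASES[alt_i],
                    transcript_id=p.transcript_id,
                    gene_symbol=p.gene_symbol,
                )
            )
            labels.append(
                {
                    "rsid": snps[-1].rsid,
                    "transcript": p.transcript_id,
                    "position": snps[-1].position,
                    "ref": snps[-1].ref,
                    "alt": snps[-1].alt,
                    "in_box": False,
                    "expected": "neutral",
                }
            )
        out_promoters.append(
            p if seq == p.sequence else dataclasses.replace(p, sequence=seq)
        )
    return out_promoters, snps, pd.DataFrame(labels)


def gen_annotations(cfg: SimConfig) -> dict[str, GeneAnnotation]:
    """Annotation table with the planted Venn region sizes (exact) and
    per-region PAI distributions (clipped normal, exact in expectation)."""
    rng = cfg.rng("annotations")
    out = {}
    for region, genes in _gene_ids(cfg).items():
        mean = cfg.pai_region_means.get(region, 10.0)
        for g in genes:
            pai = int(np.clip(round(rng.normal(mean, cfg.pai_sd)), 0, 28))
            under = {p: ("worsen" if rng.random() < 0.5 else "relief") for p in PROCESSES}
            over = {p: ("relief" if under[p] == "worsen" else "worsen") for p in PROCESSES}
            out[g] = GeneAnnotation(
                gene_symbol=g,
                membership=frozenset(_REGION_MEMBERSHIP[region]),
                pai=pai,
                effect_under=under,
                effect_over=over,
            )
    return out


_DEG_CONTEXTS = [
    ("sim dogs", "sim wolves", "blood"),
    ("sim pigs", "sim boars", "frontal cortex"),
    ("sim rabbits", "sim wild rabbits", "hippocampus"),
    ("sim foxes", "sim wild foxes", "pituitary"),
]


def gen_deg_tables(
    cfg: SimConfig, annotations: dict[str, GeneAnnotation]
) -> tuple[list, dict[str, str], dict[str, GeneAnnotation]]:
    """Hub-matched DEG records realizing the planted concordance rate.

    Exactly ``round(deg_concordance * n)`` records per process are made
    concordant (health effect 'relief' for the homolog's same-direction
    change); the hub genes' effect maps in the returned annotation table
    are rewritten to be consistent with the planting.  Each record gets a
    unique (human gene, direction) pair so the planted effects are
    well-defined.
    """
    from .deg_integration import DOWN, UP, DegRecord

    rng = cfg.rng("degs")
    hub = _gene_ids(cfg)["ABC"][: cfg.n_hub_genes]
    n = cfg.n_deg_records
    if n > 2 * len(hub):
        raise SimConfigError("n_deg_records exceeds 2 x hub genes (one per direction)")
    pairs = [(g, UP) for g in hub] + [(g, DOWN) for g in hub]
    chosen = [pairs[int(k)] for k in rng.choice(len(pairs), size=n, replace=False)]
    k_relief = round(cfg.deg_concordance * n)
    relief_sets = {
        p: set(rng.choice(n, size=k_relief, replace=False).tolist()) for p in PROCESSES
    }
    annotations = dict(annotations)
    planted: dict[str, dict[str, dict[str, str]]] = {}
    records, homology = [], {}
    for idx, (gene, direction) in enumerate(chosen):
        # up- and down-records draw from disjoint context slots so a gene
        # planted in both directions never collides on the dedup key
        # (domestic, wild, tissue, gene)
        ctx = _DEG_CONTEXTS[(idx % 2) + (0 if direction == UP else 2)]
        animal_gene = f"a_{gene}"
        homology[animal_gene] = gene
        records.append(
            DegRecord(
                domestic=ctx[0], wild=ctx[1], tissue=ctx[2],
                gene=animal_gene, direction=direction, ref="sim",
            )
        )
        side = "effect_over" if direction == UP else "effect_under"
        planted.setdefault(gene, {})[side] = {
            p: ("relief" if idx in relief_sets[p] else "worsen") for p in PROCESSES
        }
    for gene, sides in planted.items():
        ann = annotations[gene]
        over = sides.get("effect_over") or {
            p: ("relief" if v == "worsen" else "worsen")
            for p, v in sides["effect_under"].items()
        }
        under = sides.get("effect_under") or {
            p: ("relief" if v == "worsen" else "worsen") for p, v in over.items()
        }
        annotations[gene] = dataclasses.replace(
            ann, effect_under=under, effect_over=over
        )
    return records, homology, annotations


# ---------------------------------------------------------------------------
# File emission


def _write_fasta(promoters: Sequence[PromoterSequence], path: Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(f">{p.transcript_id}\n{p.sequence}\n")


def simulate(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate the full input bundle and write it to ``outdir``.

    Emits promoters.fasta, metadata.tsv, snps.tsv, snp_truth.tsv,
    annotations.tsv, degs.tsv, homology.tsv and manifest.json; byte-identical
    under a fixed seed.  Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    promoters, truth = gen_promoters(cfg)
    promoters, snps, labels = gen_snps(promoters, truth, cfg)
    annotations = gen_annotations(cfg)
    degs, homology, annotations = gen_deg_tables(cfg, annotations)

    _write_fasta(promoters, outdir / "promoters.fasta")
    pd.DataFrame(
        [{"gene": p.gene_symbol, "transcript": p.transcript_id} for p in promoters]
    ).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    write_snps_tsv(snps, outdir / "snps.tsv")
    labels.to_csv(outdir / "snp_truth.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "promoter_truth.tsv", sep="\t", index=False)
    write_annotations(annotations, outdir / "annotations.tsv")
    pd.DataFrame([r.__dict__ for r in degs]).to_csv(
        outdir / "degs.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [{"animal_gene": a, "human_gene": h} for a, h in homology.items()]
    ).to_csv(outdir / "homology.tsv", sep="\t", index=False)

    manifest = {
        "config": {
            k: (dict(v) if isinstance(v, dict) else (list(v) if isinstance(v, tuple) else v))
            for k, v in dataclasses.asdict(cfg).items()
        },
        "seed": cfg.seed,
        "counts": {
            "promoters": len(promoters),
            "snps": len(snps),
            "genes_annotated": len(annotations),
            "deg_records": len(degs),
        },
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(outdir.iterdir())
            if f.name != "manifest.json"
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
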
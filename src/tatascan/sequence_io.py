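"""Promoter and SNP input handling.

Owns all coordinate conventions for TSS-anchored proximal promoters.
The convention throughout the package: the transcription start site is
position +1, the promoter covers positions -L .. -1 immediately upstream
of it, and there is no position 0.  Internally sequences are 0-based,
left to right, 5'->3' on the transcribed strand; position ``pos`` maps to
index ``pos + L``.

Promoters are assumed to be pre-oriented to the transcribed strand, as
promoter sequences extracted from genome annotation databases are; no
reverse-complement scanning is performed anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: bases tolerated under the lenient ambiguity policy (masked out of site
#: search downstream, never scored)
AMBIGUOUS_BASES = frozenset("NRYSWKMBDHV")


class SequenceError(ValueError):
    """Invalid promoter or variant input."""


@dataclass(frozen=True)
class PromoterSequence:
    """A TSS-anchored upstream sequence for one transcript.

    The last base of ``sequence`` sits at position -1; the TSS itself
    (position +1) is not part of the sequence.
    """

    gene_symbol: str
    transcript_id: str
    sequence: str
    allow_ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise SequenceError(f"{self.transcript_id}: empty sequence")
        allowed = VALID_BASES | (AMBIGUOUS_BASES if self.allow_ambiguous else frozenset())
        for i, base in enumerate(seq):
            if base not in allowed:
                raise SequenceError(
                    f"{self.transcript_id}: disallowed base {base!r} at "
                    f"0-based offset {i} (TSS-relative position {i - len(seq)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def tss_to_index(self, position: int) -> int:
        """Map a TSS-relative position in -L..-1 to a 0-based index."""
        if not -self.length <= position <= -1:
            raise SequenceError(
                f"position {position} outside promoter window "
                f"[-{self.length}, -1] of {self.transcript_id}"
            )
        return position + self.length

    def index_to_tss(self, index: int) -> int:
        if not 0 <= index < self.length:
            raise SequenceError(f"index {index} out of range for length {self.length}")
        return index - self.length

    def base_at(self, position: int) -> str:
        return self.sequence[self.tss_to_index(position)]


@dataclass(frozen=True)
class SnpVariant:
    """A single-nucleotide substitution at a TSS-relative position.

    ``transcript_id``/``gene_symbol`` are optional resolution hints used by
    the screening stage; a variant with neither is only applicable when a
    single promoter is in play.
    """

    rsid: str
    position: int
    ref: str
    alt: str
    transcript_id: Optional[str] = None
    gene_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise SequenceError(
                f"{self.rsid}: alleles must be single bases in ACGT "
                f"(got {self.ref!r} -> {self.alt!r})"
            )
        if self.ref == self.alt:
            raise SequenceError(f"{self.rsid}: ref and alt alleles are identical")
        if self.position >= 0:
            raise SequenceError(
                f"{self.rsid}: position must be negative (TSS-relative, no position 0)"
            )

    def swapped(self) -> "SnpVariant":
        """The allele-swapped (inverse) variant."""
        return replace(self, ref=self.alt, alt=self.ref)


def read_promoters(
    fasta_path: str | Path,
    metadata_path: str | Path,
    *,
    expected_length: Optional[int] = None,
    policy: str = "strict",
) -> list[PromoterSequence]:
    """Read promoters from FASTA keyed by transcript id, joined to metadata.

    The metadata TSV must have columns ``gene`` and ``transcript``; every
    FASTA record id must have a metadata row.  ``policy`` is ``strict``
    (reject ambiguity codes) or ``lenient`` (keep them; downstream site
    search masks windows containing them).
    """
    if policy not in ("strict", "lenient"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"gene", "transcript"}
    if not required <= set(meta.columns):
        raise SequenceError(f"metadata must have columns {sorted(required)}")
    by_transcript = meta.set_index("transcript")["gene"].to_dict()

    promoters: list[PromoterSequence] = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in by_transcript:
            raise SequenceError(f"no metadata row for FASTA record {record.id!r}")
        seq = str(record.seq)
        if expected_length is not None and len(seq) != expected_length:
            raise SequenceError(
                f"{record.id}: length {len(seq)} != expected {expected_length}"
            )
        promoters.append(
            PromoterSequence(
                gene_symbol=by_transcript[record.id],
                transcript_id=record.id,
                sequence=seq,
                allow_ambiguous=(policy == "lenient"),
            )
        )
    return promoters


def _read_snps_tsv(table_path: str | Path) -> list[SnpVariant]:
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    required = {"rsid", "position", "ref", "alt"}
    if not required <= set(df.columns):
        raise SequenceError(f"SNP TSV must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SnpVariant(
                rsid=row.rsid,
                position=int(row.position),
                ref=row.ref,
                alt=row.alt,
                transcript_id=getattr(row, "transcript", None),
                gene_symbol=getattr(row, "gene", None),
            )
        )
    return out


def _read_snps_vcf(
    table_path: str | Path,
    promoter_length: int,
    offsets: Optional[dict[str, tuple[str, int]]],
) -> list[SnpVariant]:
    # Minimal SNV-only VCF dialect.  In TSS mode (no offset table) CHROM is
    # the transcript id and POS is the 1-based offset into the promoter
    # (1..L); with an offset table CHROM/POS are genomic and each transcript
    # maps to (chrom, genomic coordinate of the promoter's first base).
    import pysam

    out = []
    with pysam.VariantFile(str(table_path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    raise SequenceError(
                        f"{rec.id or rec.pos}: VCF dialect accepts single-nucleotide "
                        f"REF/ALT only (got {rec.ref!r} -> {alt!r})"
                    )
                if offsets is None:
                    transcript, index = rec.chrom, rec.pos - 1
                else:
                    matches = [
                        (t, rec.pos - start)
                        for t, (chrom, start) in offsets.items()
                        if chrom == rec.chrom and 0 <= rec.pos - start < promoter_length
                    ]
                    if not matches:
                        raise SequenceError(
                            f"{rec.id or rec.pos}: no promoter window covers "
                            f"{rec.chrom}:{rec.pos} in the offset table"
                        )
                    transcript, index = matches[0]
                if not 0 <= index < promoter_length:
                    raise SequenceError(
                        f"{rec.id or rec.pos}: position outside the "
                        f"{promoter_length}-nt promoter window"
                    )
                out.append(
                    SnpVariant(
                        rsid=rec.id or f"{rec.chrom}:{rec.pos}",
                        position=index - promoter_length,
                        ref=rec.ref,
                        alt=alt,
                        transcript_id=transcript,
                    )
                )
    return out


def read_snps(
    table_path: str | Path,
    dialect: str = "tsv",
    *,
    promoters: Optional[Sequence[PromoterSequence]] = None,
    promoter_length: int = 90,
    offsets: Optional[dict[str, tuple[str, int]]] = None,
) -> list[SnpVariant]:
    """Read SNPs from a TSV (``rsid position ref alt [gene] [transcript]``)
    or the minimal SNV-only VCF dialect.

    When ``promoters`` is supplied, every variant carrying a transcript hint
    is validated against its promoter (window bounds and reference base).
    """
    if dialect == "tsv":
        variants = _read_snps_tsv(table_path)
    elif dialect == "vcf":
        variants = _read_snps_vcf(table_path, promoter_length, offsets)
    else:
        raise ValueError(f"unknown SNP dialect {dialect!r}")

    if promoters is not None:
        by_id = {p.transcript_id: p for p in promoters}
        for v in variants:
            if v.transcript_id and v.transcript_id in by_id:
                p = by_id[v.transcript_id]
                if p.base_at(v.position) != v.ref:  # raises if out of window
                    raise SequenceError(
                        f"{v.rsid}: ref allele {v.ref} does not match promoter "
                        f"{p.transcript_id} base {p.base_at(v.position)} at {v.position}"
                    )
    return variants


def apply_variant(promoter: PromoterSequence, variant: SnpVariant) -> PromoterSequence:
    """Apply a substitution, producing the minor-allele promoter.

    The reference base at the variant's position must match ``variant.ref``;
    a mismatch signals stale coordinates or a wrong-strand variant and the
    input is returned unchanged (an exception is raised).
    """
    i = promoter.tss_to_index(variant.position)
    observed = promoter.sequence[i]
    if observed != variant.ref:
        raise SequenceError(
            f"{variant.rsid}: ref mismatch at position {variant.position} of "
            f"{promoter.transcript_id}: promoter has {observed}, variant says {variant.ref}"
        )
    new_seq = promoter.sequence[:i] + variant.alt + promoter.sequence[i + 1 :]
    return replace(promoter, sequence=new_seq)


def write_snps_tsv(variants: Iterable[SnpVariant], path: str | Path) -> None:
    rows = [
        {
            "rsid": v.rsid,
            "gene": v.gene_symbol or "",
            "transcript": v.transcript_id or "",
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
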
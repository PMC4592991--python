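"""Codon mapping and substitution classification for CDS SNPs."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table

from .core import (
    GenomicInterval,
    ReferenceSequence,
    TranscriptModel,
    VariantRecord,
    revcomp,
)

STOP = "*"

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = STOP

STATUS_SYNONYMOUS = "synonymous"
STATUS_NONSYNONYMOUS = "nonsynonymous"
STATUS_NONSENSE = "nonsense"
STATUS_START_LOSS = "start-loss"


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code ('*' for stops)."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"cannot translate ambiguous codon {codon!r}")
    return _CODON_TABLE[codon]


def translate_cds(cds_seq: str) -> str:
    """Translate a spliced CDS (length divisible by 3) into a protein string,
    including any terminal stop as '*'."""
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_seq)} not divisible by 3")
    return "".join(
        translate_codon(cds_seq[i : i + 3]) for i in range(0, len(cds_seq), 3)
    )


@dataclass(frozen=True)
class SubstitutionEffect:
    """Effect of one CDS SNP on its codon and residue."""

    gene_id: str
    transcript_id: str
    chrom: str
    pos: int  # genomic, 0-based
    ref_codon: str
    alt_codon: str
    codon_position: int  # 1..3, position within the codon on the coding strand
    ref_aa: str
    alt_aa: str
    residue_index: int  # 1-based
    status: Optional[str] = None

    @property
    def label(self) -> str:
        """Compact substitution label, e.g. ``T179P``."""
        return f"{self.ref_aa}{self.residue_index}{self.alt_aa}"

    @property
    def codon_label(self) -> str:
        return f"{self.ref_codon}/{self.alt_codon}"


def spliced_cds(model: TranscriptModel, reference: ReferenceSequence) -> str:
    """Concatenate CDS intervals in transcription order (reverse-complemented
    for minus-strand models)."""
    parts = [reference.fetch(iv) for iv in model.cds]
    seq = "".join(parts)
    return seq if model.strand == "+" else revcomp(seq)


def cds_offset_of(model: TranscriptModel, pos: int) -> Optional[int]:
    """0-based offset of a genomic position within the spliced CDS, in
    transcription order; None when the position is not in the CDS."""
    if model.strand == "+":
        offset = 0
        for iv in model.cds:
            if iv.contains(pos):
                return offset + (pos - iv.start)
            offset += len(iv)
        return None
    offset = 0
    for iv in reversed(model.cds):
        if iv.contains(pos):
            return offset + (iv.end - 1 - pos)
        offset += len(iv)
    return None


def genomic_pos_of(model: TranscriptModel, cds_offset: int) -> int:
    """Inverse of :func:`cds_offset_of`."""
    if cds_offset < 0 or cds_offset >= model.cds_length:
        raise IndexError(f"CDS offset {cds_offset} out of range")
    if model.strand == "+":
        remaining = cds_offset
        for iv in model.cds:
            if remaining < len(iv):
                return iv.start + remaining
            remaining -= len(iv)
    else:
        remaining = cds_offset
        for iv in reversed(model.cds):
            if remaining < len(iv):
                return iv.end - 1 - remaining
            remaining -= len(iv)
    raise AssertionError("unreachable")


def map_to_codon(
    variant: VariantRecord,
    model: TranscriptModel,
    reference: ReferenceSequence,
) -> SubstitutionEffect:
    """Map a CDS SNP to its ref/alt codon and residue index.

    Codons are assembled from the spliced CDS, so codons spanning splice
    junctions are handled; minus-strand variants are reverse-complemented
    onto the coding strand.
    """
    if not model.scorable:
        raise ValueError(
            f"transcript {model.transcript_id} is non-scorable "
            f"(CDS length {model.cds_length} not divisible by 3)"
        )
    genome_base = reference.base(variant.chrom, variant.pos)
    if genome_base != variant.ref:
        raise ValueError(
            f"REF mismatch at {variant.chrom}:{variant.pos + 1}: "
            f"variant has {variant.ref}, genome has {genome_base}"
        )
    offset = cds_offset_of(model, variant.pos)
    if offset is None:
        raise ValueError(
            f"variant {variant.chrom}:{variant.pos + 1} is not in the CDS of "
            f"{model.transcript_id}"
        )
    cds_seq = spliced_cds(model, reference)
    codon_index = offset // 3
    within = offset % 3
    ref_codon = cds_seq[codon_index * 3 : codon_index * 3 + 3]
    alt_base = variant.alt if model.strand == "+" else revcomp(variant.alt)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    effect = SubstitutionEffect(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        chrom=variant.chrom,
        pos=variant.pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        codon_position=within + 1,
        ref_aa=translate_codon(ref_codon),
        alt_aa=translate_codon(alt_codon),
        residue_index=codon_index + 1,
    )
    return replace(effect, status=classify_substitution(effect))


def classify_substitution(effect: SubstitutionEffect) -> str:
    """Synonymous / nonsynonymous / nonsense / start-loss."""
    if effect.alt_aa == STOP and effect.ref_aa != STOP:
        return STATUS_NONSENSE
    if effect.residue_index == 1 and effect.ref_aa == "M" and effect.alt_aa != "M":
        return STATUS_START_LOSS
    if effect.ref_aa == effect.alt_aa:
        return STATUS_SYNONYMOUS
    return STATUS_NONSYNONYMOUS


#: statuses grouped under the "nsSNP" heading in category counts
NONSYNONYMOUS_LIKE = frozenset(
    {STATUS_NONSYNONYMOUS, STATUS_NONSENSE, STATUS_START_LOSS}
)


def effects_for_variants(
    variants: Sequence[VariantRecord],
    models: Sequence[TranscriptModel],
    reference: ReferenceSequence,
) -> List[Tuple[VariantRecord, SubstitutionEffect]]:
    """Compute one effect per (variant, representative transcript) pair for
    variants falling inside a scorable CDS."""
    from .genome_io import pick_coding_transcript

    chosen = pick_coding_transcript(models)
    out: List[Tuple[VariantRecord, SubstitutionEffect]] = []
    for variant in variants:
        for model in chosen.values():
            if model.chrom != variant.chrom or not model.scorable:
                continue
            if cds_offset_of(model, variant.pos) is not None:
                out.append((variant, map_to_codon(variant, model, reference)))
    return out
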
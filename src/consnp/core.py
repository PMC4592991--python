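"""Core domain types shared across the pipeline.

All coordinates are 0-based, half-open. The format readers/writers in
:mod:`consnp.genome_io` are the only places where 1-based (VCF, GFF3) or
0-based (BED) external conventions appear.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string."""
    return seq.translate(COMPLEMENT)[::-1]


def from_vcf_pos(pos: int) -> int:
    """Convert a 1-based VCF POS to the internal 0-based coordinate."""
    return pos - 1


def to_vcf_pos(pos: int) -> int:
    """Convert an internal 0-based coordinate to a 1-based VCF POS."""
    return pos + 1


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ReferenceSequence:
    """In-memory reference: chromosome name -> nucleotide string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {c: s.upper() for c, s in sequences.items()}

    @property
    def chroms(self) -> List[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, interval: GenomicInterval) -> str:
        """Return exactly ``end - start`` bases; out-of-range is an error."""
        try:
            seq = self._seqs[interval.chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {interval.chrom!r}") from None
        if interval.end > len(seq):
            raise IndexError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds sequence length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(GenomicInterval(chrom, pos, pos + 1))


GROUP_QQ = "QQ"
GROUP_QQ_LOWER = "qq"
GROUPS = (GROUP_QQ, GROUP_QQ_LOWER)


@dataclass
class SampleManifest:
    """Maps each sample id to its QTL genotype group (``QQ`` or ``qq``)."""

    assignments: Dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.assignments.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        for g in GROUPS:
            if not self.samples_in(g):
                raise ValueError(f"group {g!r} has no samples")

    def samples_in(self, group: str) -> List[str]:
        return [s for s, g in self.assignments.items() if g == group]

    @property
    def samples(self) -> List[str]:
        return list(self.assignments)

    def group_of(self, sample: str) -> str:
        return self.assignments[sample]

    def group_sizes(self) -> Dict[str, int]:
        return {g: len(self.samples_in(g)) for g in GROUPS}

    def other(self, group: str) -> str:
        return GROUP_QQ_LOWER if group == GROUP_QQ else GROUP_QQ


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP with per-sample genotypes.

    ``pos`` is the 0-based coordinate of the substituted base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: Tuple[Tuple[str, Genotype], ...]

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(
                f"non-SNP alleles {self.ref}/{self.alt} at {self.chrom}:{self.pos}"
            )

    @classmethod
    def make(
        cls,
        chrom: str,
        pos: int,
        ref: str,
        alt: str,
        genotypes: Mapping[str, Genotype],
    ) -> "VariantRecord":
        return cls(chrom, pos, ref, alt, tuple(sorted(genotypes.items())))

    @property
    def genotype_map(self) -> Dict[str, Genotype]:
        return dict(self.genotypes)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)

    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class TranscriptModel:
    """Strand-aware gene structure used for classification and codon mapping.

    All interval lists are kept in genomic (left-to-right) order; transcription
    order is derived from ``strand`` where needed.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[GenomicInterval]
    cds: List[GenomicInterval]
    utr5: List[GenomicInterval] = field(default_factory=list)
    utr3: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"overlapping exons in {self.transcript_id}: {a} / {b}"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds)

    @property
    def scorable(self) -> bool:
        """True when the CDS has a length divisible by 3 (codon-mappable)."""
        return bool(self.cds) and self.cds_length % 3 == 0

    def cds_in_transcription_order(self) -> List[GenomicInterval]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def exons_in_transcription_order(self) -> List[GenomicInterval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> List[GenomicInterval]:
        """Genomic-order intervals between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def region_of(self, pos: int) -> Optional[str]:
        """Classify an exonic position as cds/utr5/utr3; None if intronic
        or outside the transcript."""
        for name, ivs in (("cds", self.cds), ("utr5", self.utr5), ("utr3", self.utr3)):
            if any(iv.contains(pos) for iv in ivs):
                return name
        return None


def derive_utrs(
    exons: Iterable[GenomicInterval],
    cds: Iterable[GenomicInterval],
    strand: str,
    chrom: str,
) -> Tuple[List[GenomicInterval], List[GenomicInterval]]:
    """Split exonic-minus-CDS space into 5' and 3' UTR intervals.

    UTR bases left of the CDS span are 5' on the plus strand and 3' on the
    minus strand (and vice versa on the right).
    """
    exons = sorted(exons, key=lambda iv: iv.start)
    cds = sorted(cds, key=lambda iv: iv.start)
    if not cds:
        return [], []
    cds_start, cds_end = cds[0].start, cds[-1].end
    left: List[GenomicInterval] = []
    right: List[GenomicInterval] = []
    for ex in exons:
        if ex.start < cds_start:
            left.append(
                GenomicInterval(chrom, ex.start, min(ex.end, cds_start), strand)
            )
        if ex.end > cds_end:
            right.append(
                GenomicInterval(chrom, max(ex.start, cds_end), ex.end, strand)
            )
    if strand == "+":
        return left, right
    return right, left
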
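"""Functional annotation of SNPs: CDS/UTR/splice by transcript structure,
plus CpG-island and promoter interval overlap.

CpG islands are detected with Gardiner-Garden/Frommer-style criteria when no
precomputed BED is supplied; a supplied BED always wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .core import (
    GenomicInterval,
    ReferenceSequence,
    TranscriptModel,
    VariantRecord,
)

logger = logging.getLogger(__name__)

CATEGORIES = ("CDS", "UTR5", "UTR3", "splice", "CpG", "promoter")

DEFAULT_SPLICE_WINDOW = 2
DEFAULT_PROMOTER_UPSTREAM = 2000
DEFAULT_PROMOTER_DOWNSTREAM = 0


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Functional context of one variant with respect to one gene (or none)."""

    variant: VariantRecord
    gene_id: Optional[str]
    categories: FrozenSet[str]

    def __post_init__(self) -> None:
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")


def _splice_positions(model: TranscriptModel, window: int) -> Set[int]:
    """Intronic positions within ``window`` bases of an exon-intron boundary.

    With the default window of 2 these are exactly the canonical donor and
    acceptor dinucleotide positions. Exonic splice-region bases are excluded.
    """
    out: Set[int] = set()
    for intron in model.introns():
        w = min(window, len(intron))
        out.update(range(intron.start, intron.start + w))
        out.update(range(intron.end - w, intron.end))
    return out


def annotate_variant(
    variant: VariantRecord,
    models: Sequence[TranscriptModel],
    cpg: Sequence[GenomicInterval] = (),
    promoters: Sequence[GenomicInterval] = (),
    promoter_genes: Optional[Sequence[str]] = None,
    splice_window: int = DEFAULT_SPLICE_WINDOW,
) -> List[FunctionalAnnotation]:
    """Assign functional categories to a variant.

    Returns one annotation per overlapping gene (categories from all of that
    gene's transcripts, collapsed), or a single gene-less annotation carrying
    any interval-only categories (CpG, promoter without a known gene) — empty
    for intergenic variants.
    """
    pos = variant.pos
    per_gene: Dict[str, Set[str]] = {}

    for model in models:
        if model.chrom != variant.chrom:
            continue
        cats: Set[str] = set()
        if model.contains(pos):
            region = model.region_of(pos)
            if region == "cds":
                cats.add("CDS")
            elif region == "utr5":
                cats.add("UTR5")
            elif region == "utr3":
                cats.add("UTR3")
            if pos in _splice_positions(model, splice_window):
                cats.add("splice")
        if cats:
            per_gene.setdefault(model.gene_id, set()).update(cats)

    genes_hit: Set[str] = set()
    for i, iv in enumerate(promoters):
        if iv.chrom == variant.chrom and iv.contains(pos):
            gene = promoter_genes[i] if promoter_genes else None
            if gene is not None:
                per_gene.setdefault(gene, set()).add("promoter")
            else:
                genes_hit.add("promoter")

    in_cpg = any(
        iv.chrom == variant.chrom and iv.contains(pos) for iv in cpg
    )
    if in_cpg:
        if per_gene:
            for cats in per_gene.values():
                cats.add("CpG")
        else:
            genes_hit.add("CpG")

    annotations = [
        FunctionalAnnotation(variant, gene, frozenset(cats))
        for gene, cats in sorted(per_gene.items())
    ]
    if not annotations:
        annotations.append(FunctionalAnnotation(variant, None, frozenset(genes_hit)))
    return annotations


def merged_categories(annotations: Iterable[FunctionalAnnotation]) -> FrozenSet[str]:
    """Union of categories across a variant's per-gene annotations."""
    cats: Set[str] = set()
    for ann in annotations:
        cats.update(ann.categories)
    return frozenset(cats)


# ---------------------------------------------------------------------------
# CpG islands

def cpg_obs_exp(seq: str) -> float:
    """Observed/expected CpG ratio: (N_CG * L) / (N_C * N_G)."""
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cg = seq.count("CG")
    return (n_cg * len(seq)) / (n_c * n_g)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def _window_qualifies(seq: str, min_gc: float, min_oe: float) -> bool:
    return gc_fraction(seq) >= min_gc and cpg_obs_exp(seq) >= min_oe


def detect_cpg_islands(
    reference: ReferenceSequence,
    interval: GenomicInterval,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> List[GenomicInterval]:
    """Detect CpG islands inside ``interval``.

    A base belongs to an island when it is covered by at least one window of
    exactly ``min_length`` bases satisfying GC >= ``min_gc`` and CpG
    observed/expected >= ``min_oe``. Maximal runs of such bases are merged
    and re-checked: only runs that themselves satisfy both criteria are
    reported, so every reported island meets all three thresholds.
    Windows containing N are skipped (logged once per call).
    """
    seq = reference.fetch(interval)
    n = len(seq)
    if n < min_length:
        return []

    covered = [False] * n
    # rolling counts over windows of exactly min_length
    n_skipped_n = 0
    window = seq[:min_length]
    n_c = window.count("C")
    n_g = window.count("G")
    n_cg = window.count("CG")
    n_n = window.count("N")
    for start in range(0, n - min_length + 1):
        if start > 0:
            out_ch = seq[start - 1]
            in_ch = seq[start + min_length - 1]
            if out_ch == "C":
                n_c -= 1
            elif out_ch == "G":
                n_g -= 1
            elif out_ch == "N":
                n_n -= 1
            if in_ch == "C":
                n_c += 1
            elif in_ch == "G":
                n_g += 1
            elif in_ch == "N":
                n_n += 1
            # CG dinucleotides lost at the left edge / gained at the right
            if seq[start - 1] == "C" and seq[start] == "G":
                n_cg -= 1
            if seq[start + min_length - 2] == "C" and seq[start + min_length - 1] == "G":
                n_cg += 1
        if n_n > 0:
            n_skipped_n += 1
            continue
        gc = (n_c + n_g) / min_length
        oe = 0.0 if n_c == 0 or n_g == 0 else (n_cg * min_length) / (n_c * n_g)
        if gc >= min_gc and oe >= min_oe:
            for i in range(start, start + min_length):
                covered[i] = True
    if n_skipped_n:
        logger.info("detect_cpg_islands: skipped %d window(s) containing N", n_skipped_n)

    islands: List[GenomicInterval] = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < n and covered[j]:
            j += 1
        run = seq[i:j]
        if _window_qualifies(run, min_gc, min_oe):
            islands.append(
                GenomicInterval(interval.chrom, interval.start + i, interval.start + j)
            )
        else:
            logger.debug(
                "merged CpG run %s:%d-%d fails criteria after merge; dropped",
                interval.chrom,
                interval.start + i,
                interval.start + j,
            )
        i = j
    return islands


# ---------------------------------------------------------------------------
# Promoters

def derive_promoters(
    models: Sequence[TranscriptModel],
    reference: Optional[ReferenceSequence] = None,
    upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    downstream: int = DEFAULT_PROMOTER_DOWNSTREAM,
) -> Tuple[List[GenomicInterval], List[str]]:
    """Strand-aware promoter interval per transcript, clipped at sequence
    bounds; returns parallel lists of intervals and their gene ids."""
    intervals: List[GenomicInterval] = []
    genes: List[str] = []
    for model in models:
        if model.strand == "+":
            start = model.start - upstream
            end = model.start + downstream
        else:
            start = model.end - downstream
            end = model.end + upstream
        start = max(0, start)
        if reference is not None:
            end = min(end, reference.length(model.chrom))
        if start >= end:
            continue
        intervals.append(GenomicInterval(model.chrom, start, end, model.strand))
        genes.append(model.gene_id)
    return intervals, genes
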
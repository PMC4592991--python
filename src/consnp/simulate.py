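"""Self-contained synthetic dataset with planted ground truth.

Generates a reference sequence, realistic gene models (multi-exon CDS with
canonical GT/AG introns), CpG-island and promoter intervals, per-gene
ortholog alignments, and a two-group VCF with planted consensus SNPs in
every functional category plus decoys — everything a full pipeline run
needs, with the truth serialized alongside.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import (
    GROUP_QQ,
    GROUP_QQ_LOWER,
    GROUPS,
    Genotype,
    GenomicInterval,
    ReferenceSequence,
    SampleManifest,
    TranscriptModel,
    VariantRecord,
    revcomp,
)
from .effects import STOP, genomic_pos_of, spliced_cds, translate_codon
from .genome_io import (
    write_bed_intervals,
    write_fasta,
    write_manifest,
    write_vcf,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_CODONS_FOR: Dict[str, List[str]] = {}
for _c in _CODONS:
    _CODONS_FOR.setdefault(translate_codon(_c), []).append(_c)

CATEGORY_NSSNP = "nsSNP"
CATEGORY_SYNONYMOUS = "synonymous"
CATEGORY_UTR = "UTR"
CATEGORY_SPLICE = "splice"
CATEGORY_CPG = "CpG"
CATEGORY_PROMOTER = "promoter"
CATEGORY_INTERGENIC_DECOY = "intergenic-decoy"
CATEGORY_DISCORDANT_DECOY = "discordant-decoy"

#: categories planted with a consensus genotype pattern
CONSENSUS_CATEGORIES = (
    CATEGORY_NSSNP,
    CATEGORY_SYNONYMOUS,
    CATEGORY_UTR,
    CATEGORY_SPLICE,
    CATEGORY_CPG,
    CATEGORY_PROMOTER,
    CATEGORY_INTERGENIC_DECOY,
)


@dataclass
class SimulationConfig:
    """Knobs of the simulator; the defaults echo the study design
    (1.2 Mb interval, 13 genes, two groups of 5 homozygous samples,
    3 QQ + 1 qq nonsynonymous SNPs with one at 4/5 support)."""

    seed: int
    chrom: str = "chr1"
    interval_length: int = 1_200_000
    n_genes: int = 13
    samples_per_group: int = 5
    nssnp_counts: Dict[str, int] = field(
        default_factory=lambda: {GROUP_QQ: 3, GROUP_QQ_LOWER: 1}
    )
    synonymous_counts: Dict[str, int] = field(
        default_factory=lambda: {GROUP_QQ: 1, GROUP_QQ_LOWER: 1}
    )
    utr_counts: Dict[str, int] = field(
        default_factory=lambda: {GROUP_QQ: 4, GROUP_QQ_LOWER: 3}
    )
    splice_counts: Dict[str, int] = field(
        default_factory=lambda: {GROUP_QQ: 1, GROUP_QQ_LOWER: 2}
    )
    cpg_counts: Dict[str, int] = field(
        default_factory=lambda: {GROUP_QQ: 2, GROUP_QQ_LOWER: 2}
    )
    promoter_counts: Dict[str, int] = field(
        default_factory=lambda: {GROUP_QQ: 3, GROUP_QQ_LOWER: 4}
    )
    #: targeted substitutions planted first, counted against nssnp_counts
    target_substitutions: List[Tuple[str, str, str]] = field(
        default_factory=lambda: [
            (GROUP_QQ, "T", "P"),
            (GROUP_QQ, "G", "S"),
            (GROUP_QQ, "F", "I"),
            (GROUP_QQ_LOWER, "A", "G"),
        ]
    )
    partial_support_fraction: float = 0.0
    force_partial_nssnp: bool = True
    n_intergenic_decoys: int = 3
    n_discordant_decoys: int = 5
    n_cpg_islands: int = 4
    cpg_island_length: int = 600
    promoter_upstream: int = 2000
    promoter_downstream: int = 0
    n_alignment_rows: int = 8
    background_conservation: float = 0.8
    gc_content: float = 0.40

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in (
            "nssnp_counts",
            "synonymous_counts",
            "utr_counts",
            "splice_counts",
            "cpg_counts",
            "promoter_counts",
        ):
            counts = getattr(self, name)
            if any(v < 0 for v in counts.values()):
                raise ValueError(f"negative count in {name}")
        targets_per_group = {g: 0 for g in GROUPS}
        for group, _, _ in self.target_substitutions:
            targets_per_group[group] += 1
        for g in GROUPS:
            if targets_per_group[g] > self.nssnp_counts.get(g, 0):
                raise ValueError(
                    f"{targets_per_group[g]} target substitution(s) for group {g} "
                    f"exceed nssnp_counts[{g}]"
                )


@dataclass
class GroundTruthEntry:
    """Truth for one planted SNP."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    category: str
    group: Optional[str]
    support: int
    group_size: int
    gene_id: Optional[str] = None
    transcript_id: Optional[str] = None
    residue_index: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    conservation: Optional[float] = None


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    reference: ReferenceSequence
    models: List[TranscriptModel]
    manifest: SampleManifest
    records: List[VariantRecord]
    truth: List[GroundTruthEntry]
    cpg_islands: List[GenomicInterval]
    promoters: List[GenomicInterval]
    promoter_genes: List[str]
    alignments: Dict[str, Dict[str, str]]
    paths: Dict[str, str] = field(default_factory=dict)

    def truth_by_key(self) -> Dict[Tuple[str, int, str, str], GroundTruthEntry]:
        return {(e.chrom, e.pos, e.ref, e.alt): e for e in self.truth}

    def consensus_truth(self) -> List[GroundTruthEntry]:
        return [e for e in self.truth if e.category in CONSENSUS_CATEGORIES]


# ---------------------------------------------------------------------------
# gene construction helpers

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(AA20), size=length - 1))
    return "M" + body


def _protein_to_cds(rng: np.random.Generator, protein: str) -> str:
    codons = [str(rng.choice(_CODONS_FOR[aa])) for aa in protein]
    codons.append(str(rng.choice(_CODONS_FOR[STOP])))
    return "".join(codons)


def _tx_to_genomic(
    exons_g: Sequence[GenomicInterval],
    exon_tx_spans: Sequence[Tuple[int, int]],
    strand: str,
    chrom: str,
    tx_lo: int,
    tx_hi: int,
) -> List[GenomicInterval]:
    """Map a transcript-coordinate span onto genomic sub-intervals of the
    exons (exons given in transcription order with their tx spans)."""
    out: List[GenomicInterval] = []
    for ex, (t0, t1) in zip(exons_g, exon_tx_spans):
        a = max(tx_lo, t0)
        b = min(tx_hi, t1)
        if a >= b:
            continue
        if strand == "+":
            out.append(GenomicInterval(chrom, ex.start + (a - t0), ex.start + (b - t0), strand))
        else:
            out.append(GenomicInterval(chrom, ex.end - (b - t0), ex.end - (a - t0), strand))
    return sorted(out, key=lambda iv: iv.start)


def _build_gene(
    rng: np.random.Generator,
    chrom: str,
    gene_id: str,
    gene_start: int,
    strand: str,
) -> Tuple[TranscriptModel, str, int, str]:
    """Construct one multi-exon gene; returns (model, genomic gene sequence,
    genomic span length, protein)."""
    protein_len = int(rng.integers(80, 200))
    protein = _random_protein(rng, protein_len)
    cds_seq = _protein_to_cds(rng, protein)
    utr5_len = int(rng.integers(100, 300))
    utr3_len = int(rng.integers(100, 300))
    tx_seq = _random_seq(rng, utr5_len, 0.4) + cds_seq + _random_seq(rng, utr3_len, 0.4)
    tx_len = len(tx_seq)

    n_exons = int(rng.integers(2, 5))
    # exon cut points, each exon >= 30 bases
    while True:
        cuts = sorted(int(x) for x in rng.integers(30, tx_len - 30, size=n_exons - 1))
        bounds = [0] + cuts + [tx_len]
        if all(b - a >= 30 for a, b in zip(bounds, bounds[1:])):
            break
    exon_tx_spans = list(zip(bounds, bounds[1:]))
    intron_seqs = [
        "GT" + _random_seq(rng, int(rng.integers(150, 1200)) - 4, 0.35) + "AG"
        for _ in range(n_exons - 1)
    ]

    # assemble the genomic sequence in transcription order, then orient
    pieces: List[str] = []
    for i, (a, b) in enumerate(exon_tx_spans):
        pieces.append(tx_seq[a:b])
        if i < len(intron_seqs):
            pieces.append(intron_seqs[i])
    sense_seq = "".join(pieces)
    gene_seq = sense_seq if strand == "+" else revcomp(sense_seq)
    span = len(gene_seq)

    # genomic exon intervals, in transcription order
    exons_g: List[GenomicInterval] = []
    if strand == "+":
        cursor = gene_start
        for i, (a, b) in enumerate(exon_tx_spans):
            exons_g.append(GenomicInterval(chrom, cursor, cursor + (b - a), strand))
            cursor += b - a
            if i < len(intron_seqs):
                cursor += len(intron_seqs[i])
    else:
        cursor = gene_start + span
        for i, (a, b) in enumerate(exon_tx_spans):
            exons_g.append(GenomicInterval(chrom, cursor - (b - a), cursor, strand))
            cursor -= b - a
            if i < len(intron_seqs):
                cursor -= len(intron_seqs[i])

    cds_lo, cds_hi = utr5_len, utr5_len + len(cds_seq)
    cds_g = _tx_to_genomic(exons_g, exon_tx_spans, strand, chrom, cds_lo, cds_hi)
    utr5_g = _tx_to_genomic(exons_g, exon_tx_spans, strand, chrom, 0, utr5_len)
    utr3_g = _tx_to_genomic(exons_g, exon_tx_spans, strand, chrom, cds_hi, tx_len)

    model = TranscriptModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=sorted(exons_g, key=lambda iv: iv.start),
        cds=cds_g,
        utr5=utr5_g,
        utr3=utr3_g,
    )
    return model, gene_seq, span, protein


# ---------------------------------------------------------------------------
# coding SNP planting

def _single_base_variants(codon: str) -> List[Tuple[int, str, str]]:
    """(position, alt_base, mutated_codon) for all 9 single-base changes."""
    out = []
    for i in range(3):
        for b in "ACGT":
            if b != codon[i]:
                out.append((i, b, codon[:i] + b + codon[i + 1 :]))
    return out


def substitution_realizable(ref_aa: str, alt_aa: str) -> bool:
    """True when some codon of ``ref_aa`` reaches ``alt_aa`` by one base."""
    for codon in _CODONS_FOR[ref_aa]:
        for _, _, mut in _single_base_variants(codon):
            if translate_codon(mut) == alt_aa:
                return True
    return False


def plant_coding_snp(
    model: TranscriptModel,
    reference: ReferenceSequence,
    ref_aa: str,
    alt_aa: str,
    rng: Optional[np.random.Generator] = None,
    exclude_residues: Optional[Set[int]] = None,
) -> Tuple[str, int, str, str, int, str, str]:
    """Find a single-base change in the model's CDS producing the requested
    amino-acid substitution.

    Returns ``(chrom, genomic_pos, ref_base, alt_base, residue_index,
    ref_codon, alt_codon)``. Raises when the substitution cannot be made by
    any single-base change (naming the pair), or when this CDS offers no
    usable codon.
    """
    from .effects import genomic_pos_of, spliced_cds

    if not substitution_realizable(ref_aa, alt_aa):
        raise ValueError(
            f"substitution {ref_aa}->{alt_aa} is not realizable by a "
            "single-base change in any codon"
        )
    cds_seq = spliced_cds(model, reference)
    candidates: List[Tuple[int, int, str, str]] = []  # (codon_idx, within, alt, alt_codon)
    for ci in range(len(cds_seq) // 3):
        if exclude_residues and (ci + 1) in exclude_residues:
            continue
        codon = cds_seq[ci * 3 : ci * 3 + 3]
        if translate_codon(codon) != ref_aa:
            continue
        for within, alt, mut in _single_base_variants(codon):
            if translate_codon(mut) == alt_aa:
                candidates.append((ci, within, alt, mut))
    if not candidates:
        raise ValueError(
            f"no codon in {model.transcript_id} supports {ref_aa}->{alt_aa}"
        )
    idx = int(rng.integers(len(candidates))) if rng is not None else 0
    ci, within, alt_coding, alt_codon = candidates[idx]
    offset = ci * 3 + within
    pos = genomic_pos_of(model, offset)
    ref_base = reference.base(model.chrom, pos)
    alt_base = alt_coding if model.strand == "+" else revcomp(alt_coding)
    ref_codon = cds_seq[ci * 3 : ci * 3 + 3]
    return (model.chrom, pos, ref_base, alt_base, ci + 1, ref_codon, alt_codon)


# ---------------------------------------------------------------------------
# the simulator

def _genotype_pattern(
    rng: np.random.Generator,
    manifest: SampleManifest,
    group: Optional[str],
    support: int,
    kind: str = "consensus",
) -> Dict[str, Genotype]:
    """Build a genotype map. ``consensus``: ``support`` hom-alt carriers in
    ``group``, none in the other. ``both-groups``: hom-alt everywhere."""
    gts = {s: Genotype.HOM_REF for s in manifest.samples}
    if kind == "both-groups":
        return {s: Genotype.HOM_ALT for s in manifest.samples}
    members = manifest.samples_in(group)
    carriers = list(rng.choice(members, size=support, replace=False))
    for s in carriers:
        gts[s] = Genotype.HOM_ALT
    return gts


def simulate_dataset(
    config: SimulationConfig,
    out_dir: Optional[Path] = None,
) -> SimulatedDataset:
    """Generate the full synthetic dataset; deterministic for a fixed seed.

    When ``out_dir`` is given, writes reference.fasta, genes.gff3,
    cpg_islands.bed, promoters.bed, variants.vcf, manifest.tsv,
    alignments/<gene>.afa and ground_truth.json.
    """
    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    n = config.samples_per_group
    manifest = SampleManifest(
        {
            **{f"QQ_{i + 1}": GROUP_QQ for i in range(n)},
            **{f"qq_{i + 1}": GROUP_QQ_LOWER for i in range(n)},
        }
    )

    genome = bytearray(
        _random_seq(rng, config.interval_length, config.gc_content).encode()
    )

    # --- genes, one per slot
    slot = config.interval_length // config.n_genes
    models: List[TranscriptModel] = []
    proteins: Dict[str, str] = {}
    for gi in range(config.n_genes):
        gene_id = f"gene_{gi + 1:02d}"
        strand = "+" if gi % 2 == 0 else "-"
        gene_start = gi * slot + max(slot // 8, config.promoter_upstream + 100)
        model, gene_seq, span, protein = _build_gene(
            rng, chrom, gene_id, gene_start, strand
        )
        island_anchor = gi * slot + slot // 2
        if gene_start + span + config.promoter_upstream >= island_anchor:
            raise ValueError(
                f"gene {gene_id} does not fit its slot; increase "
                "interval_length or decrease n_genes"
            )
        genome[gene_start : gene_start + span] = gene_seq.encode()
        models.append(model)
        proteins[gene_id] = protein

    # --- CpG islands in intergenic space (middle of every other slot)
    if config.n_cpg_islands > config.n_genes:
        raise ValueError("n_cpg_islands cannot exceed n_genes (one per slot)")
    islands: List[GenomicInterval] = []
    for k in range(config.n_cpg_islands):
        gi = k * max(1, config.n_genes // max(config.n_cpg_islands, 1))
        gi = min(gi, config.n_genes - 1)
        start = gi * slot + slot // 2
        length = config.cpg_island_length
        # GC-rich with abundant CpG dinucleotides: alternating CG core with
        # random GC-heavy filler keeps GC>=0.5 and obs/exp>=0.6
        core = []
        while len(core) < length:
            core.append("CG" if rng.random() < 0.5 else str(rng.choice(list("GCAT"), p=[0.3, 0.3, 0.2, 0.2])))
        island_seq = "".join(core)[:length]
        genome[start : start + length] = island_seq.encode()
        islands.append(GenomicInterval(chrom, start, start + length))

    reference = ReferenceSequence({chrom: genome.decode()})

    # --- promoters (truth intervals; pipeline may also re-derive them)
    from .annotate import derive_promoters

    promoters, promoter_genes = derive_promoters(
        models,
        reference,
        upstream=config.promoter_upstream,
        downstream=config.promoter_downstream,
    )

    # --- candidate position pools per category
    used: Set[int] = set()

    def take(pool: List[int], count: int, label: str) -> List[int]:
        pool = [p for p in pool if p not in used]
        if len(pool) < count:
            raise ValueError(
                f"cannot plant {count} {label} SNP(s): only {len(pool)} "
                "candidate positions available"
            )
        chosen = [int(p) for p in rng.choice(pool, size=count, replace=False)]
        used.update(chosen)
        return chosen

    utr_pool: List[int] = []
    splice_pool: List[int] = []
    for m in models:
        for iv in m.utr5 + m.utr3:
            utr_pool.extend(range(iv.start, iv.end))
        for intron in m.introns():
            splice_pool.extend(
                (intron.start, intron.start + 1, intron.end - 2, intron.end - 1)
            )
    cpg_pool: List[int] = []
    for iv in islands:
        cpg_pool.extend(range(iv.start + 5, iv.end - 5))
    promoter_pool: List[int] = []
    for iv in promoters:
        promoter_pool.extend(range(iv.start + 5, iv.end - 5))
    intergenic_pool: List[int] = []
    for gi in range(config.n_genes):
        lo = gi * slot + (5 * slot) // 8
        hi = gi * slot + (7 * slot) // 8
        intergenic_pool.extend(range(lo, hi))
    # keep intergenic decoys clear of planted islands
    island_cover = set()
    for iv in islands:
        island_cover.update(range(iv.start - 5, iv.end + 5))
    intergenic_pool = [p for p in intergenic_pool if p not in island_cover]

    truth: List[GroundTruthEntry] = []
    records: List[VariantRecord] = []

    def support_for(category: str, forced_partial: bool) -> int:
        if forced_partial:
            return n - 1
        if rng.random() < config.partial_support_fraction:
            return n - 1
        return n

    def add_snp(
        pos: int,
        alt: str,
        category: str,
        group: Optional[str],
        support: int,
        kind: str = "consensus",
        **extra,
    ) -> None:
        ref = reference.base(chrom, pos)
        if alt == ref:
            raise AssertionError("planted alt equals ref")
        gts = _genotype_pattern(rng, manifest, group, support, kind)
        records.append(VariantRecord.make(chrom, pos, ref, alt, gts))
        truth.append(
            GroundTruthEntry(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                category=category,
                group=group,
                support=support if kind != "both-groups" else 2 * n,
                group_size=n,
                **extra,
            )
        )

    def random_alt(ref: str) -> str:
        return str(rng.choice([b for b in "ACGT" if b != ref]))

    # --- coding SNPs (targets first, then random fill)
    coding_genes = list(models)
    gene_cursor = 0
    planted_residues: Dict[str, Set[int]] = {m.gene_id: set() for m in models}
    forced_partial_pending = config.force_partial_nssnp

    def next_gene() -> TranscriptModel:
        nonlocal gene_cursor
        m = coding_genes[gene_cursor % len(coding_genes)]
        gene_cursor += 1
        return m

    targets_by_group: Dict[str, List[Tuple[str, str]]] = {g: [] for g in GROUPS}
    for group, ra, aa in config.target_substitutions:
        targets_by_group[group].append((ra, aa))

    for group in GROUPS:
        count = config.nssnp_counts.get(group, 0)
        targets = list(targets_by_group[group])
        for i in range(count):
            model = None
            placed = None
            if targets:
                ra, aa = targets.pop(0)
                for _ in range(len(coding_genes)):
                    m = next_gene()
                    try:
                        placed = plant_coding_snp(
                            m, reference, ra, aa, rng,
                            exclude_residues=planted_residues[m.gene_id],
                        )
                        model = m
                        break
                    except ValueError:
                        continue
                if placed is None:
                    raise ValueError(
                        f"no gene supports target substitution {ra}->{aa}"
                    )
            else:
                # random nonsynonymous substitution
                for _ in range(200):
                    m = next_gene()
                    cds_len = m.cds_length // 3
                    ci = int(rng.integers(1, cds_len - 1))
                    if (ci + 1) in planted_residues[m.gene_id]:
                        continue
                    cds_seq = spliced_cds(m, reference)
                    codon = cds_seq[ci * 3 : ci * 3 + 3]
                    muts = [
                        (w, b, mc)
                        for (w, b, mc) in _single_base_variants(codon)
                        if translate_codon(mc) not in (translate_codon(codon), STOP)
                    ]
                    if not muts:
                        continue
                    w, b, mc = muts[int(rng.integers(len(muts)))]
                    pos = genomic_pos_of(m, ci * 3 + w)
                    alt_base = b if m.strand == "+" else revcomp(b)
                    placed = (
                        m.chrom, pos, reference.base(chrom, pos), alt_base,
                        ci + 1, codon, mc,
                    )
                    model = m
                    break
                if placed is None:
                    raise ValueError("failed to place a random nonsynonymous SNP")
            _, pos, ref_b, alt_b, residue, ref_codon, alt_codon = placed
            if pos in used:
                raise ValueError("planted SNP position collision")
            used.add(pos)
            planted_residues[model.gene_id].add(residue)
            forced = forced_partial_pending and group == GROUP_QQ
            support = support_for(CATEGORY_NSSNP, forced)
            if forced:
                forced_partial_pending = False
            add_snp(
                pos,
                alt_b,
                CATEGORY_NSSNP,
                group,
                support,
                gene_id=model.gene_id,
                transcript_id=model.transcript_id,
                residue_index=residue,
                ref_codon=ref_codon,
                alt_codon=alt_codon,
                ref_aa=translate_codon(ref_codon),
                alt_aa=translate_codon(alt_codon),
                conservation=1.0,
            )

    # --- synonymous coding SNPs
    for group in GROUPS:
        for _ in range(config.synonymous_counts.get(group, 0)):
            placed = None
            for _ in range(500):
                m = next_gene()
                cds_seq = spliced_cds(m, reference)
                ci = int(rng.integers(1, len(cds_seq) // 3 - 1))
                if (ci + 1) in planted_residues[m.gene_id]:
                    continue
                codon = cds_seq[ci * 3 : ci * 3 + 3]
                muts = [
                    (w, b, mc)
                    for (w, b, mc) in _single_base_variants(codon)
                    if translate_codon(mc) == translate_codon(codon)
                ]
                if not muts:
                    continue
                w, b, mc = muts[int(rng.integers(len(muts)))]
                pos = genomic_pos_of(m, ci * 3 + w)
                if pos in used:
                    continue
                alt_base = b if m.strand == "+" else revcomp(b)
                placed = (m, pos, alt_base, ci + 1, codon, mc)
                break
            if placed is None:
                raise ValueError("failed to place a synonymous SNP")
            m, pos, alt_base, residue, codon, mc = placed
            used.add(pos)
            planted_residues[m.gene_id].add(residue)
            add_snp(
                pos,
                alt_base,
                CATEGORY_SYNONYMOUS,
                group,
                support_for(CATEGORY_SYNONYMOUS, False),
                gene_id=m.gene_id,
                transcript_id=m.transcript_id,
                residue_index=residue,
                ref_codon=codon,
                alt_codon=mc,
                ref_aa=translate_codon(codon),
                alt_aa=translate_codon(mc),
            )

    # --- non-coding categories
    def gene_for(pos: int) -> Optional[str]:
        for m in models:
            if m.contains(pos):
                return m.gene_id
        return None

    for group in GROUPS:
        for pos in take(utr_pool, config.utr_counts.get(group, 0), "UTR"):
            add_snp(
                pos, random_alt(reference.base(chrom, pos)), CATEGORY_UTR, group,
                support_for(CATEGORY_UTR, False), gene_id=gene_for(pos),
            )
        for pos in take(splice_pool, config.splice_counts.get(group, 0), "splice"):
            add_snp(
                pos, random_alt(reference.base(chrom, pos)), CATEGORY_SPLICE, group,
                support_for(CATEGORY_SPLICE, False), gene_id=gene_for(pos),
            )
        for pos in take(cpg_pool, config.cpg_counts.get(group, 0), "CpG"):
            add_snp(
                pos, random_alt(reference.base(chrom, pos)), CATEGORY_CPG, group,
                support_for(CATEGORY_CPG, False),
            )
        for pos in take(promoter_pool, config.promoter_counts.get(group, 0), "promoter"):
            add_snp(
                pos, random_alt(reference.base(chrom, pos)), CATEGORY_PROMOTER, group,
                support_for(CATEGORY_PROMOTER, False),
            )

    # --- decoys
    for i in range(config.n_intergenic_decoys):
        group = GROUPS[i % 2]
        for pos in take(intergenic_pool, 1, "intergenic decoy"):
            add_snp(
                pos, random_alt(reference.base(chrom, pos)),
                CATEGORY_INTERGENIC_DECOY, group,
                support_for(CATEGORY_INTERGENIC_DECOY, False),
            )
    for i in range(config.n_discordant_decoys):
        for pos in take(intergenic_pool, 1, "discordant decoy"):
            ref = reference.base(chrom, pos)
            alt = random_alt(ref)
            if i % 2 == 0:
                # present in both groups: fails absence in both directions
                add_snp(pos, alt, CATEGORY_DISCORDANT_DECOY, None, 0, kind="both-groups")
            else:
                # support n-2 in one group: fails presence
                group = GROUPS[i % 2]
                add_snp(
                    pos, alt, CATEGORY_DISCORDANT_DECOY, group, max(n - 2, 0)
                )

    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    truth.sort(key=lambda e: (e.chrom, e.pos, e.ref, e.alt))

    # --- ortholog alignments (planted nonsynonymous columns fully conserved)
    conserved_columns: Dict[str, Set[int]] = {m.gene_id: set() for m in models}
    for e in truth:
        if e.category == CATEGORY_NSSNP and e.gene_id:
            conserved_columns[e.gene_id].add(e.residue_index)
    alignments: Dict[str, Dict[str, str]] = {}
    for m in models:
        protein = proteins[m.gene_id]
        rows: Dict[str, str] = {"ref": protein}
        for r in range(config.n_alignment_rows - 1):
            row = []
            for col, aa in enumerate(protein, start=1):
                if col in conserved_columns[m.gene_id]:
                    row.append(aa)
                elif rng.random() < config.background_conservation:
                    row.append(aa)
                else:
                    row.append(str(rng.choice(list(AA20))))
            rows[f"ortholog_{r + 1}"] = "".join(row)
        alignments[m.gene_id] = rows

    dataset = SimulatedDataset(
        config=config,
        reference=reference,
        models=models,
        manifest=manifest,
        records=records,
        truth=truth,
        cpg_islands=islands,
        promoters=promoters,
        promoter_genes=promoter_genes,
        alignments=alignments,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


# ---------------------------------------------------------------------------
# serialization

def _write_gff3(models: Sequence[TranscriptModel], path: Path) -> None:
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.chrom}\tconsnp\tgene\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.chrom}\tconsnp\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for i, ex in enumerate(m.exons):
                fh.write(
                    f"{m.chrom}\tconsnp\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id}.exon{i + 1};"
                    f"Parent={m.transcript_id}\n"
                )
            offset = 0
            for iv in m.cds_in_transcription_order():
                phase = (3 - offset % 3) % 3
                fh.write(
                    f"{m.chrom}\tconsnp\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t{phase}\tID={m.transcript_id}.cds;"
                    f"Parent={m.transcript_id}\n"
                )
                offset += len(iv)


def _write_dataset(ds: SimulatedDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    chrom = ds.config.chrom
    paths = {
        "fasta": out_dir / "reference.fasta",
        "gff3": out_dir / "genes.gff3",
        "cpg_bed": out_dir / "cpg_islands.bed",
        "promoter_bed": out_dir / "promoters.bed",
        "vcf": out_dir / "variants.vcf",
        "manifest": out_dir / "manifest.tsv",
        "alignments": out_dir / "alignments",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_fasta({chrom: ds.reference.fetch(
        GenomicInterval(chrom, 0, ds.reference.length(chrom))
    )}, paths["fasta"])
    _write_gff3(ds.models, paths["gff3"])
    write_bed_intervals(
        ds.cpg_islands, paths["cpg_bed"],
        names=[f"cpg_{i + 1}" for i in range(len(ds.cpg_islands))],
    )
    write_bed_intervals(ds.promoters, paths["promoter_bed"], names=ds.promoter_genes)
    write_vcf(
        ds.records, ds.manifest, paths["vcf"],
        contig_lengths={chrom: ds.reference.length(chrom)},
    )
    write_manifest(ds.manifest, paths["manifest"])
    paths["alignments"].mkdir(exist_ok=True)
    for gene_id, rows in ds.alignments.items():
        write_fasta(rows, paths["alignments"] / f"{gene_id}.afa")
    payload = {
        "config": asdict(ds.config),
        "snps": [asdict(e) for e in ds.truth],
    }
    with open(paths["ground_truth"], "wt") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    ds.paths = {k: str(v) for k, v in paths.items()}


def load_ground_truth(path) -> List[GroundTruthEntry]:
    with open(path) as fh:
        payload = json.load(fh)
    return [GroundTruthEntry(**e) for e in payload["snps"]]
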
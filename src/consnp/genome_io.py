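"""Readers/writers for the standard formats the pipeline touches.

External conventions handled here and nowhere else:

=======  ==============================
format   coordinate convention
=======  ==============================
VCF      1-based, closed (POS)
GFF3     1-based, closed
BED      0-based, half-open
internal 0-based, half-open
=======  ==============================

All readers accept plain or gzip-compressed input (by .gz suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .core import (
    GROUPS,
    Genotype,
    GenomicInterval,
    ReferenceSequence,
    SampleManifest,
    TranscriptModel,
    VariantRecord,
    derive_utrs,
    from_vcf_pos,
    to_vcf_pos,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _open_text(path: PathLike):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> ReferenceSequence:
    with _open_text(path) as fh:
        return ReferenceSequence(
            {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        )


def write_fasta(seqs: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: PathLike) -> Dict[str, str]:
    """Read an aligned FASTA into an ordered id -> row mapping."""
    with _open_text(path) as fh:
        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment in {path}: row lengths {sorted(lengths)}")
    return rows


# ---------------------------------------------------------------------------
# Sample manifest

def read_manifest(path: PathLike) -> SampleManifest:
    """Two-column TSV: sample id, group label (QQ|qq). Header optional."""
    assignments: Dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed manifest line: {line!r}")
            sample, group = fields[0], fields[1]
            if sample == "sample" and group not in GROUPS:
                continue  # header line
            if sample in assignments:
                raise ValueError(f"duplicate sample {sample!r} in manifest")
            assignments[sample] = group
    return SampleManifest(assignments)


def write_manifest(manifest: SampleManifest, path: PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in manifest.assignments.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# VCF

@dataclass
class VcfStats:
    """Per-read bookkeeping: how many input records were not biallelic SNPs."""

    n_records: int = 0
    n_snps: int = 0
    n_skipped_indel: int = 0
    n_skipped_other: int = 0

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_indel + self.n_skipped_other


def _classify_genotype(allele_pair: Sequence[int], alt_index: int) -> Genotype:
    """Classify a diploid genotype against one alt allele of a possibly
    multiallelic record."""
    if any(a < 0 for a in allele_pair):
        return Genotype.MISSING
    n_alt = sum(1 for a in allele_pair if a == alt_index)
    if n_alt == 2:
        return Genotype.HOM_ALT
    if n_alt == 1:
        return Genotype.HET
    return Genotype.HOM_REF


def read_vcf(
    path: PathLike,
    manifest: SampleManifest,
    reference: Optional[ReferenceSequence] = None,
) -> Tuple[List[VariantRecord], VcfStats]:
    """Read biallelic SNPs from a VCF v4.x file.

    Multiallelic records are split into one record per alt allele; indels and
    other non-SNP alleles are skipped and counted in the returned stats.
    Positions are converted to the internal 0-based convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    try:
        samples = list(vcf.samples)
        unknown = [s for s in samples if s not in manifest.assignments]
        if unknown:
            raise ValueError(f"VCF sample(s) not in manifest: {unknown}")
        missing = [s for s in manifest.samples if s not in samples]
        if missing:
            raise ValueError(f"manifest sample(s) not in VCF: {missing}")

        stats = VcfStats()
        records: List[VariantRecord] = []
        for var in vcf:
            stats.n_records += 1
            ref = var.REF.upper()
            pos0 = from_vcf_pos(var.POS)
            genotypes = var.genotypes  # [[a1, a2, phased], ...]
            emitted = False
            for alt_index0, alt in enumerate(var.ALT):
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1:
                    stats.n_skipped_indel += 1
                    continue
                if ref not in "ACGT" or alt not in "ACGT":
                    stats.n_skipped_other += 1
                    continue
                if reference is not None:
                    genome_base = reference.base(var.CHROM, pos0)
                    if genome_base != ref:
                        raise ValueError(
                            f"REF mismatch at {var.CHROM}:{var.POS}: "
                            f"VCF has {ref}, genome has {genome_base}"
                        )
                gts = {
                    sample: _classify_genotype(genotypes[i][:2], alt_index0 + 1)
                    for i, sample in enumerate(samples)
                }
                records.append(VariantRecord.make(var.CHROM, pos0, ref, alt, gts))
                emitted = True
            if emitted:
                stats.n_snps += 1
        skipped = stats.n_skipped
        if skipped:
            logger.info("read_vcf: skipped %d non-SNP allele(s) in %s", skipped, path)
        return records, stats
    finally:
        vcf.close()


_GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    records: Iterable[VariantRecord],
    manifest: SampleManifest,
    path: PathLike,
    contig_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write biallelic SNP records as a minimal VCF v4.2 file."""
    samples = manifest.samples
    records = sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            gmap = rec.genotype_map
            gts = "\t".join(_GT_STRINGS[gmap[s]] for s in samples)
            fh.write(
                f"{rec.chrom}\t{to_vcf_pos(rec.pos)}\t.\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Gene models

def _models_from_gff3(path: PathLike) -> List[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        force=True,
    )
    models: List[TranscriptModel] = []
    transcript_types = ("mRNA", "transcript")
    for ttype in transcript_types:
        for tx in db.features_of_type(ttype):
            parents = list(db.parents(tx, featuretype="gene"))
            gene_id = parents[0].id if parents else tx.attributes.get(
                "gene_id", [tx.id]
            )[0]
            exons = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in db.children(tx, featuretype="exon")
            ]
            cds = [
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
                for f in db.children(tx, featuretype="CDS")
            ]
            if not exons:
                if not cds:
                    continue
                exons = list(cds)
            strand = tx.strand if tx.strand in "+-" else "+"
            utr5, utr3 = derive_utrs(exons, cds, strand, tx.seqid)
            model = TranscriptModel(
                gene_id=gene_id,
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=strand,
                exons=exons,
                cds=cds,
                utr5=utr5,
                utr3=utr3,
            )
            if model.cds and not model.scorable:
                logger.warning(
                    "transcript %s: CDS length %d not divisible by 3; "
                    "flagged non-scorable",
                    model.transcript_id,
                    model.cds_length,
                )
            models.append(model)
    # orphan CDS: features with no transcript parent
    seen_tx = {m.transcript_id for m in models}
    for f in db.features_of_type("CDS"):
        parent_ids = [p.id for t in transcript_types for p in db.parents(f, featuretype=t)]
        if not parent_ids:
            raise ValueError(f"orphan CDS feature without transcript parent: {f.id}")
        if not any(p in seen_tx for p in parent_ids):
            raise ValueError(f"CDS {f.id} references unknown transcript {parent_ids}")
    return models


def _models_from_bed12(path: PathLike) -> List[TranscriptModel]:
    models: List[TranscriptModel] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}: {line!r}")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            ]
            cds = []
            if thick_end > thick_start:
                for ex in exons:
                    s = max(ex.start, thick_start)
                    e = min(ex.end, thick_end)
                    if s < e:
                        cds.append(GenomicInterval(chrom, s, e, strand))
            utr5, utr3 = derive_utrs(exons, cds, strand, chrom)
            models.append(
                TranscriptModel(
                    gene_id=name,
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    return models


def read_gene_models(path: PathLike) -> List[TranscriptModel]:
    """Load transcript models from GFF3 (gene/mRNA/exon/CDS) or BED12."""
    name = Path(path).name.lower()
    if name.endswith((".bed", ".bed.gz", ".bed12", ".bed12.gz")):
        return _models_from_bed12(path)
    return _models_from_gff3(path)


def pick_coding_transcript(models: Sequence[TranscriptModel]) -> Dict[str, TranscriptModel]:
    """One representative transcript per gene for coding effects: longest CDS,
    ties broken by smallest transcript id."""
    best: Dict[str, TranscriptModel] = {}
    for m in models:
        if not m.cds:
            continue
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.cds_length > cur.cds_length
            or (m.cds_length == cur.cds_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


# ---------------------------------------------------------------------------
# BED intervals (CpG islands, promoters)

def read_bed_intervals(path: PathLike) -> List[GenomicInterval]:
    """Read BED3+ intervals (0-based half-open; strand from column 6 if any)."""
    out: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return sorted(out)


def write_bed_intervals(
    intervals: Iterable[GenomicInterval],
    path: PathLike,
    names: Optional[Sequence[str]] = None,
) -> None:
    intervals = list(intervals)
    with open(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Report TSVs

def write_report_tsv(
    rows: Sequence[dict],
    path: PathLike,
    columns: Sequence[str],
    sort_by: Optional[Sequence[str]] = None,
    ascending: Union[bool, Sequence[bool]] = True,
) -> None:
    """Write a tab-separated report: one header line, stable column order,
    deterministic row order (``sort_by`` keys, default input order)."""
    df = pd.DataFrame(list(rows), columns=list(columns))
    if sort_by and len(df):
        df = df.sort_values(list(sort_by), ascending=ascending, kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
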
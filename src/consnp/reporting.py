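"""Category-count matrix, ranked substitution report, and the end-to-end
pipeline runner."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotate import (
    DEFAULT_PROMOTER_DOWNSTREAM,
    DEFAULT_PROMOTER_UPSTREAM,
    DEFAULT_SPLICE_WINDOW,
    FunctionalAnnotation,
    annotate_variant,
    derive_promoters,
    detect_cpg_islands,
    merged_categories,
)
from .consensus import ConsensusCall, call_consensus, summarize_concordance
from .core import GROUPS, GenomicInterval, to_vcf_pos
from .effects import (
    NONSYNONYMOUS_LIKE,
    SubstitutionEffect,
    effects_for_variants,
)
from .genome_io import (
    read_bed_intervals,
    read_fasta,
    read_gene_models,
    read_manifest,
    read_vcf,
    write_report_tsv,
)
from .scoring import EffectScore, SubstitutionMatrix, load_alignment_dir, score_substitutions

logger = logging.getLogger(__name__)

MATRIX_ROWS = (GROUPS[0], GROUPS[1], "Total")
MATRIX_COLUMNS = ("nsSNP", "UTR", "splice", "CpG", "promoter", "Total")

#: annotation category -> matrix column (CDS handled via effect status)
_CATEGORY_TO_COLUMN = {
    "UTR5": "UTR",
    "UTR3": "UTR",
    "splice": "splice",
    "CpG": "CpG",
    "promoter": "promoter",
}


def regulatory_subtotal(matrix: pd.DataFrame, group: str) -> int:
    """Sum of the regulatory category cells (UTR, splice, CpG, promoter)
    for one group row, excluding the nsSNP cell."""
    return int(matrix.loc[group, ["UTR", "splice", "CpG", "promoter"]].sum())


def build_category_matrix(
    annotations: Mapping[Tuple[str, int, str, str], FrozenSet[str]],
    calls: Sequence[ConsensusCall],
    nonsynonymous_keys: Optional[Set[Tuple[str, int, str, str]]] = None,
) -> Tuple[pd.DataFrame, List[ConsensusCall]]:
    """Tally consensus calls into the per-group category matrix.

    ``annotations`` maps variant key -> merged category set. A SNP with
    multiple categories increments each corresponding cell once. Calls whose
    merged annotation yields no countable column land in the returned
    "unlinked" bucket (logged), not in the matrix. Totals are always
    recomputed, never taken from input.
    """
    nonsynonymous_keys = nonsynonymous_keys or set()
    counts = {g: {c: 0 for c in MATRIX_COLUMNS} for g in MATRIX_ROWS}
    unlinked: List[ConsensusCall] = []
    for call in calls:
        key = call.variant.key()
        cats = annotations.get(key, frozenset())
        columns = {_CATEGORY_TO_COLUMN[c] for c in cats if c in _CATEGORY_TO_COLUMN}
        if "CDS" in cats and key in nonsynonymous_keys:
            columns.add("nsSNP")
        if not columns:
            unlinked.append(call)
            continue
        for col in columns:
            counts[call.group][col] += 1
    if unlinked:
        logger.info(
            "build_category_matrix: %d call(s) without countable categories",
            len(unlinked),
        )
    for g in GROUPS:
        counts[g]["Total"] = sum(counts[g][c] for c in MATRIX_COLUMNS[:-1])
    for c in MATRIX_COLUMNS:
        counts["Total"][c] = sum(counts[g][c] for g in GROUPS)
    matrix = pd.DataFrame(
        [[counts[r][c] for c in MATRIX_COLUMNS] for r in MATRIX_ROWS],
        index=list(MATRIX_ROWS),
        columns=list(MATRIX_COLUMNS),
    )
    return matrix, unlinked


@dataclass
class RankedEffectRow:
    """One row of the ranked nonsynonymous-substitution report."""

    gene_id: str
    group: str
    coordinate: int  # 1-based, as printed in reports
    codon: str  # "REF/ALT"
    substitution: str  # e.g. T179P
    support: str  # "4/5"
    physchem: float
    conservation: Optional[float]


def rank_effects(
    scored: Sequence[Tuple[SubstitutionEffect, EffectScore]],
    calls_by_key: Mapping[Tuple[str, int, str, str], ConsensusCall],
    variant_keys: Mapping[int, Tuple[str, int, str, str]],
) -> List[RankedEffectRow]:
    """Order scored substitutions by descending conservation, then descending
    physchem, then coordinate. Absent conservation sorts last."""
    rows: List[RankedEffectRow] = []
    for i, (effect, score) in enumerate(scored):
        key = variant_keys[i]
        call = calls_by_key.get(key)
        rows.append(
            RankedEffectRow(
                gene_id=effect.gene_id,
                group=call.group if call else "",
                coordinate=to_vcf_pos(effect.pos),
                codon=effect.codon_label,
                substitution=effect.label,
                support=call.support if call else "",
                physchem=score.physchem,
                conservation=score.conservation,
            )
        )
    rows.sort(
        key=lambda r: (
            -(r.conservation if r.conservation is not None else -1.0),
            -r.physchem,
            r.coordinate,
        )
    )
    return rows


# ---------------------------------------------------------------------------
# end-to-end pipeline

@dataclass
class PipelineConfig:
    """Resolved inputs and parameters for one pipeline run."""

    vcf: str
    manifest: str
    fasta: str
    gene_models: str
    out_dir: str
    cpg_bed: Optional[str] = None
    promoter_bed: Optional[str] = None
    alignments_dir: Optional[str] = None
    matrix_tsv: Optional[str] = None
    presence_min: Optional[int] = None
    absence_max: int = 0
    carrier_rule: str = "any-alt-allele"
    strict_missing: bool = False
    splice_window: int = DEFAULT_SPLICE_WINDOW
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM
    promoter_downstream: int = DEFAULT_PROMOTER_DOWNSTREAM
    conservation_method: str = "identity"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


@dataclass
class PipelineResult:
    calls: List[ConsensusCall]
    annotations: Dict[Tuple[str, int, str, str], FrozenSet[str]]
    per_gene: Dict[Tuple[str, int, str, str], List[FunctionalAnnotation]]
    effects: List[SubstitutionEffect]
    scored: List[Tuple[SubstitutionEffect, EffectScore]]
    matrix: pd.DataFrame
    unlinked: List[ConsensusCall]
    ranked: List[RankedEffectRow]
    concordance: Dict[str, int]
    files: Dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run consensus calling, annotation, coding effects, scoring and
    reporting; writes every intermediate TSV beside the final reports."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("pipeline stage: %s", name)

    stage("load inputs")
    reference = read_fasta(config.fasta)
    manifest = read_manifest(config.manifest)
    models = read_gene_models(config.gene_models)
    variants, vcf_stats = read_vcf(config.vcf, manifest, reference)

    stage("consensus")
    calls = call_consensus(
        variants,
        manifest,
        presence_min=config.presence_min,
        absence_max=config.absence_max,
        carrier_rule=config.carrier_rule,
        strict_missing=config.strict_missing,
    )
    concordance = summarize_concordance(calls)
    write_report_tsv(
        [
            {
                "chrom": c.variant.chrom,
                "pos": to_vcf_pos(c.variant.pos),
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "group": c.group,
                "support": c.support,
                "carriers_in_other": c.carriers_in_other,
            }
            for c in calls
        ],
        out_dir / "consensus.tsv",
        columns=["chrom", "pos", "ref", "alt", "group", "support", "carriers_in_other"],
        sort_by=["chrom", "pos", "ref", "alt"],
    )

    stage("regulatory intervals")
    if config.cpg_bed:
        cpg = read_bed_intervals(config.cpg_bed)
    else:
        cpg = []
        for chrom in reference.chroms:
            cpg.extend(
                detect_cpg_islands(
                    reference, GenomicInterval(chrom, 0, reference.length(chrom))
                )
            )
    if config.promoter_bed:
        promoters = read_bed_intervals(config.promoter_bed)
        promoter_genes: Optional[List[str]] = None
    else:
        promoters, promoter_genes = derive_promoters(
            models,
            reference,
            upstream=config.promoter_upstream,
            downstream=config.promoter_downstream,
        )

    stage("annotate")
    called_variants = [c.variant for c in calls]
    per_gene: Dict[Tuple[str, int, str, str], List[FunctionalAnnotation]] = {}
    annotations: Dict[Tuple[str, int, str, str], FrozenSet[str]] = {}
    for v in called_variants:
        anns = annotate_variant(
            v,
            models,
            cpg=cpg,
            promoters=promoters,
            promoter_genes=promoter_genes,
            splice_window=config.splice_window,
        )
        per_gene[v.key()] = anns
        annotations[v.key()] = merged_categories(anns)
    write_report_tsv(
        [
            {
                "chrom": key[0],
                "pos": to_vcf_pos(key[1]),
                "ref": key[2],
                "alt": key[3],
                "genes": ",".join(sorted({a.gene_id for a in anns if a.gene_id})),
                "categories": ",".join(sorted(annotations[key])),
            }
            for key, anns in per_gene.items()
        ],
        out_dir / "annotations.tsv",
        columns=["chrom", "pos", "ref", "alt", "genes", "categories"],
        sort_by=["chrom", "pos", "ref", "alt"],
    )

    stage("coding effects")
    cds_variants = [
        v for v in called_variants if "CDS" in annotations.get(v.key(), frozenset())
    ]
    effect_pairs = effects_for_variants(cds_variants, models, reference)
    effects = [e for _, e in effect_pairs]
    write_report_tsv(
        [
            {
                "gene": e.gene_id,
                "transcript": e.transcript_id,
                "chrom": e.chrom,
                "pos": to_vcf_pos(e.pos),
                "ref_codon": e.ref_codon,
                "alt_codon": e.alt_codon,
                "codon_position": e.codon_position,
                "substitution": e.label,
                "status": e.status,
            }
            for e in effects
        ],
        out_dir / "effects.tsv",
        columns=[
            "gene", "transcript", "chrom", "pos", "ref_codon", "alt_codon",
            "codon_position", "substitution", "status",
        ],
        sort_by=["chrom", "pos"],
    )

    stage("score")
    alignments = (
        load_alignment_dir(config.alignments_dir) if config.alignments_dir else {}
    )
    matrix_obj = (
        SubstitutionMatrix.from_tsv(config.matrix_tsv)
        if config.matrix_tsv
        else SubstitutionMatrix.grantham()
    )
    ns_pairs = [(v, e) for v, e in effect_pairs if e.status in NONSYNONYMOUS_LIKE]
    ns_effects = [e for _, e in ns_pairs]
    scored = score_substitutions(
        ns_effects,
        alignments,
        matrix=matrix_obj,
        conservation_method=config.conservation_method,
    )
    write_report_tsv(
        [
            {
                "gene": e.gene_id,
                "pos": to_vcf_pos(e.pos),
                "substitution": e.label,
                "physchem": s.physchem,
                "conservation": "" if s.conservation is None else s.conservation,
            }
            for e, s in scored
        ],
        out_dir / "scores.tsv",
        columns=["gene", "pos", "substitution", "physchem", "conservation"],
        sort_by=["gene", "pos"],
    )

    stage("reports")
    nonsyn_keys = {v.key() for v, _ in ns_pairs}
    matrix, unlinked = build_category_matrix(annotations, calls, nonsyn_keys)
    matrix.to_csv(out_dir / "category_matrix.tsv", sep="\t", index_label="Genotypes")

    calls_by_key = {c.variant.key(): c for c in calls}
    variant_keys = {i: ns_pairs[i][0].key() for i in range(len(scored))}
    ranked = rank_effects(scored, calls_by_key, variant_keys)
    write_report_tsv(
        [
            {
                "gene": r.gene_id,
                "group": r.group,
                "coordinate": r.coordinate,
                "codon": r.codon,
                "substitution": r.substitution,
                "support": r.support,
                "physchem": round(r.physchem, 4),
                "conservation": (
                    "" if r.conservation is None else round(r.conservation, 4)
                ),
            }
            for r in ranked
        ],
        out_dir / "ranked_effects.tsv",
        columns=[
            "gene", "group", "coordinate", "codon", "substitution",
            "support", "physchem", "conservation",
        ],
    )

    files = {
        name: str(out_dir / f"{name}.tsv")
        for name in ("consensus", "annotations", "effects", "scores", "category_matrix", "ranked_effects")
    }
    return PipelineResult(
        calls=calls,
        annotations=annotations,
        per_gene=per_gene,
        effects=effects,
        scored=scored,
        matrix=matrix,
        unlinked=unlinked,
        ranked=ranked,
        concordance=concordance,
        files=files,
    )
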
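# consnp

Prioritize candidate causal SNPs inside a fine-mapped QTL interval.

Given a multi-sample VCF restricted to a target interval, a reference FASTA,
gene models (GFF3 or BED12) and a two-group sample manifest (`QQ` / `qq`
homozygous QTL genotype classes), the pipeline:

1. **Consensus calling** — keeps SNPs carried by (almost) every sample of one
   genotype group and absent from the other (default: at least group size − 1
   carriers, strict absence).
2. **Functional annotation** — classifies each consensus SNP by gene-related
   context: CDS, 5′/3′ UTR, canonical splice site (intronic GT/AG window),
   CpG island (supplied BED or Gardiner-Garden/Frommer-style detection) and
   promoter (2 kb upstream of the TSS by default).
3. **Coding effects** — maps CDS SNPs onto spliced, strand-aware codons and
   classifies them as synonymous / nonsynonymous / nonsense / start-loss.
4. **Scoring** — ranks nonsynonymous substitutions with two components, each
   in [0, 1] with 0 = neutral: a normalized Grantham physicochemical-change
   score and a conservation score from per-gene ortholog alignments
   (identity fraction by default, entropy-based as an option).
5. **Reporting** — a per-group category-count matrix and a ranked
   substitution report (conservation desc, physchem desc, coordinate).

A fully self-contained simulator (`consnp.simulate`) generates a toy dataset
(reference, multi-exon gene models with canonical splice dinucleotides, CpG
islands, promoters, ortholog alignments, two-group VCF) with planted ground
truth for every category, so the whole pipeline is testable offline.

## CLI

```bash
# generate a synthetic dataset with planted truth
consnp simulate --seed 42 --out data/

# individual stages
consnp consensus --vcf data/variants.vcf --manifest data/manifest.tsv --out consensus.tsv
consnp annotate  --vcf data/variants.vcf --manifest data/manifest.tsv \
                 --gff data/genes.gff3 --fasta data/reference.fasta \
                 --cpg data/cpg_islands.bed --out annotations.tsv
consnp effects   --vcf data/variants.vcf --manifest data/manifest.tsv \
                 --gff data/genes.gff3 --fasta data/reference.fasta --out effects.tsv
consnp score     --effects effects.tsv --alignments data/alignments --out scores.tsv

# end-to-end from a YAML config (see consnp.reporting.PipelineConfig fields)
consnp run --config pipeline.yaml
```

All coordinates are 0-based half-open internally; VCF/GFF3 (1-based) and BED
(0-based) conversions happen only in `consnp.genome_io`. Readers accept plain
or gzip-compressed input.

## Layout

- `consnp.core` — domain types (intervals, reference, manifest, variants, transcript models)
- `consnp.genome_io` — VCF/GFF3/BED/FASTA/TSV readers and writers
- `consnp.simulate` — synthetic dataset generator with planted ground truth
- `consnp.consensus` — group-consensus SNP calling
- `consnp.annotate` — functional categories, CpG-island detection, promoter derivation
- `consnp.effects` — codon mapping and substitution classification
- `consnp.scoring` — Grantham-based physicochemical score, conservation score
- `consnp.reporting` — category matrix, ranked report, pipeline runner
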
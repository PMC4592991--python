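import itertools

import pytest
from Bio.Seq import Seq

from consnp.core import (
    Genotype,
    GenomicInterval,
    ReferenceSequence,
    TranscriptModel,
    VariantRecord,
    derive_utrs,
    revcomp,
)
from consnp.effects import (
    SubstitutionEffect,
    classify_substitution,
    cds_offset_of,
    effects_for_variants,
    genomic_pos_of,
    map_to_codon,
    spliced_cds,
    translate_cds,
    translate_codon,
)

GTS = {"a": Genotype.HOM_ALT, "b": Genotype.HOM_REF}


class TestTranslateCodon:
    @pytest.mark.parametrize(
        "codon,aa",
        [
            ("ACT", "T"), ("CCT", "P"),
            ("GGT", "G"), ("AGT", "S"),
            ("TTT", "F"), ("ATT", "I"),
            ("GCA", "A"), ("GGA", "G"),
            ("ATG", "M"), ("TAA", "*"),
        ],
    )
    def test_known_codons(self, codon, aa):
        assert translate_codon(codon) == aa

    def test_all_codons_match_biopython(self):
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            assert translate_codon(codon) == str(Seq(codon).translate())

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            translate_codon("ANT")
        with pytest.raises(ValueError):
            translate_codon("AC")


class TestClassifySubstitution:
    def _effect(self, ref_codon, alt_codon, residue=2):
        diff = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
        return SubstitutionEffect(
            gene_id="g", transcript_id="t", chrom="c", pos=0,
            ref_codon=ref_codon, alt_codon=alt_codon,
            codon_position=diff[0] + 1 if diff else 1,
            ref_aa=translate_codon(ref_codon),
            alt_aa=translate_codon(alt_codon),
            residue_index=residue,
        )

    def test_paper_codon_pair_nonsynonymous(self):
        assert classify_substitution(self._effect("ACT", "CCT")) == "nonsynonymous"

    def test_synonymous(self):
        assert classify_substitution(self._effect("CTT", "CTA")) == "synonymous"

    def test_nonsense(self):
        assert classify_substitution(self._effect("TAT", "TAA")) == "nonsense"

    def test_start_loss(self):
        assert classify_substitution(self._effect("ATG", "GTG", residue=1)) == "start-loss"

    def test_all_single_base_mutations_match_enumeration(self):
        # independent oracle: classify via Biopython translation directly
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            for i, b in itertools.product(range(3), "ACGT"):
                if codon[i] == b:
                    continue
                mut = codon[:i] + b + codon[i + 1 :]
                got = classify_substitution(self._effect(codon, mut, residue=2))
                ref_aa = str(Seq(codon).translate())
                alt_aa = str(Seq(mut).translate())
                if alt_aa == "*" and ref_aa != "*":
                    expected = "nonsense"
                elif ref_aa == alt_aa:
                    expected = "synonymous"
                else:
                    expected = "nonsynonymous"
                assert got == expected, (codon, mut)


def single_exon_model(cds_seq, strand="+", cds_start=150):
    """A model whose CDS is laid out contiguously from cds_start; genomic
    sequence carries cds_seq on the coding strand."""
    chrom_seq = "A" * cds_start
    genomic = cds_seq if strand == "+" else revcomp(cds_seq)
    chrom_seq += genomic + "A" * 50
    exons = [GenomicInterval("c", 100, cds_start + len(cds_seq) + 20, strand)]
    cds = [GenomicInterval("c", cds_start, cds_start + len(cds_seq), strand)]
    utr5, utr3 = derive_utrs(exons, cds, strand, "c")
    model = TranscriptModel(
        gene_id="g", transcript_id="t", chrom="c", strand=strand,
        exons=exons, cds=cds, utr5=utr5, utr3=utr3,
    )
    return model, ReferenceSequence({"c": chrom_seq})


class TestMapToCodon:
    def test_first_cds_base(self):
        model, ref = single_exon_model("ATGGCTTAA")
        v = VariantRecord.make("c", 150, "A", "G", GTS)
        eff = map_to_codon(v, model, ref)
        assert eff.residue_index == 1
        assert eff.codon_position == 1
        assert eff.ref_codon == "ATG"

    def test_offset_534_is_residue_179(self):
        cds = "ATG" + "GCT" * 200 + "TAA"
        model, ref = single_exon_model(cds)
        pos = 150 + 534
        v = VariantRecord.make("c", pos, ref.base("c", pos), "T", GTS)
        eff = map_to_codon(v, model, ref)
        assert eff.residue_index == 534 // 3 + 1 == 179

    def test_minus_strand_reverse_complement(self):
        cds = "ATGGGTCCATAA"  # M G P *
        model, ref = single_exon_model(cds, strand="-")
        # codon 2 is GGT; genomic carries revcomp; mutate coding G->A (pos 3 of CDS)
        offset = 3
        pos = genomic_pos_of(model, offset)
        assert ref.base("c", pos) == revcomp("G")
        v = VariantRecord.make("c", pos, "C", "T", GTS)  # coding G->A
        eff = map_to_codon(v, model, ref)
        assert eff.ref_codon == "GGT"
        assert eff.alt_codon == "AGT"
        assert eff.ref_aa == "G" and eff.alt_aa == "S"
        assert eff.status == "nonsynonymous"

    def test_non_scorable_model_rejected(self):
        model, ref = single_exon_model("ATGGCTTAAC"[:10])  # length 10
        v = VariantRecord.make("c", 151, ref.base("c", 151), "G", GTS)
        with pytest.raises(ValueError, match="non-scorable"):
            map_to_codon(v, model, ref)

    def test_ref_mismatch_rejected(self):
        model, ref = single_exon_model("ATGGCTTAA")
        v = VariantRecord.make("c", 150, "C", "G", GTS)  # genome has A
        with pytest.raises(ValueError, match="mismatch"):
            map_to_codon(v, model, ref)

    def test_outside_cds_rejected(self):
        model, ref = single_exon_model("ATGGCTTAA")
        v = VariantRecord.make("c", 120, "A", "G", GTS)
        with pytest.raises(ValueError, match="not in the CDS"):
            map_to_codon(v, model, ref)

    def test_strand_mirror_equivalence(self):
        """A gene and its reverse-complement mirror yield identical effects."""
        cds = "ATGTTTGGTCCAGAGTAA"
        plus_model, plus_ref = single_exon_model(cds, strand="+")
        minus_model, minus_ref = single_exon_model(cds, strand="-")
        for offset in range(3, len(cds) - 3):  # skip start/stop codons
            p_pos = genomic_pos_of(plus_model, offset)
            m_pos = genomic_pos_of(minus_model, offset)
            coding_ref = cds[offset]
            for coding_alt in "ACGT":
                if coding_alt == coding_ref:
                    continue
                vp = VariantRecord.make("c", p_pos, coding_ref, coding_alt, GTS)
                vm = VariantRecord.make(
                    "c", m_pos, revcomp(coding_ref), revcomp(coding_alt), GTS
                )
                ep = map_to_codon(vp, plus_model, plus_ref)
                em = map_to_codon(vm, minus_model, minus_ref)
                assert (ep.ref_codon, ep.alt_codon, ep.residue_index, ep.status) == (
                    em.ref_codon, em.alt_codon, em.residue_index, em.status
                )


class TestCdsCoordinates:
    def test_offset_roundtrip_on_simulated_genes(self, small_dataset):
        for model in small_dataset.models:
            for offset in range(0, model.cds_length, 7):
                pos = genomic_pos_of(model, offset)
                assert cds_offset_of(model, pos) == offset

    def test_spliced_cds_translates_cleanly(self, small_dataset):
        for model in small_dataset.models:
            protein = translate_cds(spliced_cds(model, small_dataset.reference))
            assert protein[0] == "M"
            assert protein[-1] == "*"
            assert "*" not in protein[:-1]


class TestRetranslationOracle:
    def test_full_cds_retranslation_differs_only_at_reported_residue(
        self, default_dataset
    ):
        """For every planted CDS SNP, mutate the genome, re-extract and
        re-translate the whole CDS, and compare proteins position by
        position — both strands are exercised by the simulated genes."""
        ds = default_dataset
        models_by_gene = {m.gene_id: m for m in ds.models}
        strands_seen = set()
        checked = 0
        for entry in ds.truth:
            if entry.category not in ("nsSNP", "synonymous"):
                continue
            model = models_by_gene[entry.gene_id]
            strands_seen.add(model.strand)
            variant = next(
                r for r in ds.records if (r.chrom, r.pos, r.ref, r.alt)
                == (entry.chrom, entry.pos, entry.ref, entry.alt)
            )
            effect = map_to_codon(variant, model, ds.reference)
            # oracle: mutate the genome and retranslate the entire CDS
            chrom_seq = ds.reference.fetch(
                GenomicInterval(entry.chrom, 0, ds.reference.length(entry.chrom))
            )
            mutated = ReferenceSequence(
                {
                    entry.chrom: chrom_seq[: entry.pos]
                    + entry.alt
                    + chrom_seq[entry.pos + 1 :]
                }
            )
            ref_protein = translate_cds(spliced_cds(model, ds.reference))
            alt_protein = translate_cds(spliced_cds(model, mutated))
            diffs = [
                i + 1
                for i, (a, b) in enumerate(zip(ref_protein, alt_protein))
                if a != b
            ]
            if effect.status == "synonymous":
                assert diffs == []
            else:
                assert diffs == [effect.residue_index]
            checked += 1
        assert checked >= 4
        assert strands_seen == {"+", "-"}


class TestEffectsForVariants:
    def test_only_cds_variants_scored(self, small_dataset):
        ds = small_dataset
        pairs = effects_for_variants(ds.records, ds.models, ds.reference)
        truth = ds.truth_by_key()
        coding_keys = {
            k for k, e in truth.items() if e.category in ("nsSNP", "synonymous")
        }
        assert {v.key() for v, _ in pairs} == coding_keys
        for v, eff in pairs:
            entry = truth[v.key()]
            assert eff.residue_index == entry.residue_index
            assert eff.ref_codon == entry.ref_codon
            assert eff.alt_codon == entry.alt_codon
            expected_status = (
                "nonsynonymous" if entry.category == "nsSNP" else "synonymous"
            )
            assert eff.status == expected_status
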
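import filecmp
import json
from collections import Counter
from pathlib import Path

import pytest

from consnp.consensus import call_consensus
from consnp.core import Genotype
from consnp.effects import translate_codon
from consnp.simulate import (
    CONSENSUS_CATEGORIES,
    SimulationConfig,
    load_ground_truth,
    plant_coding_snp,
    simulate_dataset,
    substitution_realizable,
)


def _tree_files(root: Path):
    return sorted(p.relative_to(root) for p in root.rglob("*") if p.is_file())


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=42, interval_length=250_000, n_genes=5,
                                  n_cpg_islands=3)
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_dataset(config, a)
        simulate_dataset(
            SimulationConfig(seed=42, interval_length=250_000, n_genes=5,
                             n_cpg_islands=3),
            b,
        )
        files = _tree_files(a)
        assert files == _tree_files(b)
        for rel in files:
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel

    def test_different_seed_differs(self, tmp_path):
        cfg = dict(interval_length=250_000, n_genes=5, n_cpg_islands=3)
        a = simulate_dataset(SimulationConfig(seed=1, **cfg))
        b = simulate_dataset(SimulationConfig(seed=2, **cfg))
        assert [r.pos for r in a.records] != [r.pos for r in b.records]


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, utr_counts={"QQ": -1, "qq": 0})

    def test_targets_exceeding_nssnp_counts_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SimulationConfig(seed=1, nssnp_counts={"QQ": 0, "qq": 0})

    def test_overfull_category_fails_before_writing(self, tmp_path):
        out = tmp_path / "never"
        config = SimulationConfig(
            seed=1, interval_length=250_000, n_genes=5, n_cpg_islands=3,
            splice_counts={"QQ": 10_000, "qq": 0},
        )
        with pytest.raises(ValueError, match="splice"):
            simulate_dataset(config, out)
        assert not out.exists()


class TestGroundTruth:
    def test_planted_counts(self, default_dataset):
        counts = Counter(e.category for e in default_dataset.truth)
        cfg = default_dataset.config
        assert counts["nsSNP"] == sum(cfg.nssnp_counts.values())
        assert counts["UTR"] == sum(cfg.utr_counts.values())
        assert counts["splice"] == sum(cfg.splice_counts.values())
        assert counts["CpG"] == sum(cfg.cpg_counts.values())
        assert counts["promoter"] == sum(cfg.promoter_counts.values())
        assert counts["intergenic-decoy"] == cfg.n_intergenic_decoys
        assert counts["discordant-decoy"] == cfg.n_discordant_decoys

    def test_nssnp_group_split_mirrors_config(self, default_dataset):
        ns = [e for e in default_dataset.truth if e.category == "nsSNP"]
        per_group = Counter(e.group for e in ns)
        assert per_group == Counter({"QQ": 3, "qq": 1})

    def test_at_least_one_partial_support_nssnp(self, default_dataset):
        ns = [e for e in default_dataset.truth if e.category == "nsSNP"]
        assert any(e.support == e.group_size - 1 for e in ns)

    def test_ref_allele_matches_reference(self, default_dataset):
        ds = default_dataset
        for rec in ds.records:
            assert ds.reference.base(rec.chrom, rec.pos) == rec.ref

    def test_consensus_pattern_planted_correctly(self, default_dataset):
        ds = default_dataset
        n = ds.config.samples_per_group
        by_key = ds.truth_by_key()
        for rec in ds.records:
            entry = by_key[rec.key()]
            gmap = rec.genotype_map
            if entry.category in CONSENSUS_CATEGORIES:
                carriers = sum(
                    1 for s in ds.manifest.samples_in(entry.group)
                    if gmap[s] is Genotype.HOM_ALT
                )
                others = sum(
                    1 for s in ds.manifest.samples_in(ds.manifest.other(entry.group))
                    if gmap[s] is not Genotype.HOM_REF
                )
                assert carriers == entry.support >= n - 1
                assert others == 0

    def test_coding_truth_consistent(self, default_dataset):
        for e in default_dataset.truth:
            if e.category == "nsSNP":
                assert translate_codon(e.ref_codon) == e.ref_aa
                assert translate_codon(e.alt_codon) == e.alt_aa
                assert e.ref_aa != e.alt_aa
            elif e.category == "synonymous":
                assert translate_codon(e.ref_codon) == translate_codon(e.alt_codon)

    def test_serialized_truth_loads_back(self, default_dataset):
        entries = load_ground_truth(default_dataset.paths["ground_truth"])
        assert len(entries) == len(default_dataset.truth)
        assert entries[0] == default_dataset.truth[0]

    def test_no_position_collisions(self, default_dataset):
        positions = [r.pos for r in default_dataset.records]
        assert len(positions) == len(set(positions))


class TestRecordConservation:
    def test_no_decoys_yields_exactly_planted_records(self, tmp_path):
        config = SimulationConfig(
            seed=5, interval_length=250_000, n_genes=5, n_cpg_islands=3,
            n_intergenic_decoys=0, n_discordant_decoys=0,
        )
        ds = simulate_dataset(config)
        k = (
            sum(config.nssnp_counts.values())
            + sum(config.synonymous_counts.values())
            + sum(config.utr_counts.values())
            + sum(config.splice_counts.values())
            + sum(config.cpg_counts.values())
            + sum(config.promoter_counts.values())
        )
        assert len(ds.records) == k


class TestPlantCodingSnp:
    @pytest.mark.parametrize(
        "ref_aa,alt_aa,expect_codons",
        [
            ("T", "P", {("ACT", "CCT"), ("ACC", "CCC"), ("ACA", "CCA"), ("ACG", "CCG")}),
            ("G", "S", {("GGT", "AGT"), ("GGC", "AGC")}),
        ],
    )
    def test_worked_substitutions(self, default_dataset, ref_aa, alt_aa, expect_codons):
        model = default_dataset.models[0]
        result = plant_coding_snp(model, default_dataset.reference, ref_aa, alt_aa)
        chrom, pos, ref, alt, residue, ref_codon, alt_codon = result
        assert (ref_codon, alt_codon) in expect_codons
        assert translate_codon(ref_codon) == ref_aa
        assert translate_codon(alt_codon) == alt_aa
        # the planted change really is a single genomic base
        assert ref != alt
        assert default_dataset.reference.base(chrom, pos) == ref

    def test_unrealizable_substitution_named(self, default_dataset):
        # M -> W needs two base changes (ATG -> TGG)
        with pytest.raises(ValueError, match="M->W"):
            plant_coding_snp(
                default_dataset.models[0], default_dataset.reference, "M", "W"
            )

    def test_realizability_brute_force(self):
        # oracle: enumerate all 9 single-base mutants of every M codon
        assert not substitution_realizable("M", "W")
        assert substitution_realizable("T", "P")
        mutants = set()
        for i in range(3):
            for b in "ACGT":
                if "ATG"[i] != b:
                    mutants.add(translate_codon("ATG"[:i] + b + "ATG"[i + 1 :]))
        assert "W" not in mutants

    def test_planted_consensus_recovered_for_fuzz_seeds(self):
        for seed in (3, 11, 23):
            config = SimulationConfig(
                seed=seed, interval_length=250_000, n_genes=5, n_cpg_islands=3,
            )
            ds = simulate_dataset(config)
            calls = call_consensus(ds.records, ds.manifest)
            expected = {
                (e.chrom, e.pos, e.ref, e.alt, e.group)
                for e in ds.consensus_truth()
            }
            got = {
                (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt, c.group)
                for c in calls
            }
            assert got == expected, f"seed {seed}"
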
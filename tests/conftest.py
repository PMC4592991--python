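import pytest

from consnp.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The default synthetic dataset (1.2 Mb, 13 genes, 5+5 samples),
    written to disk once per session."""
    out = tmp_path_factory.mktemp("simdata_default")
    return simulate_dataset(SimulationConfig(seed=42), out)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A reduced dataset for faster unit tests."""
    out = tmp_path_factory.mktemp("simdata_small")
    config = SimulationConfig(
        seed=7,
        interval_length=300_000,
        n_genes=6,
        n_cpg_islands=3,
        utr_counts={"QQ": 2, "qq": 2},
        splice_counts={"QQ": 1, "qq": 1},
        cpg_counts={"QQ": 1, "qq": 1},
        promoter_counts={"QQ": 1, "qq": 1},
    )
    return simulate_dataset(config, out)


@pytest.fixture(scope="session")
def default_pipeline(default_dataset, tmp_path_factory):
    """Full pipeline run on the default dataset."""
    from consnp.reporting import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline_default")
    config = PipelineConfig(
        vcf=default_dataset.paths["vcf"],
        manifest=default_dataset.paths["manifest"],
        fasta=default_dataset.paths["fasta"],
        gene_models=default_dataset.paths["gff3"],
        out_dir=str(out),
        cpg_bed=default_dataset.paths["cpg_bed"],
        alignments_dir=default_dataset.paths["alignments"],
    )
    return run_pipeline(config)
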
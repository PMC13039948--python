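import json
from pathlib import Path

import pytest

from m6a_landscape.synthetic_data import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=80,
        hypo_gene_set_size=20,
        hyper_gene_fraction=0.2,
        de_down_core_size=10,
        de_up_core_size=10,
        de_private_per_line=5,
        coverage_mean=60.0,
        reads_per_transcript=40,
    )


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory, small_config):
    """A small but complete synthetic corpus written to disk once per session."""
    outdir = tmp_path_factory.mktemp("corpus")
    ann = generate_corpus(small_config, seed=11, outdir=outdir)
    return {"dir": Path(outdir), "ann": ann, "config": small_config, "seed": 11}


@pytest.fixture(scope="session")
def landscape_config(small_corpus):
    d = small_corpus["dir"]
    return {
        "condition_a": "tumor",
        "condition_b": "normal",
        "pileups": {
            "tumor": [str(d / "pileup_tumor_rep1.tsv"), str(d / "pileup_tumor_rep2.tsv")],
            "normal": [str(d / "pileup_normal_rep1.tsv"), str(d / "pileup_normal_rep2.tsv")],
        },
        "annotation_gtf": str(d / "annotation.gtf"),
        "genome_fasta": str(d / "genome.fa"),
        "read_level_tsv": str(d / "read_level.tsv"),
        "n_perm": 200,
    }


@pytest.fixture(scope="session")
def treatment_config(small_corpus, landscape_bundle):
    d = small_corpus["dir"]
    return {
        "pileups": {
            "treated": [
                str(d / "pileup_tumor_treated_rep1.tsv"),
                str(d / "pileup_tumor_treated_rep2.tsv"),
            ],
            "untreated": [
                str(d / "pileup_tumor_untreated_rep1.tsv"),
                str(d / "pileup_tumor_untreated_rep2.tsv"),
            ],
        },
        "hypo_sites_tsv": str(landscape_bundle / "differential_sites.tsv"),
        "annotation_gtf": str(d / "annotation.gtf"),
        "genome_fasta": str(d / "genome.fa"),
        "de_table": str(d / "de_lineA.tsv"),
    }


@pytest.fixture(scope="session")
def landscape_bundle(small_corpus, landscape_config, tmp_path_factory):
    from m6a_landscape.pipeline_cli import run_landscape_comparison

    outdir = tmp_path_factory.mktemp("landscape")
    run_landscape_comparison(landscape_config, outdir, seed=1)
    return Path(outdir)
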
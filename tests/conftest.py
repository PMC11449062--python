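import numpy as np
import pytest

from camevo import synthetic_data as sd


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across read-only tests."""
    cfg = sd.GenomeConfig(n_scaffolds=2, scaffold_length=300_000,
                          n_orthogroups=150, haplotig_fraction=0.2)
    genomes, gene_models, te_features, orthogroups, truth = \
        sd.generate_genome_pair(cfg, seed=42)
    return {
        "config": cfg,
        "genomes": genomes,
        "gene_models": gene_models,
        "te_features": te_features,
        "orthogroups": orthogroups,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
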
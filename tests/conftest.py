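import numpy as np
import pytest

from mapscall.genome_io import GeneAnnotation, GenomeSequence
from mapscall.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study, scaled down for unit tests."""
    return SimulationConfig(
        seed=11,
        genome_length=80_000,
        n_genes=50,
        n_planted_targets=6,
        n_planted_pwm_sites=4,
        n_true_up=10,
        n_true_down=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def random_genome():
    rng = np.random.default_rng(2024)
    residues = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
    return GenomeSequence(seq_id="chr", residues=residues)


@pytest.fixture
def plus_gene():
    return GeneAnnotation(gene_id="geneA", seq_id="chr", start=1000, end=2000, strand="+")


@pytest.fixture
def minus_gene():
    return GeneAnnotation(gene_id="geneB", seq_id="chr", start=1000, end=2000, strand="-")
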
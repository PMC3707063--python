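import numpy as np
import pytest

from hybridome import simulate
from hybridome.config import AnalysisConfig


@pytest.fixture(scope="session")
def small_genome():
    """Two 500 kb chromosomes, 100 genes, 50% TE density."""
    ann = simulate.make_genome(2, 500_000, 100, 0.5, seed=7)
    ann.validate()
    return ann


@pytest.fixture(scope="session")
def planted_libs(small_genome):
    """Counts for the full design with planted modes (fold 4 parents/hybrids)."""
    truth = simulate.plant_modes(small_genome.gene_ids, seed=11)
    libs = simulate.simulate_counts(
        small_genome, simulate.Design(), truth, dispersion=0.01, seed=12,
        depth=200_000,
    )
    return libs, truth


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
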
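import numpy as np
import pytest

from ufcpred import simdata
from ufcpred.genmap import GeneticMap, build_genetic_map
from ufcpred.meiosis import haldane_inverse


@pytest.fixture(scope="session")
def gmap_small() -> GeneticMap:
    """Seven chromosomes x 10 markers, 150 cM each."""
    return build_genetic_map(7, 10, 150.0, seed=7)


@pytest.fixture()
def two_locus_map():
    """Factory for a one-chromosome, two-marker map at a given r."""

    def make(r: float) -> GeneticMap:
        d = haldane_inverse(r) if r < 0.5 else 1e6
        return GeneticMap(
            np.array(["mA", "mB"], object),
            np.array(["1", "1"], object),
            np.array([0.0, float(d)]),
        )

    return make


@pytest.fixture(scope="session")
def tiny_program() -> simdata.ProgramDataset:
    """Two-cycle, ~60-line programme used by scenario/schema tests."""
    config = simdata.ProgramConfig(
        markers_per_chrom=40,
        n_founders=12,
        cycle_sizes=(30, 40),
        n_families=6,
        n_envs_per_cycle=4,
        mean_envs_per_genotype=2.5,
    )
    return simdata.simulate_program(config, seed=11)


@pytest.fixture(scope="session")
def small_program() -> simdata.ProgramDataset:
    """Quarter-of-a-quarter scale five-cycle programme (fast, realistic shape)."""
    config = simdata.ProgramConfig(scale=0.08, markers_per_chrom=60,
                                   n_founders=30, n_envs_per_cycle=4)
    return simdata.simulate_program(config, seed=5)
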
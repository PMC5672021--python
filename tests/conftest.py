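import numpy as np
import pytest

from plastomics.simulate import build_template, simulate_dataset


@pytest.fixture(scope="session")
def sim42():
    """The standard study-like scenario: 13 taxa, IR expansion, 4 inversions."""
    return simulate_dataset("reduced", seed=42)


@pytest.fixture(scope="session")
def reduced_template():
    return build_template("reduced", seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20170)


def by_id(sim, genome_id):
    for g in sim.genomes:
        if g.id == genome_id:
            return g
    raise KeyError(genome_id)
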
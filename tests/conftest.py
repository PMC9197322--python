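import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from ssrscape.mining import MiningThresholds, SequenceRecord
from ssrscape.simulate import SimConfig, simulate_genotypes, simulate_reference


@pytest.fixture(scope="session")
def thresholds() -> MiningThresholds:
    return MiningThresholds()


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(
        seed=7,
        n_chrom=2,
        chrom_length=80_000,
        loci_per_chrom=24,
        n_genotypes=3,
        variant_rate=0.3,
        compound_fraction=0.15,
        strand_flip_prob=0.25,
    )


@pytest.fixture(scope="session")
def sim_reference(sim_config):
    return simulate_reference(sim_config)


@pytest.fixture(scope="session")
def sim_genotypes(sim_reference, sim_config):
    return simulate_genotypes(sim_reference, sim_config)


@pytest.fixture(scope="session")
def sim_genome(sim_reference) -> dict[str, SequenceRecord]:
    return {r.id: r for r in sim_reference.records}
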
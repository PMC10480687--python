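import numpy as np
import pytest

from replift import (
    ChainIndex,
    GenomeSource,
    LocusSpec,
    build_chains,
    make_repeat_genome,
)


def random_consensus(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def toy_consensus() -> dict[str, str]:
    return {"L1toy": random_consensus(600, seed=12345)}


@pytest.fixture(scope="session")
def fixture(toy_consensus):
    """A moderately diverged 20-instance fixture used across the suite."""
    return make_repeat_genome(
        toy_consensus,
        n_instances=20,
        sub_rate=0.08,
        indel_rate=0.01,
        minus_fraction=0.4,
        spacer_len=500,
        seed=7,
    )


@pytest.fixture(scope="session")
def chains(fixture):
    return build_chains(
        fixture.align_records, fixture.consensus_sizes(), fixture.chrom_sizes()
    )


@pytest.fixture(scope="session")
def chain_index(chains):
    return ChainIndex(chains)


@pytest.fixture(scope="session")
def genome_source(fixture):
    return GenomeSource(fixture.genome)


@pytest.fixture(scope="session")
def planted_locus():
    return LocusSpec("L1toy", 300, 320)
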
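import numpy as np
import pytest

from prdm9bind.genome import fragments_to_coverage
from prdm9bind.simulate import (
    SimConfig,
    genome_index_for,
    simulate_chip,
    simulate_genome,
    simulate_repeat_family,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A 500-kb genome with 60 planted sites: small enough for unit tests,
    large enough for the peak caller to see both ploidy blocks."""
    return SimConfig(
        genome_length=500_000,
        gc_block_length=100_000,
        ploidy_blocks=((100_000, 150_000, 1.5), (300_000, 350_000, 3.0)),
        n_sites=60,
        n_repeat_copies=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    seq, truth = simulate_genome(small_cfg)
    return seq, truth


@pytest.fixture(scope="session")
def small_tracks(small_cfg, small_sim):
    _, truth = small_sim
    rep1, rep2, inp = simulate_chip(truth, small_cfg)
    gidx = genome_index_for(small_cfg)
    return (
        fragments_to_coverage(rep1, gidx, "rep1"),
        fragments_to_coverage(rep2, gidx, "rep2"),
        fragments_to_coverage(inp, gidx, "input"),
    )


@pytest.fixture(scope="session")
def small_fragments(small_cfg, small_sim):
    _, truth = small_sim
    return simulate_chip(truth, small_cfg)


@pytest.fixture(scope="session")
def small_repeats(small_cfg):
    copies, truth = simulate_repeat_family(small_cfg)
    return copies, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20_170)
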
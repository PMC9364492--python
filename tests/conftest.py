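"""Shared fixtures: small seeded genomes and read sets."""

import numpy as np
import pytest

import ucrsim as u


@pytest.fixture(scope="session")
def tetra_genome():
    """Allotetraploid, 60 kb per subgenome, 5% divergence, 0.22% heterozygosity."""
    g = u.make_subgenomes(60_000, 0.05, (5_000, 5_000), seed=101)
    return u.add_heterozygosity(g, 0.0022, seed=102)


@pytest.fixture(scope="session")
def diploid_genome():
    """Diploid control: one subgenome, no divergence, no heterozygosity."""
    return u.make_subgenomes(60_000, 0.0, (5_000, 5_000), seed=103,
                             n_subgenomes=1)


@pytest.fixture(scope="session")
def ont_reads(tetra_genome):
    return u.simulate_long_reads(tetra_genome, 10, (8_000, 1_000),
                                 u.ONT_PROFILE, seed=104)


@pytest.fixture(scope="session")
def clean_long_reads(tetra_genome):
    return u.simulate_long_reads(tetra_genome, 10, (8_000, 1_000),
                                 u.ERROR_FREE, seed=105)


@pytest.fixture(scope="session")
def tetra_run():
    """A small self-correction run on an allotetraploid (no heterozygosity)."""
    g = u.make_subgenomes(80_000, 0.05, (5_000, 5_000), seed=51)
    reads = u.simulate_long_reads(g, 25, (8_000, 1_000), u.ONT_PROFILE,
                                  seed=52)
    graph = u.find_overlaps(reads, g, 2_000)
    corrected = u.correct_reads(reads, graph)
    return g, reads, graph, corrected
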
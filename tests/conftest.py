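import pytest

from slicerscan.simulate import (SimulationConfig, build_toy_genome,
                                 simulate_library)


@pytest.fixture(scope="session")
def default_sim():
    """One standard synthetic run (seed 0), shared read-only across tests."""
    cfg = SimulationConfig(seed=0)
    genome, loci = build_toy_genome(cfg)
    gfp = simulate_library(genome, loci, "gfp_kd", cfg)
    dcr1 = simulate_library(genome, loci, "dcr1_kd", cfg)
    return cfg, genome, loci, gfp, dcr1


@pytest.fixture(scope="session")
def small_sim():
    """A lighter simulation for round-trip and IO tests."""
    cfg = SimulationConfig(seed=5, library_depth=15_000, n_background=500)
    genome, loci = build_toy_genome(cfg)
    lib = simulate_library(genome, loci, "gfp_kd", cfg)
    return cfg, genome, loci, lib
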
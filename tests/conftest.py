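"""Shared fixtures: a small simulated study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from tismap.config import PipelineConfig
from tismap.simulate import Simulation, paperlike_simulation, simulate_reads

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim() -> Simulation:
    """Desk-scale study: 3 x 120 kb chromosomes, 8 planted insertions, 15x."""
    return paperlike_simulation(seed=7, chrom_len=120_000)


@pytest.fixture(scope="session")
def small_sim_clean_reads(small_sim) -> list:
    """Error-free reads over the same modified genome."""
    reads, _ = simulate_reads(small_sim.modified_genome, small_sim.params.error_free())
    return reads


@pytest.fixture(scope="session")
def small_run(small_sim, small_sim_clean_reads):
    """Full pipeline output on the error-free small study."""
    from tismap.pipeline import run_pipeline

    sites, density, report = run_pipeline(
        PipelineConfig(),
        small_sim_clean_reads,
        small_sim.plasmid,
        small_sim.unit,
        small_sim.genome,
        genes=small_sim.genes,
        peaks=small_sim.peaks,
    )
    return sites, density, report
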
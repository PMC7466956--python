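"""Shared fixtures: small synthetic genomes and experiments.

Everything is generated programmatically at test time; session scope keeps
the larger simulations to one run per session.
"""

from __future__ import annotations

import logging

import pytest

from mamut.simulate import (
    SimulationConfig,
    generate_genome,
    simulate_ma_lines,
)

logging.getLogger("mamut").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A 120 kb two-chromosome genome with study-like composition."""
    return SimulationConfig(
        genome_length=120_000,
        n_chromosomes=2,
        n_lines=6,
        generations_per_line=25,
        mu_bs=2.0e-6,
        mu_indel=1.0e-6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_genome):
    return simulate_ma_lines(small_genome, small_config)


@pytest.fixture(scope="session")
def megabase_genome():
    """A 1 Mb genome at study-like composition for calibration tests."""
    cfg = SimulationConfig(
        genome_length=1_000_000,
        n_chromosomes=2,
        n_lines=37,
        generations_per_line=20,
        mu_bs=2.5e-6,
        mu_indel=4.93e-6,
        seed=2024,
    )
    return generate_genome(cfg)
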
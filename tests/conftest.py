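"""Shared fixtures: simulated datasets at two scales.

The session-scoped ``full_benchmark`` runs the complete twelve-ratio
titration at study scale (16,569 bp, 88 SNVs + 2 insertions, 3,000X) once
and is shared by the acceptance tests; the small fixtures are for fast unit
tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from circvar.pipeline import analyse_sample
from circvar.simulate import (
    MixtureDesign,
    make_haplotypes,
    run_benchmark,
    simulate_reads,
)

FULL_SEED = 20177


@pytest.fixture(scope="session")
def full_design() -> MixtureDesign:
    return MixtureDesign(seed=FULL_SEED)


@pytest.fixture(scope="session")
def full_benchmark(full_design):
    return run_benchmark(full_design)


@pytest.fixture(scope="session")
def small_design() -> MixtureDesign:
    return MixtureDesign(length=3000, n_snvs=12, coverage=200.0, seed=5)


@pytest.fixture(scope="session")
def small_haplotypes(small_design):
    return make_haplotypes(small_design)


@pytest.fixture(scope="session")
def small_sim(small_design, small_haplotypes):
    """One 50/50 mixture of the small design."""
    ref, truth = small_haplotypes
    rng = np.random.default_rng(42)
    return simulate_reads(small_design, ref, truth, 50.0, rng)


@pytest.fixture(scope="session")
def small_rows(small_design, small_haplotypes, small_sim):
    ref, _ = small_haplotypes
    return analyse_sample(small_sim.records_original, small_sim.records_shifted, ref)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
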
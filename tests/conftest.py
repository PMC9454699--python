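"""Shared fixtures.

The planted-signal cohort and the small GA run on it are session-scoped:
the run is the package's headline computation and several tests read
different aspects of the same trace (activation schedule, elitism
monotonicity, planted-gene recovery, transfer to a sibling cohort).
"""

import numpy as np
import pytest

from stratga import GAConfig, SimConfig, run_ga, simulate_cohort

SIM_SEED = 7
TRANSFER_SIM_SEED = 8
GA_SEED = 11


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=SIM_SEED)


@pytest.fixture(scope="session")
def cohort_truth(sim_config):
    return simulate_cohort(sim_config)


@pytest.fixture(scope="session")
def cohort(cohort_truth):
    return cohort_truth[0]


@pytest.fixture(scope="session")
def truth(cohort_truth):
    return cohort_truth[1]


@pytest.fixture(scope="session")
def small_cohort_truth():
    """A quick cohort for unit tests that only need valid structure."""
    cfg = SimConfig(
        n_samples=80, n_prognostic_pos=5, n_prognostic_neg=5,
        n_noise_genes=30, seed=3,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_truth):
    return small_cohort_truth[0]


@pytest.fixture(scope="session")
def recovery_ga_config():
    """Scaled-down GA: 4 islands x 50 chromosomes, patience 5."""
    return GAConfig(
        n_subpopulations=4, subpop_size=50, stagnation_patience=5,
        seed=GA_SEED, max_generations=400,
    )


@pytest.fixture(scope="session")
def recovery_run(cohort, recovery_ga_config):
    """One full GA run on the planted-signal cohort: (GeneSetResult, GAState)."""
    return run_ga(cohort, recovery_ga_config)
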
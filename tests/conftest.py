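"""Shared fixtures: a default-scale truth bundle and a miniature
experiment configuration that runs in seconds."""

import numpy as np
import pytest

from imputefilter.pipeline import ExperimentConfig
from imputefilter.synthetic_data import SimulationConfig, simulate_truth_bundle


def small_sim_config(**overrides) -> SimulationConfig:
    """A miniature simulation: seconds, not minutes."""
    params = dict(
        n_ref_haplotypes=120, n_study=80, region_length_bp=30_000,
        n_sites=400, n_typed=50, n_founders=80, seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def small_experiment_config(**overrides) -> ExperimentConfig:
    params = dict(simulation=small_sim_config(), masking=0.5, masking_folds=2)
    params.update(overrides)
    return ExperimentConfig(**params)


@pytest.fixture(scope="session")
def default_bundle():
    """The default-scale truth bundle (the study conditions)."""
    return simulate_truth_bundle(SimulationConfig())


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_truth_bundle(small_sim_config())


@pytest.fixture(scope="session")
def small_result():
    """One miniature end-to-end experiment, shared across tests."""
    from imputefilter.pipeline import run_experiment

    return run_experiment(small_experiment_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
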
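"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import wsigomp as w

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_markers():
    return w.simulate_genotypes(60, 80, seed=101)


@pytest.fixture(scope="session")
def small_truth(small_markers):
    arch, truth = w.simulate_true_effects(
        small_markers, n_qtl=4, heritability=0.8, seed=102
    )
    return arch, truth


@pytest.fixture(scope="session")
def small_trajectories(small_markers, small_truth):
    _, truth = small_truth
    design = w.DesignSpec(n_accessions=60, n_replicated=6, n_experiments=2)
    return w.simulate_experiment(
        small_markers, truth, design=design, noise_cv=0.05, seed=103
    )


@pytest.fixture(scope="session")
def drought_balance():
    """One noiseless drought water balance for a typical genotype."""
    params = w.GrowthParams(psa_max=200.0, r=8.0, alpha=1.5)
    return params, w.simulate_water_balance("drought", params)
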
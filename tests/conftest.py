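import numpy as np
import pytest

from declust.core_model import (
    CompartmentFractions,
    CompartmentProfiles,
    ExpressionMatrix,
    SubtypeAssignment,
    reconstruct_mixture,
)
from declust.optimizer import OptimizerConfig
from declust.simulator import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_instance(rng):
    """Random consistent 5-gene x 4-sample model instance plus its exact mixture."""
    G, S, K = 5, 4, 2
    profiles = CompartmentProfiles(rng.normal(2, 1, (G, K)),
                                   rng.normal(2, 1, G), rng.normal(2, 1, G))
    frac = rng.dirichlet([5, 2, 2], size=S)
    fractions = CompartmentFractions.from_array(frac)
    assignment = SubtypeAssignment(rng.integers(1, K + 1, S), K)
    observed = reconstruct_mixture(profiles, fractions, assignment)
    return observed, profiles, fractions, assignment


@pytest.fixture(scope="session")
def exact_dataset():
    """Zero-noise cohort following the mixture identity exactly."""
    cfg = SimulationConfig(n_genes=200, n_samples=40, n_subtypes=3,
                           noise_level=0.0,
                           target_noncancer_profile_correlation=1.0, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Small noisy cohort with the default correlation structure."""
    cfg = SimulationConfig(n_genes=200, n_samples=40, n_subtypes=3,
                           noise_level=0.3, seed=8)
    return simulate_dataset(cfg)


@pytest.fixture
def fast_config():
    return OptimizerConfig(seed=0, kmeans_restarts=5, profile_maxiter=150,
                           fraction_maxiter=150, grid_maxiter=40,
                           max_outer_iter=5)
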
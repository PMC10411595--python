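import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strainexpr import SimulationConfig, filter_low_counts, simulate_experiment
from strainexpr import size_factors as compute_size_factors

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_bundle():
    """Default study-scale simulation: 5 strains x 3 treatments x 3 reps."""
    config = SimulationConfig(seed=1)
    matrix, design, truth = simulate_experiment(config)
    return config, matrix, design, truth


@pytest.fixture(scope="session")
def fitted_bundle(study_bundle):
    """Filtered matrix with size factors and true (planted) dispersions."""
    config, matrix, design, truth = study_bundle
    filtered = filter_low_counts(matrix)
    sf = compute_size_factors(filtered)
    idx = {g: i for i, g in enumerate(truth.gene_ids)}
    alpha = np.array([truth.alpha[idx[g]] for g in filtered.gene_ids])
    return config, filtered, design, truth, sf, alpha


@pytest.fixture(scope="session")
def null_bundle():
    """Null simulation: no planted effects of any kind."""
    config = SimulationConfig(seed=11, frac_strain_de=0.0, frac_interaction=0.0,
                              frac_off=0.0)
    matrix, design, truth = simulate_experiment(config)
    return config, matrix, design, truth
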
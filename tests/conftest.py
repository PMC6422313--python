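import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def baseline_trials():
    """30 constrained trials of the baseline rho=0.93 position-width model."""
    from lateralstep import ConstraintSpec, SimulationConfig, simulate_trials
    from lateralstep.experiments import baseline_position_width_model

    model = baseline_position_width_model()
    config = SimulationConfig(n_steps=290, n_trials=30, seed=1)
    return simulate_trials(model, config, ConstraintSpec())


@pytest.fixture(scope="session")
def reference_fixture():
    """Full-size synthetic reference set (65 x 290) and its bands."""
    from lateralstep.experiments import generate_reference_fixture

    return generate_reference_fixture(seed=11)
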
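import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fs() -> float:
    return 1000.0


@pytest.fixture(scope="session")
def coupled_recording():
    """One strongly coupled 60 s stochastic-theta signal, reused across tests."""
    from mazelfp.synthetic import CouplingSpec, generate_coupled_process

    return generate_coupled_process(
        CouplingSpec(coupling_strength=0.8), duration=60.0, fs=1000.0, seed=7
    )


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic session shared by pipeline-level tests."""
    from mazelfp.synthetic import SessionSpec, generate_session

    spec = SessionSpec(
        pre_maze_duration=30.0, n_trials=2, trial_durations=10.0,
        platform_duration=10.0, seed=11,
    )
    return spec, generate_session(spec)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
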
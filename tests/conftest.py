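import numpy as np
import pytest

from behavosc import (
    ExperimentConfig,
    FRAME_MS,
    ObserverModel,
    SpectralSettings,
    generate_experiment,
)


@pytest.fixture(scope="session")
def small_config():
    """A small but complete experiment: 3 subjects x 2 sessions, 5 delays."""
    return ExperimentConfig(
        n_subjects=3,
        n_sessions=2,
        delay_grid_ms=tuple(np.arange(19, 24) * FRAME_MS),
        trials_per_delay=8,
        control_trials_per_delay=1,
        catch_rate=0.1,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_observers(small_config):
    return [
        ObserverModel(soa_threshold_ms=30.0 + 10.0 * i) for i in range(small_config.n_subjects)
    ]


@pytest.fixture(scope="session")
def small_trials(small_config, small_observers):
    return generate_experiment(small_config, small_observers)


@pytest.fixture
def settings():
    return SpectralSettings()
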
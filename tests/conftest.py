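import numpy as np
import pytest

from skigears import (GEARS, PreprocessConfig, SimulationConfig,
                      extract_cycles, simulate_trial, train_classifier)


@pytest.fixture(scope="session")
def default_cfg():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def trained_classifier():
    """Classifier fitted on 50 synthetic cycles per gear at default noise."""
    cycles = {}
    for i, gear in enumerate(GEARS):
        stream, _ = simulate_trial(gear, 50, SimulationConfig(seed=101 + i))
        cycles[gear] = extract_cycles(stream)
    return train_classifier(cycles)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
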
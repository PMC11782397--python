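import numpy as np
import pytest

from gaitfatigue.simulate import (
    GaitTemplate,
    NoiseSpec,
    simulate_recording,
)


@pytest.fixture(scope="session")
def template():
    return GaitTemplate()


@pytest.fixture(scope="session")
def clean_recording(template):
    """A short noise-free recording (drift on) with its ground-truth table."""
    rec, truth = simulate_recording(
        template,
        "non_fatigue",
        duration_s=20.0,
        noise=NoiseSpec(0.0, 0.0, 0.0, 0.0, drift_deg_per_s=0.05),
        seed=11,
    )
    return rec, truth


@pytest.fixture(scope="session")
def noisy_recording(template):
    rec, truth = simulate_recording(
        template, "non_fatigue", duration_s=30.0, noise=NoiseSpec(), seed=23
    )
    return rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
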
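import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phonodeform import (
    NetworkConfig,
    SynthesisSpec,
    load_laryngopathy_dataset,
    synth_phoneme,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    return load_laryngopathy_dataset()


@pytest.fixture(scope="session")
def periodic_window():
    """256 samples (4 cycles of period 64) of a zero-perturbation vowel."""
    signal = synth_phoneme(SynthesisSpec(n_cycles=5, base_period=64, seed=0))
    return signal.samples[:256]


@pytest.fixture
def fast_config():
    return NetworkConfig(max_epochs=50, seed=0)


def random_consistent_table(rng, n_cases, n_attrs=2):
    """A random numeric decision table with distinct values per attribute
    (hence consistent) and at least two decision labels."""
    from phonodeform import DecisionSystem

    while True:
        values = np.round(rng.uniform(0, 10, size=(n_cases, n_attrs)), 3)
        if any(len(np.unique(values[:, j])) < n_cases for j in range(n_attrs)):
            continue
        labels = rng.choice(["no", "yes"], size=n_cases)
        if len(set(labels)) > 1:
            break
    return DecisionSystem(
        tuple(f"c{i}" for i in range(n_cases)),
        tuple(f"a{j + 1}" for j in range(n_attrs)),
        tuple(tuple(float(v) for v in row) for row in values),
        tuple(labels),
    )
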
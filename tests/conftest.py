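import numpy as np
import pytest

from fallverify import (
    Incident,
    SimulationConfig,
    generate_dataset,
    make_fixtures,
)


@pytest.fixture(scope="session")
def dataset86():
    """Canonical seeded dataset: 41 falls + 45 lean-overs, default noise."""
    dataset, _ = make_fixtures()
    return dataset


@pytest.fixture(scope="session")
def mini10():
    """Noise-free 10-incident set with exact closed-form trajectories."""
    _, mini = make_fixtures()
    return mini


@pytest.fixture(scope="session")
def noisefree86():
    """Default study conditions but zero sensor noise (separable classes)."""
    return generate_dataset(SimulationConfig(height_noise_sd=0.0, seed=7))


def linear_descent(duration=1.0, h0=1.0, n=11, ident="lin", label=None):
    """Straight-line descent h(t) = h0 (1 - t/T): analytic crossing times."""
    t = np.linspace(0.0, duration, n)
    return Incident(id=ident, t=t, h=h0 * (1 - t / duration), label=label)
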
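import numpy as np
import pytest

from gradsig import ExpressionProfile, SimulationSpec, generate_replicate


@pytest.fixture(scope="session")
def default_spec() -> SimulationSpec:
    """The documented default simulation conditions (small replicate budget)."""
    return SimulationSpec(n_reps=20)


@pytest.fixture(scope="session")
def noisy_replicate(default_spec):
    """(truth, noisy) pair for replicate 0 of the default conditions."""
    return generate_replicate(default_spec, 0)


@pytest.fixture()
def simple_profile() -> ExpressionProfile:
    x = np.linspace(0.0, 100.0, 21)
    y = 100.0 * np.exp(-x / 25.0)
    return ExpressionProfile("simple", x, y, "simulated_truth")
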
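import numpy as np
import pytest

import gsiskit as gk


@pytest.fixture(scope="session")
def model():
    """Default β-cell GSIS model (reference/ground-truth parameterization)."""
    return gk.build_model()


@pytest.fixture(scope="session")
def default_scan(model):
    """11-point steady-state glucose scan of the default model."""
    return gk.dose_response_scan(model, np.linspace(1.0, 35.0, 11))


@pytest.fixture(scope="session")
def step_trajectory(model):
    """Basal-to-stimulated protocol trajectory (3 -> 16.7 mM)."""
    return gk.run_protocol(model, gk.Protocol(3.0, 16.7))
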
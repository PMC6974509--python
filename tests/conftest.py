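import numpy as np
import pytest

from petkin import (
    InputFunctionSpec,
    KineticParameters,
    default_schedule,
)

#: Published whole-brain group-mean rate constants used as canonical
#: ground-truth sets throughout the suite.
WHOLE_BRAIN_ROWS = {
    ("RRMS", "GM"): dict(K1=0.087, k2=0.535, k3=0.035, k4=0.020, VB=0.075),
    ("HC", "GM"): dict(K1=0.085, k2=0.686, k3=0.032, k4=0.029, VB=0.075),
    ("RRMS", "WM"): dict(K1=0.062, k2=0.378, k3=0.043, k4=0.032, VB=0.057),
    ("HC", "WM"): dict(K1=0.062, k2=0.526, k3=0.057, k4=0.058, VB=0.054),
}


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def input_spec():
    return InputFunctionSpec()


@pytest.fixture(scope="session")
def true_inputs(input_spec):
    """Noise-free default input-function set."""
    return input_spec.true_input_set()


@pytest.fixture(scope="session")
def gm_rrms_params():
    return KineticParameters("2T4k", **WHOLE_BRAIN_ROWS[("RRMS", "GM")])


def random_2t4k(rng, model_id="2T4k"):
    """A random plausible reversible two-tissue parameter set."""
    K1 = rng.uniform(0.02, 0.4)
    k2 = rng.uniform(0.1, 1.5)
    k3 = rng.uniform(0.0, 0.3)
    k4 = rng.uniform(0.01, 0.4)
    VB = rng.uniform(0.0, 0.2)
    return KineticParameters(model_id, K1=K1, k2=k2, k3=k3, k4=k4, VB=VB)
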
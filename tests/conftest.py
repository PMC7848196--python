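import numpy as np
import pytest

import circabp as c

SEED = 20210118


def constant_inputs(a=100.0, ne=2.5, glc=5.0, n=48):
    """Constant forcing signals on the standard half-hour grid."""
    grid = c.half_hour_grid(n)
    return c.InputSignals(grid=grid, A=np.full(n, a), NE=np.full(n, ne),
                          glc=np.full(n, glc), mode="linear")


@pytest.fixture(scope="session")
def dipper_inputs():
    return c.make_inputs("dipper")


@pytest.fixture(scope="session")
def nondipper_inputs():
    return c.make_inputs("non_dipper")


@pytest.fixture(scope="session")
def dipper_init(dipper_inputs):
    return c.default_initial_state(c.REFERENCE_DIPPER, dipper_inputs)


@pytest.fixture(scope="session")
def clean_dipper_dataset(dipper_inputs):
    """Noise-free dataset: exact model output at the reference parameters."""
    return c.generate_dataset(c.REFERENCE_DIPPER, dipper_inputs,
                              noise_cv=0.0, seed=SEED)


@pytest.fixture(scope="session")
def noisy_dipper_dataset(dipper_inputs):
    return c.generate_dataset(c.REFERENCE_DIPPER, dipper_inputs,
                              noise_cv=0.01, seed=SEED)


@pytest.fixture(scope="session")
def dipper_trajectory(dipper_inputs, dipper_init):
    return c.simulate(c.REFERENCE_DIPPER, dipper_inputs, dipper_init,
                      dipper_inputs.grid)


@pytest.fixture(scope="session")
def dipper_sensitivities(dipper_inputs, dipper_init):
    return c.local_sensitivities(c.REFERENCE_DIPPER, dipper_inputs,
                                 dipper_init, dipper_inputs.grid)
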
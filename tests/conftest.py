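import numpy as np
import pytest

from craniosex import female_params, male_params

# Printed degree-6 fit of the male frontal arc (constant term first).
Y1_COEFFS = np.array([-8.6663, -1.4380, -2.3911, -3.9862,
                      1.0611, -4.0991, -3.2628])


@pytest.fixture(scope="session")
def y1_landmarks():
    """18 noiseless landmarks sampled from the printed male arc polynomial."""
    x = np.linspace(-1.0, 1.0, 18)
    y = np.polynomial.polynomial.polyval(x, Y1_COEFFS)
    return np.column_stack([x, y, np.zeros(18)])


@pytest.fixture(scope="session")
def quiet_male():
    return male_params(noise_sd=0.0)


@pytest.fixture(scope="session")
def quiet_female():
    return female_params(noise_sd=0.0)
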
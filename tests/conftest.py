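import numpy as np
import pytest

from gmorpho.synthetic import make_template
from gmorpho.tps import bending_spectrum


@pytest.fixture(scope="session")
def humerus_template():
    return make_template("humerus36")


@pytest.fixture(scope="session")
def humerus_spectrum(humerus_template):
    return bending_spectrum(humerus_template[0].points)


@pytest.fixture(scope="session")
def small_reference():
    """A 12-point smooth outline: big enough for warps, cheap to decompose."""
    theta = 2 * np.pi * np.arange(12) / 12
    r = 1 + 0.2 * np.cos(2 * theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pts -= pts.mean(axis=0)
    return pts / np.sqrt((pts ** 2).sum())


@pytest.fixture(scope="session")
def small_spectrum(small_reference):
    return bending_spectrum(small_reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
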
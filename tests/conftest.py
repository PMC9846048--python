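import warnings
from dataclasses import replace

import numpy as np
import pytest

from lcicquant import analyze_section, generate_section, preset


@pytest.fixture(scope="session")
def c3_p8():
    """One C3/GAD section at P8 with ground truth (fixed seed)."""
    return generate_section(replace(preset("C3", "P8"), seed=11))


@pytest.fixture(scope="session")
def c3_p8_result(c3_p8):
    image, _ = c3_p8
    return analyze_section(image, section_id="c3p8", age="P8")


@pytest.fixture(scope="session")
def cd11b_p8():
    return generate_section(replace(preset("CD11b", "P8"), seed=5))


@pytest.fixture(scope="session")
def iba1_p8():
    return generate_section(replace(preset("Iba1", "P8"), seed=7))


@pytest.fixture
def quiet():
    """Silence expected pipeline warnings (contour clipping etc.)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def make_total(shape=(64, 96), margin=8):
    total = np.zeros(shape, dtype=bool)
    total[margin : shape[0] - margin, margin : shape[1] - margin] = True
    return total
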
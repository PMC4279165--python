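import numpy as np
import pytest

from chaperokin import ExperimentCondition, preset


@pytest.fixture(scope="session")
def i154f():
    return preset("I154F")


@pytest.fixture(scope="session")
def d122y():
    return preset("D122Y")


@pytest.fixture(scope="session")
def wt():
    return preset("WT")


@pytest.fixture()
def standard_condition():
    """The study's reference condition: 3 µM chaperonin, 2 µM protein."""
    return ExperimentCondition(el_conc=3.0, protein0=2.0)


@pytest.fixture()
def minute_grid():
    return np.linspace(0.0, 60.0, 61)
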
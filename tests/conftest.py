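import numpy as np
import pytest

from shieldfit.chelator import AssaySolution, load_constants
from shieldfit.shielding import load_default_cations, load_default_params


@pytest.fixture(scope="session")
def params():
    return load_default_params()


@pytest.fixture(scope="session")
def cations():
    return load_default_cations()


@pytest.fixture(scope="session")
def constants():
    return load_constants()


@pytest.fixture
def base_solution():
    """The enzyme-assay base solution: 3 mM CaCl2 / 3 mM EGTA, pH 7.3,
    ionic strength 0.073, 20 C."""
    return AssaySolution(
        metals={"Ca": 3e-3},
        ligands={"EGTA": 3e-3},
        ph=7.3,
        ionic_strength=0.073,
        temperature=293.15,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20151211)
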
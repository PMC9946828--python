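import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from famhal.fixtures import (ToyFamilySpec, make_planted_problem,
                             make_synthetic_design_model, make_toy_family)
from famhal.geometry import BinSpec

PLANTED_18MER = "MKVLAEHGFDWITNRSQY"


@pytest.fixture(scope="session")
def bin_spec():
    return BinSpec.default()


@pytest.fixture(scope="session")
def planted_spec():
    return ToyFamilySpec(planted_sequence=PLANTED_18MER)


@pytest.fixture(scope="session")
def planted_problem(planted_spec):
    """The shared 18-mer planted toy problem (construction self-verifies)."""
    return make_planted_problem(planted_spec, seed=1)


@pytest.fixture(scope="session")
def toy_family(planted_spec):
    return make_toy_family(planted_spec)


@pytest.fixture(scope="session")
def synthetic_model():
    return make_synthetic_design_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
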
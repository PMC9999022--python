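import warnings

import numpy as np
import pytest

from seqcea.curve_engine import build_all_curves
from seqcea.econ import EconParams
from seqcea.params import load_strategies, load_tariff

# lifelines emits convergence chatter on tiny fixtures; keep output readable
warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


@pytest.fixture(scope="session")
def tariff():
    return load_tariff()


@pytest.fixture(scope="session")
def curves():
    return build_all_curves()


@pytest.fixture(scope="session")
def econ():
    return EconParams.from_table()


@pytest.fixture(scope="session")
def strategy_map():
    return load_strategies()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
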
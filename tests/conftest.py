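import numpy as np
import pytest

from prostox_cea import default_life_table, default_parameters, load_printed_table
from prostox_cea.markov import LifeTable


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def printed_table():
    return load_printed_table()


def make_constant_life_table(q: float, start_age: int = 67,
                             terminal_age: int = 110) -> LifeTable:
    """Life table with constant annual death probability (terminal q = 1)."""
    ages = np.arange(start_age, terminal_age + 1)
    qs = np.full(ages.shape, q, dtype=float)
    qs[-1] = 1.0
    return LifeTable(ages=ages, q=qs)


@pytest.fixture(scope="session")
def zero_mortality_table():
    return make_constant_life_table(0.0)
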
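import numpy as np
import pytest

from hvspop.core import load_reference, load_table3_fixture, load_table4_fixture
from hvspop.haplogroups import load_mt_tree, load_y_panel


@pytest.fixture(scope="session")
def table3():
    return load_table3_fixture()


@pytest.fixture(scope="session")
def table4():
    return load_table4_fixture()


@pytest.fixture(scope="session")
def mt_tree():
    return load_mt_tree()


@pytest.fixture(scope="session")
def y_panel():
    return load_y_panel()


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250925)
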
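import numpy as np
import pytest

from thermolipase import datasets


@pytest.fixture(scope="session")
def table1_records():
    return datasets.load_table1()


@pytest.fixture(scope="session")
def table2():
    return datasets.load_table2()


@pytest.fixture(scope="session")
def table2_ea():
    return datasets.load_table2_ea()


@pytest.fixture(scope="session")
def sp14_70_truth():
    """The most thermostable lipase's 70 degC parameter triple."""
    return {"alpha1": 0.647, "k1": 2.24e-2, "k2": 1.82e-4}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
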
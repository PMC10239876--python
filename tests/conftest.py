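import numpy as np
import pytest

from lbmff import SyntheticSpec, compute_measures, generate


@pytest.fixture(scope="session")
def default_dataset():
    ds, truth = generate(SyntheticSpec())
    return ds, truth


@pytest.fixture(scope="session")
def default_measures(default_dataset):
    ds, _ = default_dataset
    return compute_measures(ds)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230522)
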
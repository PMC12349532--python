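import numpy as np
import pytest

from petsorb.records import build_feature_matrix, minmax_normalize
from petsorb.synth import default_params, generate_dataset


@pytest.fixture(scope="session")
def noiseless_params():
    return default_params(noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_params):
    return generate_dataset(params=noiseless_params, seed=7)


@pytest.fixture(scope="session")
def normalized_features(noiseless_dataset):
    return minmax_normalize(build_feature_matrix(noiseless_dataset))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
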
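import numpy as np
import pytest
from hypothesis import settings

from somscore import build_cluster_model

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def toy_ab():
    """Two 2-point clusters at x=0 and x=10; every index value known by hand."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
    labels = np.array([0, 0, 1, 1])
    return X, labels, build_cluster_model(X, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
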
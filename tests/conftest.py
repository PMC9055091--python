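import numpy as np
import pytest

import pkpdsvr as pk


@pytest.fixture(scope="session")
def mc():
    return pk.load_fixture("mc")


@pytest.fixture(scope="session")
def mcc():
    return pk.load_fixture("mcc")


@pytest.fixture(scope="session")
def toy_line_model():
    """Interpolating fit on 4 collinear 1-D points."""
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0.0, 1.0, 2.0, 3.0])
    return pk.train_svr(X, y, penalty=100.0, sigma=1.0, epsilon=0.01, scale=False), X, y
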
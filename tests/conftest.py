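import numpy as np
import pytest

import cecbbb as c


@pytest.fixture(scope="session")
def table1():
    return c.load_compound_table()


@pytest.fixture(scope="session")
def table1_fit(table1):
    return c.fit_ols(table1)


@pytest.fixture(scope="session")
def separable_traces():
    """Well-separated 3-class trace set (30 per class, replicate groups)."""
    raw, y, manifest = c.simulate_dataset((30, 30, 30), c.TraceSimConfig(), seed=42)
    X = c.preprocess_dataset(raw)
    return X, y, manifest


@pytest.fixture(scope="session")
def separable_cv_report(separable_traces):
    X, y, _ = separable_traces
    return c.nested_cv(X, y, seed=42)


@pytest.fixture(scope="session")
def small_traces():
    """Small separable set for fast classifier checks."""
    raw, y, manifest = c.simulate_dataset((8, 8, 8), c.TraceSimConfig(), seed=7)
    X = c.preprocess_dataset(raw)
    return X, y, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
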
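import numpy as np
import pytest

from dfnckit import WindowSpec, compute_dfnc_tensor, default_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Eight-subject synthetic dataset with its ground truth (seed 7)."""
    return default_fixture(n_subjects=8, seed=7)


@pytest.fixture(scope="session")
def small_tensors(small_fixture):
    tcs, _ = small_fixture
    spec = WindowSpec()
    return [compute_dfnc_tensor(tc, spec) for tc in tcs]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
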
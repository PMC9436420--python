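import numpy as np
import pytest

import ctrestore.nn.autograd as autograd


@pytest.fixture
def float64_engine():
    """Run the autodiff engine in float64 (for numerical gradient checks)."""
    autograd.set_dtype("float64")
    yield
    autograd.set_dtype("float32")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grad(fval, arr, eps=1e-6):
    """Central-difference gradient of scalar fval() w.r.t. arr (in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = arr[i]
        arr[i] = x0 + eps
        fp = fval()
        arr[i] = x0 - eps
        fm = fval()
        arr[i] = x0
        g[i] = (fp - fm) / (2 * eps)
    return g
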
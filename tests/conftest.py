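import numpy as np
import pytest

from manet.engine import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_grads(f, params, eps=1e-5):
    """Central-difference gradients of the scalar ``f()`` w.r.t. ``params``.

    Parameters must be float64 tensors; ``f`` re-runs the forward pass and
    reads the current parameter values.
    """
    grads = []
    for p in params:
        flat = p.data.ravel()
        g = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = float(f())
            flat[i] = orig - eps
            fm = float(f())
            flat[i] = orig
            g[i] = (fp - fm) / (2 * eps)
        grads.append(g.reshape(p.data.shape))
    return grads


def check_grads(f, params, atol=1e-6, rtol=1e-4):
    """Compare analytic backward() gradients against central differences."""
    for p in params:
        p.grad = None
    out = f()
    out.backward()
    num = numeric_grads(f, params)
    for p, n in zip(params, num):
        assert p.grad is not None, "missing analytic gradient"
        np.testing.assert_allclose(p.grad, n, atol=atol, rtol=rtol)


def tensor64(rng, *shape, requires_grad=True):
    return Tensor(rng.standard_normal(shape), requires_grad=requires_grad)
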
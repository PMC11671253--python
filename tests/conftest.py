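import numpy as np
import pytest

from gcalink.autodiff import Tensor
from gcalink.synthetic import SyntheticConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_ds():
    """20x8 planted-block dataset, dense enough for 5-fold splits."""
    return generate(SyntheticConfig(n_m=20, n_d=8, n_blocks=2,
                                    p_in=0.6, p_out=0.05, seed=7))


def finite_diff_grad(f, arrays, h=1e-6):
    """Central finite-difference gradients of f(list of ndarrays) -> scalar."""
    grads = []
    for k, x in enumerate(arrays):
        g = np.zeros_like(x, dtype=np.float64)
        flat = x.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            fp = f(arrays)
            flat[i] = orig - h
            fm = f(arrays)
            flat[i] = orig
            gflat[i] = (fp - fm) / (2 * h)
        grads.append(g)
    return grads


def check_gradients(build_loss, arrays, rtol=1e-4, atol=1e-6):
    """Compare autodiff gradients of build_loss(tensors) with finite diffs."""
    tensors = [Tensor(a.copy(), requires_grad=True) for a in arrays]
    loss = build_loss(tensors)
    loss.backward()

    def numeric(arrs):
        ts = [Tensor(a) for a in arrs]
        return float(build_loss(ts).data)

    expected = finite_diff_grad(numeric, [a.copy() for a in arrays])
    for t, e in zip(tensors, expected):
        g = t.grad if t.grad is not None else np.zeros_like(e)
        np.testing.assert_allclose(g, e, rtol=rtol, atol=atol)
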
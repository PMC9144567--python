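import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def isruc_graph():
    from somnograph.graph import SleepGraph, load_montage

    labels, edges = load_montage("isruc6")
    return SleepGraph.from_montage(labels, edges=edges)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """The default synthetic study: 4 subjects x 200 epochs, 6 channels."""
    from somnograph.synthetic import SimSpec, simulate_feature_dataset

    x, y, subjects = simulate_feature_dataset(SimSpec(seed=0))
    return x, y, subjects


@pytest.fixture(scope="session")
def tiny_network_inputs(rng):
    """Small random (B, C, T, V) blocks for oracle/gradient checks."""
    return rng.normal(size=(2, 4, 3, 5))


def numeric_gradient(fn, arrays, index, eps=1e-6):
    """Central finite difference of scalar fn w.r.t. arrays[index]."""
    base = [np.array(a, dtype=float) for a in arrays]
    grad = np.zeros_like(base[index])
    it = np.nditer(base[index], flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        plus = [a.copy() for a in base]
        minus = [a.copy() for a in base]
        plus[index][ix] += eps
        minus[index][ix] -= eps
        grad[ix] = (fn(*plus) - fn(*minus)) / (2 * eps)
    return grad


def relative_error(a, b, floor=1e-4):
    """Max elementwise relative difference.

    The denominator floor keeps central-difference noise (~1e-9 in
    float64) from dominating entries whose true gradient is ~0.
    """
    a, b = np.asarray(a), np.asarray(b)
    denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    return float(np.max(np.abs(a - b) / denom))


@pytest.fixture
def gradcheck():
    """Compare autodiff gradients of a scalar-valued tensor function
    against central finite differences, at 1e-4 relative error."""
    from somnograph.autodiff import Tensor

    def check(fn, *arrays, tol=1e-4, eps=1e-6):
        tensors = [Tensor(np.array(a, dtype=float), requires_grad=True)
                   for a in arrays]
        out = fn(*tensors)
        out.backward()

        def scalar(*arrs):
            return fn(*[Tensor(a) for a in arrs]).item()

        for i, t in enumerate(tensors):
            num = numeric_gradient(scalar, arrays, i, eps=eps)
            assert t.grad is not None
            err = relative_error(t.grad, num)
            assert err < tol, f"gradient mismatch on arg {i}: {err:.2e}"

    return check
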
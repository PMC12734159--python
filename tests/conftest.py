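import numpy as np
import pytest

from stripfuse import PhantomSpec, generate_dataset, render_phantom, split_dataset
from stripfuse.autodiff import Tensor


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small split phantom dataset on disk: 8 images/class at 64 px."""
    root = tmp_path_factory.mktemp("phantoms")
    manifest = generate_dataset(n_per_class=8, out_dir=root, seed=11, image_side=64)
    manifest = split_dataset(manifest, seed=11)
    manifest.write(root / "manifest.tsv")
    return root, manifest


def numeric_grad(fn, arrays, eps=1e-5):
    """Central-difference gradients of scalar ``fn`` w.r.t. each input array."""
    grads = []
    for a in arrays:
        g = np.zeros_like(a, dtype=float)
        flat = a.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = fn()
            flat[i] = orig - eps
            lo = fn()
            flat[i] = orig
            gflat[i] = (hi - lo) / (2 * eps)
        grads.append(g)
    return grads


def check_gradients(build, arrays, atol=1e-6, rtol=1e-4):
    """Compare autodiff gradients of ``build(tensors) -> scalar Tensor``
    against central differences on float64 copies of ``arrays``."""
    arrays = [np.asarray(a, dtype=np.float64) for a in arrays]
    tensors = [Tensor(a, requires_grad=True) for a in arrays]
    out = build(*tensors)
    out.backward()
    expected = numeric_grad(lambda: float(build(*[Tensor(a) for a in arrays]).data),
                            arrays)
    for t, e in zip(tensors, expected):
        np.testing.assert_allclose(t.grad, e, atol=atol, rtol=rtol)
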
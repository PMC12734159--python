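"""Convolution/pooling reference primitives and the two backbone blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import correlate2d

from stripfuse.autodiff import Tensor
from stripfuse.nn import (
    BatchNorm2d,
    PoolSpec,
    ResidualBlock,
    ResidualBlockConfig,
    SpatialBlock,
    SpatialBlockConfig,
    conv2d_valid,
    pool,
)

RNG = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# conv2d_valid
# ---------------------------------------------------------------------------


def test_conv_identity_kernel():
    f = RNG.random((5, 6))
    np.testing.assert_allclose(conv2d_valid(f, np.array([[1.0]])), f)


def test_conv_constant_input():
    k = RNG.random((3, 3))
    out = conv2d_valid(np.full((6, 6), 2.5), k)
    np.testing.assert_allclose(out, 2.5 * k.sum())


def test_conv_ramp_all_ones_kernel():
    f = np.arange(16, dtype=float).reshape(4, 4)
    out = conv2d_valid(f, np.ones((2, 2)))
    assert out.shape == (3, 3)
    expected = np.array(
        [[f[i : i + 2, j : j + 2].sum() for j in range(3)] for i in range(3)]
    )
    np.testing.assert_allclose(out, expected)


@pytest.mark.parametrize("m,n,r,s", [(4, 4, 2, 2), (8, 8, 3, 3), (5, 8, 3, 2), (8, 5, 1, 3)])
def test_conv_matches_scipy_correlate(m, n, r, s):
    """Independent oracle: scipy valid cross-correlation, inputs up to 8x8."""
    f = RNG.standard_normal((m, n))
    k = RNG.standard_normal((r, s))
    np.testing.assert_allclose(
        conv2d_valid(f, k), correlate2d(f, k, mode="valid"), atol=1e-6
    )


def test_conv_kernel_too_large():
    with pytest.raises(ValueError):
        conv2d_valid(np.ones((2, 2)), np.ones((3, 3)))


# ---------------------------------------------------------------------------
# pool
# ---------------------------------------------------------------------------


def test_pool_constant_input():
    f = np.full((5, 5), 3.2)
    for kind in ("max", "avg"):
        out = pool(f, PoolSpec(kind, (2, 2), 1))
        np.testing.assert_allclose(out, 3.2)


def test_pool_enumerated_example():
    f = np.arange(1, 17, dtype=float).reshape(4, 4)
    spec22 = PoolSpec("avg", (2, 2), 2)
    np.testing.assert_allclose(pool(f, spec22), [[3.5, 5.5], [11.5, 13.5]])
    np.testing.assert_allclose(
        pool(f, PoolSpec("max", (2, 2), 2)), [[6.0, 8.0], [14.0, 16.0]]
    )


def test_pool_all_window_stride_combos_on_6x6():
    """Brute-force window enumeration via an independent stride-tricks oracle."""
    f = RNG.standard_normal((6, 6))
    for r in range(1, 7):
        for s in range(1, 7):
            for t in range(1, 4):
                win = sliding_window_view(f, (r, s))[::t, ::t]
                np.testing.assert_allclose(
                    pool(f, PoolSpec("max", (r, s), t)), win.max(axis=(2, 3))
                )
                np.testing.assert_allclose(
                    pool(f, PoolSpec("avg", (r, s), t)), win.mean(axis=(2, 3))
                )


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 10_000))
def test_max_pool_dominates_avg_pool(seed):
    f = np.random.default_rng(seed).standard_normal((6, 6))
    spec = PoolSpec("max", (3, 2), 2), PoolSpec("avg", (3, 2), 2)
    assert np.all(pool(f, spec[0]) >= pool(f, spec[1]) - 1e-12)


def test_pool_rejects_bad_specs():
    with pytest.raises(ValueError):
        PoolSpec("max", (2, 2), 0)
    with pytest.raises(ValueError):
        PoolSpec("median", (2, 2), 1)
    with pytest.raises(ValueError):
        pool(np.ones((3, 3)), PoolSpec("max", (4, 4), 1))


# ---------------------------------------------------------------------------
# spatial block
# ---------------------------------------------------------------------------


def test_spatial_block_zero_input_zero_output():
    block = SpatialBlock(SpatialBlockConfig(2, 4, pool="max")).eval()
    out = block(Tensor(np.zeros((1, 2, 8, 8), dtype=np.float32)))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-7)


def test_spatial_block_output_nonnegative():
    block = SpatialBlock(SpatialBlockConfig(2, 4, pool="avg"),
                         rng=np.random.default_rng(0))
    out = block(Tensor(RNG.standard_normal((2, 2, 8, 8)).astype(np.float32)))
    assert out.data.min() >= 0.0
    assert out.data.shape == (2, 4, 4, 4)  # pooling halves the spatial size


def test_spatial_block_matches_primitive_composition():
    """Eval-mode block == conv2d_valid on a padded grid -> BN affine -> ReLU -> pool."""
    rng = np.random.default_rng(3)
    block = SpatialBlock(SpatialBlockConfig(1, 1, pool="max"), rng=rng).eval()
    # freeze hand-set parameters and running statistics
    block.conv.weight.data = rng.standard_normal((1, 1, 3, 3))
    block.conv.bias.data = np.array([0.2])
    block.bn.gamma.data = np.array([[[[1.3]]]])
    block.bn.beta.data = np.array([[[[-0.1]]]])
    block.bn.running_mean[...] = 0.4
    block.bn.running_var[...] = 2.0

    x = rng.standard_normal((8, 8))
    out = block(Tensor(x[None, None]))

    padded = np.pad(x, 1)
    conv = conv2d_valid(padded, block.conv.weight.data[0, 0]) + 0.2
    bn = 1.3 * (conv - 0.4) / np.sqrt(2.0 + block.bn.eps) - 0.1
    relu = np.maximum(bn, 0.0)
    expected = pool(relu, PoolSpec("max", (2, 2), 2))
    np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-5)


def test_spatial_block_rejects_channel_mismatch():
    block = SpatialBlock(SpatialBlockConfig(2, 4))
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 3, 8, 8), dtype=np.float32)))
    with pytest.raises(ValueError):
        SpatialBlockConfig(8, 4)  # narrowing is rejected


# ---------------------------------------------------------------------------
# residual block
# ---------------------------------------------------------------------------


def test_zeroed_residual_block_is_identity():
    block = ResidualBlock(ResidualBlockConfig(3, 3, stride=1))
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    x = RNG.standard_normal((2, 3, 6, 6)).astype(np.float32)
    out = block(Tensor(x))
    np.testing.assert_allclose(out.data, x, atol=1e-7)


def test_zeroed_residual_block_identity_jacobian():
    block = ResidualBlock(ResidualBlockConfig(2, 2, stride=1))
    for p in block.parameters():
        p.data = np.zeros_like(p.data)
    x = Tensor(RNG.standard_normal((1, 2, 4, 4)), requires_grad=True)
    upstream = RNG.standard_normal((1, 2, 4, 4))
    (block(x) * upstream).sum().backward()
    np.testing.assert_allclose(x.grad, upstream, atol=1e-7)


def test_residual_block_matches_step_by_step_recomputation():
    rng = np.random.default_rng(5)
    block = ResidualBlock(ResidualBlockConfig(4, 4, stride=1), rng=rng).eval()
    x = rng.standard_normal((1, 4, 6, 6)).astype(np.float32)
    out = block(Tensor(x))

    def conv_same(inp, layer):
        b, cin, h, w = inp.shape
        cout = layer.weight.data.shape[0]
        res = np.zeros((b, cout, h, w))
        padded = np.pad(inp, ((0, 0), (0, 0), (1, 1), (1, 1)))
        for o in range(cout):
            for c in range(cin):
                res[0, o] += conv2d_valid(padded[0, c], layer.weight.data[o, c])
            res[0, o] += layer.bias.data[o]
        return res

    h1 = conv_same(x, block.conv1)
    bn = block.bn1
    h1 = bn.gamma.data * (h1 - bn.running_mean) / np.sqrt(bn.running_var + bn.eps) \
        + bn.beta.data
    h1 = np.maximum(h1, 0.0)
    h2 = np.maximum(conv_same(h1, block.conv2), 0.0)
    np.testing.assert_allclose(out.data, h2 + x, atol=1e-4)


def test_residual_projection_changes_shape():
    block = ResidualBlock(ResidualBlockConfig(2, 4, stride=2))
    assert block.projection is not None
    out = block(Tensor(RNG.standard_normal((1, 2, 8, 8)).astype(np.float32)))
    assert out.data.shape == (1, 4, 4, 4)
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 3, 8, 8), dtype=np.float32)))


def test_batch_norm_eval_is_affine_and_deterministic():
    bn = BatchNorm2d(2).eval()
    bn.running_mean[...] = np.array([0.5, -0.2]).reshape(1, 2, 1, 1)
    bn.running_var[...] = np.array([1.5, 0.7]).reshape(1, 2, 1, 1)
    x = RNG.standard_normal((3, 2, 4, 4))
    out1 = bn(Tensor(x)).data
    out2 = bn(Tensor(x)).data
    np.testing.assert_array_equal(out1, out2)
    scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
    np.testing.assert_allclose(out1, scale * (x - bn.running_mean) + bn.beta.data)
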
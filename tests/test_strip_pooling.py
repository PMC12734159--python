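"""Directional strip pooling, the attention gate, and the combination head."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import numeric_grad

from stripfuse.autodiff import Tensor
from stripfuse.strip import (
    ComboHead,
    StripAttention,
    strip_pool_horizontal,
    strip_pool_vertical,
)

RNG = np.random.default_rng(13)


def _zero_attention(att: StripAttention) -> StripAttention:
    for p in att.parameters():
        p.data = np.zeros_like(p.data)
    # keep BN gammas at 1 so the zero path stays exactly zero
    att.bn_h.gamma.data = np.ones_like(att.bn_h.gamma.data)
    att.bn_v.gamma.data = np.ones_like(att.bn_v.gamma.data)
    return att


# ---------------------------------------------------------------------------
# pooling operators
# ---------------------------------------------------------------------------


def test_strip_pool_constant_map():
    z = np.full((1, 2, 3, 4), 0.7)
    np.testing.assert_allclose(strip_pool_horizontal(z), 0.7)
    np.testing.assert_allclose(strip_pool_vertical(z), 0.7)


def test_strip_pool_single_hot_pixel():
    z = np.zeros((1, 1, 4, 5))
    z[0, 0, 2, 3] = 1.0
    h = strip_pool_horizontal(z)
    assert h[0, 0, 2] == pytest.approx(1.0 / 5)
    assert np.all(h[0, 0, [0, 1, 3]] == 0.0)


def test_strip_pool_matches_brute_force_means():
    z = RNG.standard_normal((1, 2, 3, 4))
    expected_h = np.array(
        [[[z[0, c, h, :].sum() / 4 for h in range(3)] for c in range(2)]]
    )
    np.testing.assert_allclose(strip_pool_horizontal(z), expected_h)
    zv = RNG.standard_normal((1, 1, 4, 3))
    expected_v = np.array([[[zv[0, 0, :, j].sum() / 4 for j in range(3)]]])
    np.testing.assert_allclose(strip_pool_vertical(zv), expected_v)


def test_vertical_equals_horizontal_of_transpose():
    z = RNG.standard_normal((2, 3, 5, 4))
    np.testing.assert_allclose(
        strip_pool_vertical(z), strip_pool_horizontal(z.transpose(0, 1, 3, 2))
    )


@settings(max_examples=20, derandomize=True)
@given(st.integers(0, 10_000))
def test_flip_symmetries(seed):
    """Row means are invariant under horizontal flips; column means reverse."""
    z = np.random.default_rng(seed).standard_normal((1, 2, 4, 6))
    flipped = z[:, :, :, ::-1]
    np.testing.assert_allclose(
        strip_pool_horizontal(flipped), strip_pool_horizontal(z)
    )
    np.testing.assert_allclose(
        strip_pool_vertical(flipped), strip_pool_vertical(z)[:, :, ::-1]
    )
    vflipped = z[:, :, ::-1, :]
    np.testing.assert_allclose(strip_pool_vertical(vflipped), strip_pool_vertical(z))
    np.testing.assert_allclose(
        strip_pool_horizontal(vflipped), strip_pool_horizontal(z)[:, :, ::-1]
    )


# ---------------------------------------------------------------------------
# attention gate
# ---------------------------------------------------------------------------


def test_zero_weight_gate_is_exactly_half():
    att = _zero_attention(StripAttention(2)).eval()
    z = Tensor(RNG.standard_normal((1, 2, 4, 4)).astype(np.float32))
    gate = att.gate(z)
    np.testing.assert_allclose(gate.data, 0.5)
    out = att(z)
    np.testing.assert_allclose(out.data, 0.5 * z.data, atol=1e-7)


def test_gate_bounds_and_energy():
    att = StripAttention(3, rng=np.random.default_rng(1)).eval()
    z = RNG.standard_normal((2, 3, 5, 5)).astype(np.float32)
    gate = att.gate(Tensor(z)).data
    assert np.all(gate > 0.0) and np.all(gate < 1.0)
    out = att(Tensor(z)).data
    assert np.all(np.abs(out) <= np.abs(z) + 1e-7)
    assert (out**2).sum() <= (z**2).sum()


@pytest.mark.parametrize("side", [4, 6, 8])
def test_attention_matches_brute_force_recomposition(side):
    """Step-by-step recomputation from the primitive definitions."""
    att = StripAttention(2, rng=np.random.default_rng(9)).eval()
    z = RNG.standard_normal((1, 2, side, side)).astype(np.float32)
    out = att(Tensor(z)).data

    def conv1d_same(x, layer):  # x: (C, L)
        cout = layer.weight.data.shape[0]
        xp = np.pad(x, ((0, 0), (1, 1)))
        res = np.zeros((cout, x.shape[1]))
        for o in range(cout):
            for c in range(x.shape[0]):
                k = layer.weight.data[o, c, 0]
                for pos in range(x.shape[1]):
                    res[o, pos] += (xp[c, pos : pos + 3] * k).sum()
            res[o] += layer.bias.data[o]
        return res

    def bn_eval(x, bn):  # (C, L)
        g = bn.gamma.data[0, :, 0][:, None]
        b = bn.beta.data[0, :, 0][:, None]
        rm = bn.running_mean[0, :, 0][:, None]
        rv = bn.running_var[0, :, 0][:, None]
        return g * (x - rm) / np.sqrt(rv + bn.eps) + b

    rows = bn_eval(conv1d_same(z[0].mean(axis=2), att.conv_h), att.bn_h)
    cols = bn_eval(conv1d_same(z[0].mean(axis=1), att.conv_v), att.bn_v)
    fused = rows[:, :, None] + cols[:, None, :]
    mixed = np.einsum("oc,chw->ohw", att.conv_fuse.weight.data[:, :, 0, 0], fused)
    mixed += att.conv_fuse.bias.data[:, None, None]
    gate = 1.0 / (1.0 + np.exp(-mixed))
    np.testing.assert_allclose(out[0], z[0] * gate, atol=1e-5)


def test_attention_rejects_small_maps():
    att = StripAttention(2)
    with pytest.raises(ValueError):
        att(Tensor(np.zeros((1, 2, 2, 4), dtype=np.float32)))


def test_gradients_reach_every_attention_parameter():
    """Finite-difference check on a tiny instance, parameter by parameter."""
    att = StripAttention(2, rng=np.random.default_rng(4))
    for p in att.parameters():
        p.data = p.data.astype(np.float64)
    att.train()
    z_data = RNG.standard_normal((2, 2, 4, 4))

    def loss_value():
        return float(att(Tensor(z_data)).pow(2).sum().data)

    att.zero_grad()
    out = att(Tensor(z_data)).pow(2).sum()
    out.backward()
    names = dict(att.named_parameters())
    for name, p in names.items():
        assert p.grad is not None and np.any(p.grad != 0.0), name
        (num,) = numeric_grad(loss_value, [p.data], eps=1e-5)
        np.testing.assert_allclose(p.grad, num, atol=1e-4, rtol=1e-3, err_msg=name)


# ---------------------------------------------------------------------------
# combination head
# ---------------------------------------------------------------------------


def test_combo_head_eval_deterministic():
    head = ComboHead(3, out_dim=5, rng=np.random.default_rng(2)).eval()
    z = Tensor(RNG.standard_normal((2, 3, 4, 4)).astype(np.float32))
    out1 = head(z).data
    out2 = head(z).data
    np.testing.assert_array_equal(out1, out2)
    assert out1.shape == (2, 5)


def test_combo_head_full_dropout_returns_bias():
    head = ComboHead(3, out_dim=4, dropout_rate=1.0, rng=np.random.default_rng(2))
    head.train()
    z = Tensor(RNG.standard_normal((2, 3, 4, 4)).astype(np.float32))
    out = head(z).data
    np.testing.assert_allclose(out, np.broadcast_to(head.fc.bias.data, (2, 4)),
                               atol=1e-7)


def test_combo_head_constant_input_closed_form():
    """Zeroed attention on a constant map: gate 0.5, so FC sees 0.5*v*ones."""
    head = ComboHead(3, out_dim=4, rng=np.random.default_rng(8)).eval()
    _zero_attention(head.attention)
    v = 0.8
    z = Tensor(np.full((1, 3, 4, 4), v, dtype=np.float32))
    out = head(z).data
    expected = (0.5 * v) * head.fc.weight.data.sum(axis=0) + head.fc.bias.data
    np.testing.assert_allclose(out[0], expected, atol=1e-6)
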
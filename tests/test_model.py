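"""Network components against hand-computed oracles and structural contracts."""

import dataclasses

import numpy as np
import pytest
from scipy.special import erf

from permutedds import autograd as ag
from permutedds.autograd import Tensor
from permutedds.errors import ShapeError
from permutedds.model import (
    ConvEncoderConfig,
    ConvEncoder,
    FusionConfig,
    ModelConfig,
    PermuteDDS,
    PermuteMLPBlock,
    PredictionTriple,
    mse_loss,
    stack_features,
)

TINY = ModelConfig(
    kinds=("maccs",),
    fp_lengths={"maccs": 8},
    expr_len=8,
    mut_len=8,
    conv=ConvEncoderConfig(channels=(2, 2, 2), kernel=3, out_dim=4),
    fusion=FusionConfig(feature_dim=4, hidden_dim=8, out_dim=4),
    head_hidden=2,
    dtype="float64",
)


def _gelu(x):
    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def _swish(x):
    return x / (1.0 + np.exp(-x))


def _ln(x, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


# -- Conv1D encoder ---------------------------------------------------------

def test_third_layer_channel_width_is_configured(rng):
    enc = ConvEncoder(16, ConvEncoderConfig(), np.random.Generator(np.random.PCG64(0)), np.float64)
    fmap = enc.feature_map(Tensor(rng.normal(size=(2, 16))))
    assert fmap.shape == (2, 16, 32)


def test_zero_input_yields_projection_bias(rng):
    gen = np.random.Generator(np.random.PCG64(1))
    enc = ConvEncoder(10, ConvEncoderConfig(out_dim=5), gen, np.float64)
    enc.proj.bias.data = rng.normal(size=5)
    out = enc(Tensor(np.zeros((3, 10))))
    np.testing.assert_allclose(out.data, np.tile(enc.proj.bias.data, (3, 1)), atol=1e-14)


def test_conv_encoder_matches_hand_oracle(rng):
    """L=6, kernel 3, channels (1,1,1), D=2 against an explicit loop."""
    gen = np.random.Generator(np.random.PCG64(2))
    enc = ConvEncoder(6, ConvEncoderConfig(channels=(1, 1, 1), kernel=3, out_dim=2), gen, np.float64)
    x = rng.normal(size=6)

    def conv_layer(seq, w, b):
        padded = np.concatenate([[0.0], seq, [0.0]])
        return np.array(
            [_gelu(w[0] * padded[i] + w[1] * padded[i + 1] + w[2] * padded[i + 2] + b)
             for i in range(6)]
        )

    h = x
    for conv in (enc.conv1, enc.conv2, enc.conv3):
        h = conv_layer(h, conv.weight.data[:, 0], conv.bias.data[0])
    expected = h @ enc.proj.weight.data + enc.proj.bias.data
    out = enc(Tensor(x.reshape(1, 6)))
    np.testing.assert_allclose(out.data[0], expected, rtol=1e-12)


def test_encoder_rejects_short_sequences():
    gen = np.random.Generator(np.random.PCG64(0))
    with pytest.raises(ShapeError):
        ConvEncoder(2, ConvEncoderConfig(kernel=3), gen, np.float64)


# -- Stacking ---------------------------------------------------------------

def test_stack_order_and_roundtrip(rng):
    vs = [rng.normal(size=3) for _ in range(4)]
    h = stack_features(*vs)
    assert h.shape == (4, 3)
    for row, v in enumerate(vs):
        np.testing.assert_array_equal(h.data[row], v)


def test_stack_batched_has_four_views(rng):
    vs = [rng.normal(size=(5, 3)) for _ in range(4)]
    assert stack_features(*vs).shape == (5, 4, 3)


def test_stack_rejects_mismatched_widths(rng):
    with pytest.raises(ShapeError):
        stack_features(np.ones(3), np.ones(3), np.ones(4), np.ones(3))


# -- Permute-MLP block ------------------------------------------------------

def test_permute_block_identity_with_zero_residual_weights(rng):
    gen = np.random.Generator(np.random.PCG64(3))
    block = PermuteMLPBlock(4, 6, gen, np.float64)
    block.zero_residual_branches()
    x = rng.normal(size=(2, 4, 6))
    out = block(Tensor(x))
    np.testing.assert_array_equal(out.data, x)  # bit-for-bit


@pytest.mark.parametrize("n,d", [(2, 3), (4, 6), (5, 2)])
def test_permute_block_preserves_shape(n, d, rng):
    gen = np.random.Generator(np.random.PCG64(4))
    block = PermuteMLPBlock(n, d, gen, np.float64)
    assert block(Tensor(rng.normal(size=(3, n, d)))).shape == (3, n, d)


def test_permute_block_matches_hand_formula(rng):
    """2x3 tensor against a direct evaluation of the two residual MLP units."""
    gen = np.random.Generator(np.random.PCG64(5))
    block = PermuteMLPBlock(2, 3, gen, np.float64)
    h = rng.normal(size=(1, 2, 3))

    w1d, w2d = block.lin1_d.weight.data, block.lin2_d.weight.data
    w1n, w2n = block.lin1_n.weight.data, block.lin2_n.weight.data
    u = h[0] + _ln(_swish(h[0] @ w1d) @ w2d)
    t = u.T
    v = t + _ln(_swish(t @ w1n) @ w2n)
    expected = v.T

    np.testing.assert_allclose(block(Tensor(h)).data[0], expected, rtol=1e-10)


# -- Fusion projection and heads -------------------------------------------

def test_fuse_and_project_contract_and_zero_case(rng):
    model = PermuteDDS(TINY)
    fsn = model.fsns[0]
    out = fsn.fuse_and_project(Tensor(rng.normal(size=(3, 4, 4))))
    assert out.shape == (3, TINY.fusion.out_dim)
    fsn.proj1.bias.data[:] = 0
    fsn.proj2.bias.data[:] = 0
    zero = fsn.fuse_and_project(Tensor(np.zeros((2, 4, 4))))
    np.testing.assert_array_equal(zero.data, 0.0)


def test_fuse_and_project_matches_hand_oracle(rng):
    model = PermuteDDS(TINY)
    fsn = model.fsns[0]
    h = rng.normal(size=(1, 4, 4))
    flat = h.reshape(1, -1)
    expected = (
        _gelu(flat @ fsn.proj1.weight.data + fsn.proj1.bias.data)
        @ fsn.proj2.weight.data
        + fsn.proj2.bias.data
    )
    np.testing.assert_allclose(
        fsn.fuse_and_project(Tensor(h)).data, expected, rtol=1e-12
    )


def test_prediction_triple_head_averaging():
    t = PredictionTriple.from_scores({"hashtt": 3.0, "map4": 6.0, "maccs": 9.0})
    assert t.y_hat == 6.0
    t = PredictionTriple.from_scores({"hashtt": 2.5, "map4": 2.5, "maccs": 2.5})
    assert t.y_hat == 2.5
    partial = PredictionTriple.from_scores({"hashtt": 1.0, "map4": 3.0})
    assert partial.y_s is None and partial.y_hat == 2.0


def test_fsn_outputs_finite_scalar_and_is_order_sensitive(rng):
    model = PermuteDDS(TINY)
    fsn = model.fsns[0]
    fi = rng.integers(0, 2, size=(1, 8)).astype(float)
    fj = rng.integers(0, 2, size=(1, 8)).astype(float)
    e = rng.normal(size=(1, 8))
    m = rng.normal(size=(1, 8))
    _, y_ij = fsn(Tensor(fi), Tensor(fj), Tensor(e), Tensor(m))
    _, y_ji = fsn(Tensor(fj), Tensor(fi), Tensor(e), Tensor(m))
    assert np.isfinite(y_ij.data).all()
    # no symmetry is enforced: swapping the drugs permutes the stack rows
    assert y_ij.data.shape == (1,) and y_ji.data.shape == (1,)


# -- Loss -------------------------------------------------------------------

def test_mse_loss_values(rng):
    assert mse_loss(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0
    assert mse_loss(np.array([0.0]), np.array([2.0])) == 4.0
    t = rng.normal(size=7)
    p = rng.normal(size=7)
    oracle = sum((a - b) ** 2 for a, b in zip(t, p)) / 7
    assert mse_loss(t, p) == pytest.approx(oracle, rel=1e-12)
    with pytest.raises(ShapeError):
        mse_loss(np.ones(3), np.ones(4))


# -- End-to-end gradient check ---------------------------------------------

def test_fsn_gradient_matches_finite_differences(rng):
    model = PermuteDDS(TINY)
    fps = rng.integers(0, 2, size=(3, 8)).astype(float)
    fqs = rng.integers(0, 2, size=(3, 8)).astype(float)
    e = rng.normal(size=(3, 8))
    m = rng.normal(size=(3, 8))
    y = rng.normal(size=3)

    def loss_value():
        y_hat, _ = model.forward({"maccs": fps}, {"maccs": fqs}, e, m)
        return mse_loss(Tensor(y), y_hat)

    loss = loss_value()
    loss.backward()
    params = dict(model.named_parameters())
    grads = {k: p.grad.copy() for k, p in params.items() if p.grad is not None}

    check_rng = np.random.Generator(np.random.PCG64(99))
    names = check_rng.choice(sorted(grads), size=8, replace=False)
    eps = 1e-6
    for name in names:
        p = params[name]
        flat_idx = int(check_rng.integers(p.data.size))
        orig = p.data.reshape(-1)[flat_idx]
        p.data.reshape(-1)[flat_idx] = orig + eps
        hi = float(loss_value().data)
        p.data.reshape(-1)[flat_idx] = orig - eps
        lo = float(loss_value().data)
        p.data.reshape(-1)[flat_idx] = orig
        numeric = (hi - lo) / (2 * eps)
        analytic = grads[name].reshape(-1)[flat_idx]
        denom = max(abs(numeric), abs(analytic), 1e-8)
        assert abs(numeric - analytic) / denom < 1e-4, name


# -- Checkpointing ----------------------------------------------------------

def test_checkpoint_roundtrip_is_bit_identical(tmp_path, rng):
    model = PermuteDDS(TINY)
    path = str(tmp_path / "ckpt")
    model.save(path)
    restored = PermuteDDS.load(path)
    fi = {"maccs": rng.integers(0, 2, size=(4, 8)).astype(float)}
    fj = {"maccs": rng.integers(0, 2, size=(4, 8)).astype(float)}
    e = rng.normal(size=(4, 8))
    m = rng.normal(size=(4, 8))
    a, _ = model.forward(fi, fj, e, m)
    b, _ = restored.forward(fi, fj, e, m)
    np.testing.assert_array_equal(a.data, b.data)
    assert restored.config == dataclasses.replace(model.config)
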
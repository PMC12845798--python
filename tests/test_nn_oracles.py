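"""Brute-force oracle checks for every network primitive.

Each oracle evaluates the defining equations literally (scalar loops),
independently of the vectorised implementation it checks.
"""

import math

import numpy as np
import pytest

from bcgfusion.nn import (
    BiLSTM, CausalConv1d, Dense, LSTMCellParams, MultiHeadSelfAttention,
    TCNBlock, Tensor, adjust_heads, crossmodal_fuse, lstm_forward,
)

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------- oracles --

def causal_conv_oracle(x, f, d=1):
    """F(s) = sum_i f(i) * x(s - d*i), zero for negative indices."""
    T, k = len(x), len(f)
    out = np.zeros(T)
    for s in range(T):
        for i in range(k):
            j = s - d * i
            if j >= 0:
                out[s] += f[i] * x[j]
    return out


def lstm_oracle(x, W, U, b, H):
    """Literal gate recurrence, gates packed [f, i, o, c~]."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    T = x.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    outs = []
    for t in range(T):
        z = x[t] @ W + h @ U + b
        f, i, o, g = z[:H], z[H:2 * H], z[2 * H:3 * H], z[3 * H:]
        f, i, o, g = sig(f), sig(i), sig(o), np.tanh(g)
        c = f * c + i * g
        h = o * np.tanh(c)
        outs.append(h.copy())
    return np.array(outs)


def mhsa_oracle(x, Wq, Wk, Wv, Wo, heads):
    """Per-head scaled dot-product attention, concatenated, projected."""
    T, D = x.shape
    dk = D // heads
    q, k, v = x @ Wq, x @ Wk, x @ Wv
    cols = []
    for h in range(heads):
        sl = slice(h * dk, (h + 1) * dk)
        scores = q[:, sl] @ k[:, sl].T / math.sqrt(dk)
        a = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = a / a.sum(axis=1, keepdims=True)
        cols.append(a @ v[:, sl])
    return np.concatenate(cols, axis=1) @ Wo


def fuse_oracle(pb, pp):
    """S = softmax(Pb Pp^T / sqrt(D)); F = S Pp + (J - S) Pb."""
    T, D = pb.shape
    scores = pb @ pp.T / math.sqrt(D)
    S = np.exp(scores - scores.max(axis=1, keepdims=True))
    S = S / S.sum(axis=1, keepdims=True)
    J = np.ones((T, T))
    return S @ pp + (J - S) @ pb, S


# ------------------------------------------------------------------ tests --

@pytest.mark.parametrize("trial", range(25))
def test_causal_conv_matches_literal_summation(trial):
    rng = np.random.default_rng(trial)
    T = int(rng.integers(5, 40))
    k = int(rng.integers(1, 6))
    x = rng.normal(size=T)
    conv = CausalConv1d(1, 1, k, rng)
    f = conv.W.data[:, 0, 0]
    conv.b.data[:] = 0.0
    out = conv(Tensor(x.reshape(1, T, 1))).data[0, :, 0]
    np.testing.assert_allclose(out, causal_conv_oracle(x, f), atol=1e-6)


def test_causal_conv_identity_and_delay_kernels():
    x = np.array([1.0, 2.0, 3.0])
    conv = CausalConv1d(1, 1, 1, RNG)
    conv.W.data[:] = 1.0
    conv.b.data[:] = 0.0
    np.testing.assert_allclose(conv(Tensor(x.reshape(1, 3, 1))).data.ravel(), x)
    delay = CausalConv1d(1, 1, 2, RNG)
    delay.W.data[:, 0, 0] = [0.0, 1.0]   # f = [0, 1]: unit delay
    delay.b.data[:] = 0.0
    np.testing.assert_allclose(
        delay(Tensor(x.reshape(1, 3, 1))).data.ravel(), [0.0, 1.0, 2.0])


@pytest.mark.parametrize("trial", range(25))
def test_dilated_conv_matches_literal_summation(trial):
    rng = np.random.default_rng(100 + trial)
    T = int(rng.integers(8, 40))
    k = int(rng.integers(2, 5))
    d = int(rng.integers(1, 5))
    x = rng.normal(size=T)
    conv = CausalConv1d(1, 1, k, rng, dilation=d)
    conv.b.data[:] = 0.0
    out = conv(Tensor(x.reshape(1, T, 1))).data[0, :, 0]
    np.testing.assert_allclose(out, causal_conv_oracle(
        x, conv.W.data[:, 0, 0], d), atol=1e-6)


def test_dilated_conv_worked_example():
    # f = [1, 1], d = 2, x = [1,2,3,4] -> [1, 2, 4, 6]
    conv = CausalConv1d(1, 1, 2, RNG, dilation=2)
    conv.W.data[:, 0, 0] = [1.0, 1.0]
    conv.b.data[:] = 0.0
    out = conv(Tensor(np.array([1.0, 2, 3, 4]).reshape(1, 4, 1)))
    np.testing.assert_allclose(out.data.ravel(), [1.0, 2.0, 4.0, 6.0])


def test_dilation_one_reduces_to_plain_causal_conv():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(1, 20, 3))
    c1 = CausalConv1d(3, 2, 3, np.random.default_rng(5), dilation=1)
    c2 = CausalConv1d(3, 2, 3, np.random.default_rng(5), dilation=1)
    np.testing.assert_array_equal(c1(Tensor(x)).data, c2(Tensor(x)).data)


def test_conv_causality_perturbation():
    """Changing x at t0 never changes outputs before t0."""
    rng = np.random.default_rng(3)
    conv = CausalConv1d(2, 3, 5, rng, dilation=3)
    x = rng.normal(size=(1, 30, 2))
    base = conv(Tensor(x)).data
    t0 = 17
    x2 = x.copy()
    x2[0, t0, :] += 5.0
    pert = conv(Tensor(x2)).data
    np.testing.assert_array_equal(base[0, :t0], pert[0, :t0])
    assert not np.allclose(base[0, t0], pert[0, t0])


@pytest.mark.parametrize("trial", range(10))
def test_bilstm_matches_scalar_recurrence(trial):
    rng = np.random.default_rng(200 + trial)
    T, D, H = 4, 3, 3
    x = rng.normal(size=(T, D))
    net = BiLSTM(D, H, rng)
    out = net(Tensor(x.reshape(1, T, D))).data[0]
    fwd = lstm_oracle(x, net.fwd.W.data, net.fwd.U.data, net.fwd.b.data, H)
    bwd = lstm_oracle(x[::-1], net.bwd.W.data, net.bwd.U.data,
                      net.bwd.b.data, H)[::-1]
    np.testing.assert_allclose(out, np.concatenate([fwd, bwd], axis=1),
                               atol=1e-6)


def test_lstm_zero_weights_gives_zero_output():
    # gates = sigmoid(0) = 0.5 but c~ = tanh(0) = 0, so C = h = 0
    p = LSTMCellParams(2, 3, RNG)
    p.W.data[:] = 0; p.U.data[:] = 0; p.b.data[:] = 0
    out = lstm_forward(Tensor(np.ones((1, 5, 2))), p)
    np.testing.assert_array_equal(out.data, np.zeros((1, 5, 3)))


def test_bilstm_output_dim_is_twice_hidden():
    net = BiLSTM(4, 6, RNG)
    out = net(Tensor(np.zeros((2, 7, 4))))
    assert out.shape == (2, 7, 12)


@pytest.mark.parametrize("dim,req,expected", [(128, 4, 4), (6, 4, 3), (7, 4, 1)])
def test_adjust_heads(dim, req, expected):
    assert adjust_heads(dim, req) == expected


@pytest.mark.parametrize("trial", range(10))
def test_mhsa_matches_per_head_oracle(trial):
    rng = np.random.default_rng(300 + trial)
    T, D, h = int(rng.integers(2, 8)), 8, int(rng.choice([1, 2, 4]))
    x = rng.normal(size=(T, D))
    attn = MultiHeadSelfAttention(D, h, rng)
    out = attn(Tensor(x.reshape(1, T, D))).data[0]
    ref = mhsa_oracle(x, attn.Wq.data, attn.Wk.data, attn.Wv.data,
                      attn.Wo.data, h)
    np.testing.assert_allclose(out, ref, atol=1e-6)


def test_mhsa_degenerate_single_timestep():
    # T = 1: attention weight is exactly 1, output = x Wv Wo
    rng = np.random.default_rng(9)
    attn = MultiHeadSelfAttention(6, 2, rng)
    x = rng.normal(size=(1, 1, 6))
    out = attn(Tensor(x))
    np.testing.assert_allclose(out.data[0, 0],
                               x[0, 0] @ attn.Wv.data @ attn.Wo.data,
                               atol=1e-10)


def test_mhsa_rows_stochastic_and_permutation_equivariant(rng=np.random.default_rng(11)):
    T, D = 9, 8
    attn = MultiHeadSelfAttention(D, 4, rng)
    x = rng.normal(size=(1, T, D))
    out = attn(Tensor(x)).data
    rows = attn.last_attention.sum(axis=-1)
    np.testing.assert_allclose(rows, np.ones_like(rows), atol=1e-6)
    perm = rng.permutation(T)
    out_p = attn(Tensor(x[:, perm, :])).data
    np.testing.assert_allclose(out_p, out[:, perm, :], atol=1e-10)


def test_mhsa_rejects_indivisible_dims():
    with pytest.raises(ValueError):
        MultiHeadSelfAttention(7, 4, RNG)


@pytest.mark.parametrize("trial", range(10))
def test_projection_matches_explicit_loop(trial):
    rng = np.random.default_rng(400 + trial)
    T, Din, Dout = 5, 4, 6
    proj = Dense(Din, Dout, rng)
    x = rng.normal(size=(T, Din))
    out = proj(Tensor(x.reshape(1, T, Din))).data[0]
    ref = np.array([x[t] @ proj.W.data + proj.b.data for t in range(T)])
    np.testing.assert_allclose(out, ref, atol=1e-6)


def test_projection_identity_and_constant():
    proj = Dense(3, 3, RNG)
    proj.W.data = np.eye(3)
    proj.b.data[:] = 0.0
    x = np.arange(12.0).reshape(1, 4, 3)
    np.testing.assert_array_equal(proj(Tensor(x)).data, x)
    proj.W.data[:] = 0.0
    proj.b.data[:] = [1.0, 2.0, 3.0]
    np.testing.assert_array_equal(proj(Tensor(x)).data,
                                  np.tile([1.0, 2, 3], (1, 4, 1)))


@pytest.mark.parametrize("trial", range(30))
def test_crossmodal_fusion_matches_literal_equations(trial):
    rng = np.random.default_rng(500 + trial)
    T = int(rng.integers(1, 6))
    D = int(rng.integers(1, 5))
    pb = rng.normal(size=(T, D))
    pp = rng.normal(size=(T, D))
    fused, S = crossmodal_fuse(Tensor(pb.reshape(1, T, D)),
                               Tensor(pp.reshape(1, T, D)),
                               return_similarity=True)
    ref, S_ref = fuse_oracle(pb, pp)
    np.testing.assert_allclose(fused.data[0], ref, atol=1e-6)
    np.testing.assert_allclose(S.data[0], S_ref, atol=1e-6)
    np.testing.assert_allclose(S.data[0].sum(axis=1), np.ones(T), atol=1e-6)


def test_fusion_single_timestep_returns_ppg():
    # T = 1: S = [[1]], (J - S) = 0, so the fused feature is exactly P_ppg
    pb = Tensor(np.array([[[2.0, -1.0]]]))
    pp = Tensor(np.array([[[0.5, 3.0]]]))
    fused = crossmodal_fuse(pb, pp)
    np.testing.assert_allclose(fused.data, pp.data, atol=1e-12)


def test_fusion_rejects_shape_mismatch():
    with pytest.raises(ValueError):
        crossmodal_fuse(Tensor(np.zeros((1, 3, 2))), Tensor(np.zeros((1, 4, 2))))


def test_tcn_block_zero_residual_is_relu_of_input():
    rng = np.random.default_rng(21)
    blk = TCNBlock(3, 3, 3, 2, 0.0, rng)
    for conv in (blk.conv1, blk.conv2):
        conv.W.data[:] = 0.0
        conv.b.data[:] = 0.0
    x = rng.normal(size=(1, 10, 3))
    np.testing.assert_allclose(blk(Tensor(x)).data, np.maximum(x, 0.0))


def test_tcn_stack_receptive_field_61():
    """Kernel 3, dilations (1,2,4,8): RF = 1 + sum 2(k-1)d = 61 samples,
    measured by perturbation probing."""
    rng = np.random.default_rng(33)
    blocks = [TCNBlock(1 if d == 1 else 4, 4, 3, d, 0.0, rng)
              for d in (1, 2, 4, 8)]
    rf_theory = 1 + sum(2 * (3 - 1) * d for d in (1, 2, 4, 8))
    assert rf_theory == 61

    def fwd(x):
        h = Tensor(x)
        for b in blocks:
            h = b(h)
        return h.data

    T = 150
    x = rng.normal(size=(1, T, 1))
    base = fwd(x)
    t_out = 120
    affected = []
    for t0 in range(T):
        x2 = x.copy()
        x2[0, t0, 0] += 10.0
        if not np.allclose(fwd(x2)[0, t_out], base[0, t_out]):
            affected.append(t0)
    assert affected, "probe produced no response; dead ReLUs in fixture"
    # no future leakage, and the influencing span is exactly the RF window
    assert max(affected) <= t_out
    assert min(affected) >= t_out - 61 + 1


def test_tcn_eval_mode_is_deterministic():
    rng = np.random.default_rng(55)
    blk = TCNBlock(2, 4, 3, 2, 0.5, rng)
    blk.eval()
    x = rng.normal(size=(2, 20, 2))
    a = blk(Tensor(x)).data
    b = blk(Tensor(x)).data
    np.testing.assert_array_equal(a, b)
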
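"""Network building blocks: causal convolutions, TCN residual blocks,
(Bi)LSTM, multi-head self-attention and the cross-modal fusion operator.

Sequence tensors follow the ``[batch, time, channels]`` layout everywhere.
Weights are initialised with a uniform fan-in scheme,
``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``, from a caller-supplied generator so
that model construction is fully reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator, Sequence

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Module", "Dense", "CausalConv1d", "MultiScaleConv1d", "MaxPool1d",
    "SpatialDropout", "TCNBlock", "LSTMCellParams", "lstm_forward", "BiLSTM",
    "MultiHeadSelfAttention", "adjust_heads", "crossmodal_fuse",
]


def _uniform(rng: np.random.Generator, shape, fan_in: int,
             gain: float = 1.0) -> Tensor:
    bound = gain / math.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    """Minimal container with recursive parameter discovery and a
    train/eval mode flag (dropout is the only mode-dependent layer)."""

    training: bool = True

    def parameters(self) -> Iterator[Tensor]:
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in vars(self).values():
            for m in _collect_modules(v):
                yield m

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _collect(v) -> Iterator[Tensor]:
    if isinstance(v, Tensor) and v.requires_grad:
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


def _collect_modules(v) -> Iterator[Module]:
    if isinstance(v, Module):
        yield from v.modules()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect_modules(item)


class Dense(Module):
    """Affine map applied to the last axis.

    ``gain`` rescales the fan-in initialisation bound; a near-zero gain on
    an output layer starts its predictions at the midpoint regardless of
    upstream activation scale."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 gain: float = 1.0):
        self.W = _uniform(rng, (d_in, d_out), d_in, gain)
        self.b = _uniform(rng, (d_out,), d_in, gain)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class CausalConv1d(Module):
    """Dilated causal convolution over ``[B, T, C_in] -> [B, T, C_out]``.

    Implements F(s) = sum_i f(i) * x(s - d*i) with implicit left zero
    padding, so each output depends on the current and past d*(k-1)
    samples only.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1):
        if kernel_size < 1:
            raise ValueError(f"kernel_size must be >= 1, got {kernel_size}")
        if dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {dilation}")
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = c_in * kernel_size
        # W[i] maps the input delayed by d*i taps
        self.W = _uniform(rng, (kernel_size, c_in, c_out), fan_in)
        self.b = _uniform(rng, (c_out,), fan_in)

    def __call__(self, x: Tensor) -> Tensor:
        k, d = self.kernel_size, self.dilation
        T = x.shape[1]
        pad = d * (k - 1)
        xp = x.pad_axis(1, pad) if pad else x
        out = xp[:, pad:pad + T, :] @ self.W[0]
        for i in range(1, k):
            out = out + xp[:, pad - d * i:pad - d * i + T, :] @ self.W[i]
        return out + self.b

    @property
    def receptive_field(self) -> int:
        return 1 + self.dilation * (self.kernel_size - 1)


class MultiScaleConv1d(Module):
    """Parallel causal convolutions with several kernel sizes,
    channel-concatenated, to capture waveform features at multiple
    temporal scales."""

    def __init__(self, c_in: int, filters_per_kernel: int,
                 kernel_sizes: Sequence[int], rng: np.random.Generator):
        self.convs = [CausalConv1d(c_in, filters_per_kernel, k, rng)
                      for k in kernel_sizes]

    def __call__(self, x: Tensor) -> Tensor:
        return concat([c(x).relu() for c in self.convs], axis=-1)

    @property
    def c_out(self) -> int:
        return sum(c.W.shape[2] for c in self.convs)


class MaxPool1d(Module):
    """Non-overlapping max pooling along time; trailing remainder samples
    are dropped."""

    def __init__(self, pool_size: int):
        self.pool_size = pool_size

    def __call__(self, x: Tensor) -> Tensor:
        p = self.pool_size
        if p == 1:
            return x
        B, T, C = x.shape
        Tp = (T // p) * p
        x = x[:, :Tp, :].reshape(B, Tp // p, p, C)
        return x.max(axis=2)


class SpatialDropout(Module):
    """Channel dropout: zeroes whole feature channels (per sample) during
    training, scaling survivors by 1/(1-p).  Identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        B, _, C = x.shape
        keep = self._rng.random((B, 1, C)) >= self.p
        return x * (keep / (1.0 - self.p))


class TCNBlock(Module):
    """Pre-activation residual block: o = ReLU(skip(x) + F(x)) where
    F = [ReLU -> dilated causal conv -> spatial dropout] x 2 and skip is the
    identity, or a 1x1 convolution when channel counts differ."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, dilation: int,
                 dropout_p: float, rng: np.random.Generator):
        self.conv1 = CausalConv1d(c_in, c_out, kernel_size, rng, dilation)
        self.conv2 = CausalConv1d(c_out, c_out, kernel_size, rng, dilation)
        self.drop1 = SpatialDropout(dropout_p, rng)
        self.drop2 = SpatialDropout(dropout_p, rng)
        self.skip = (CausalConv1d(c_in, c_out, 1, rng)
                     if c_in != c_out else None)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop1(self.conv1(x.relu()))
        h = self.drop2(self.conv2(h.relu()))
        s = self.skip(x) if self.skip is not None else x
        return (s + h).relu()

    @property
    def receptive_field(self) -> int:
        # two convs of span d*(k-1) each, plus the current sample
        d = self.conv1.dilation
        k = self.conv1.kernel_size
        return 1 + 2 * d * (k - 1)


class LSTMCellParams(Module):
    """One direction's LSTM weights, gates packed [f, i, o, c~]."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.W = _uniform(rng, (d_in, 4 * hidden), d_in)
        self.U = _uniform(rng, (hidden, 4 * hidden), hidden)
        self.b = _uniform(rng, (4 * hidden,), d_in)


def lstm_forward(x: Tensor, p: LSTMCellParams, reverse: bool = False) -> Tensor:
    """Run the LSTM recurrence over ``[B, T, D]`` with zero initial state.

    f_t = sigma(W_f x_t + U_f h_{t-1} + b_f)   (forget gate)
    i_t, o_t analogous; c~_t = tanh(...); C_t = f_t*C_{t-1} + i_t*c~_t;
    h_t = o_t * tanh(C_t).
    """
    B, T, _ = x.shape
    H = p.hidden
    h = Tensor(np.zeros((B, H)))
    c = Tensor(np.zeros((B, H)))
    steps = range(T - 1, -1, -1) if reverse else range(T)
    outs: list[Tensor] = []
    xw = x @ p.W + p.b            # precompute input contributions [B,T,4H]
    for t in steps:
        z = xw[:, t, :] + h @ p.U
        f = z[:, 0 * H:1 * H].sigmoid()
        i = z[:, 1 * H:2 * H].sigmoid()
        o = z[:, 2 * H:3 * H].sigmoid()
        g = z[:, 3 * H:4 * H].tanh()
        c = f * c + i * g
        h = o * c.tanh()
        outs.append(h.reshape(B, 1, H))
    if reverse:
        outs.reverse()
    return concat(outs, axis=1)


class BiLSTM(Module):
    """Independent forward and backward LSTMs, hidden states concatenated
    per time step -> ``[B, T, 2H]``."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.fwd = LSTMCellParams(d_in, hidden, rng)
        self.bwd = LSTMCellParams(d_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([lstm_forward(x, self.fwd),
                       lstm_forward(x, self.bwd, reverse=True)], axis=-1)


def adjust_heads(feature_dim: int, requested: int) -> int:
    """Largest head count <= requested that divides the feature dimension.

    Guarantees the per-head dimension d_k = D / h is integral; always >= 1.
    """
    if feature_dim < 1 or requested < 1:
        raise ValueError("feature_dim and requested head count must be >= 1")
    for h in range(min(requested, feature_dim), 0, -1):
        if feature_dim % h == 0:
            return h
    return 1


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention, h heads on D/h-dim subspaces,
    concatenated and projected back to D.  No positional encoding: order
    information is supplied by the recurrent/convolutional stages upstream.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError(
                f"d_model={d_model} not divisible by n_heads={n_heads}; "
                "use adjust_heads() to pick a valid head count")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.Wq = _uniform(rng, (d_model, d_model), d_model)
        self.Wk = _uniform(rng, (d_model, d_model), d_model)
        self.Wv = _uniform(rng, (d_model, d_model), d_model)
        self.Wo = _uniform(rng, (d_model, d_model), d_model)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dk = self.n_heads, self.d_k
        q = (x @ self.Wq).reshape(B, T, h, dk).swapaxes(1, 2)  # [B,h,T,dk]
        k = (x @ self.Wk).reshape(B, T, h, dk).swapaxes(1, 2)
        v = (x @ self.Wv).reshape(B, T, h, dk).swapaxes(1, 2)
        scores = (q @ k.swapaxes(2, 3)) * (1.0 / math.sqrt(dk))
        attn = scores.softmax(axis=-1)                          # [B,h,T,T]
        self.last_attention = attn.data
        out = (attn @ v).swapaxes(1, 2).reshape(B, T, D)
        return out @ self.Wo


def crossmodal_fuse(p_bcg: Tensor, p_ppg: Tensor,
                    return_similarity: bool = False):
    """Cross-modal attention fusion of two projected feature sequences.

    S = softmax(P_bcg @ P_ppg^T / sqrt(D)) row-wise, S in R^{T x T};
    F_fused = S @ P_ppg + (J - S) @ P_bcg with J the all-ones matrix.
    """
    if p_bcg.shape != p_ppg.shape:
        raise ValueError(
            f"modality shapes differ: {p_bcg.shape} vs {p_ppg.shape}")
    D = p_bcg.shape[-1]
    scores = (p_bcg @ p_ppg.swapaxes(-1, -2)) * (1.0 / math.sqrt(D))
    S = scores.softmax(axis=-1)
    # (J - S) @ P_bcg = sum_t P_bcg[t] - S @ P_bcg, computed without
    # materialising J
    col_sum = p_bcg.sum(axis=-2, keepdims=True)
    fused = S @ p_ppg + col_sum + (-(S @ p_bcg))
    if return_similarity:
        return fused, S
    return fused
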
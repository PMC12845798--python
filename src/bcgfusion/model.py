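"""Dual-branch temporal fusion network for heart-rate regression.

Architecture (both branches in parallel):

* BCG branch: 4-channel input → multi-scale causal convolutions (kernels
  3/5/7, channel-concatenated) → max pooling → four TCN residual blocks
  with dilations 1, 2, 4, 8.
* PPG branch: 1-channel input → multi-scale convolutions (kernels 3/5) →
  max pooling → three TCN blocks with dilations 1, 2, 4.
* Each branch → BiLSTM → multi-head self-attention (head count adjusted to
  divide the feature dimension) → linear projection into a shared
  ``d_fusion``-dimensional space.
* Cross-modal attention fusion mixes the two projected sequences through a
  time-by-time similarity matrix; global average pooling over time feeds a
  128 → 64 → 1 fully connected head whose sigmoid output is scaled onto
  the physiological 35–120 BPM range.

Ablation switches reproduce the progressive variants (baseline without
TCN/BiLSTM/attention, single-modality branches, concatenation instead of
dynamic fusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn import (
    BiLSTM, Dense, MaxPool1d, Module, MultiHeadSelfAttention,
    MultiScaleConv1d, TCNBlock, Tensor, adjust_heads, concat, crossmodal_fuse,
)

__all__ = ["ModelConfig", "TemporalFusionNet", "build_model",
           "ablation_variants"]


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters and ablation switches."""

    bcg_kernels: tuple[int, ...] = (3, 5, 7)
    ppg_kernels: tuple[int, ...] = (3, 5)
    filters_per_kernel: int = 32
    pool_size: int = 2
    bcg_tcn_dilations: tuple[int, ...] = (1, 2, 4, 8)
    ppg_tcn_dilations: tuple[int, ...] = (1, 2, 4)
    tcn_channels: int = 128
    tcn_kernel: int = 3
    lstm_hidden: int = 128
    attn_heads: int = 4
    d_fusion: int = 128
    dropout_p: float = 0.1
    use_tcn: bool = True
    use_bilstm: bool = True
    use_mhsa: bool = True
    use_dynamic_fusion: bool = True
    modality: str = "both"          # both | bcg_only | ppg_only
    hr_min: float = 35.0
    hr_max: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("both", "bcg_only", "ppg_only"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality != "both" and self.use_dynamic_fusion:
            raise ValueError(
                "cross-modal fusion requires both modalities; set "
                "use_dynamic_fusion=False for single-modality variants")
        if self.hr_min >= self.hr_max:
            raise ValueError("hr_min must be < hr_max")
        if self.d_fusion < 1 or self.attn_heads < 1:
            raise ValueError("d_fusion and attn_heads must be >= 1")


def ablation_variants() -> dict[str, dict]:
    """Config overrides for the progressive ablation study."""
    return {
        "baseline": dict(use_tcn=False, use_bilstm=False, use_mhsa=False),
        "tcn": dict(use_tcn=True, use_bilstm=False, use_mhsa=False),
        "tcn_bilstm": dict(use_tcn=True, use_bilstm=True, use_mhsa=False),
        "full": dict(),
        "no_fusion": dict(use_dynamic_fusion=False),
        "bcg_only": dict(modality="bcg_only", use_dynamic_fusion=False),
        "ppg_only": dict(modality="ppg_only", use_dynamic_fusion=False),
    }


class _Branch(Module):
    """One modality's feature extractor: multi-scale conv → pool →
    TCN stack → BiLSTM → self-attention (stages optional)."""

    def __init__(self, c_in: int, kernels: Sequence[int],
                 dilations: Sequence[int], cfg: ModelConfig,
                 rng: np.random.Generator):
        self.msconv = MultiScaleConv1d(c_in, cfg.filters_per_kernel,
                                       kernels, rng)
        self.pool = MaxPool1d(cfg.pool_size)
        width = self.msconv.c_out
        self.tcn: list[TCNBlock] = []
        if cfg.use_tcn:
            for d in dilations:
                self.tcn.append(TCNBlock(width, cfg.tcn_channels,
                                         cfg.tcn_kernel, d, cfg.dropout_p,
                                         rng))
                width = cfg.tcn_channels
        self.bilstm = BiLSTM(width, cfg.lstm_hidden, rng) \
            if cfg.use_bilstm else None
        if cfg.use_bilstm:
            width = 2 * cfg.lstm_hidden
        self.mhsa = None
        if cfg.use_mhsa:
            heads = adjust_heads(width, cfg.attn_heads)
            self.mhsa = MultiHeadSelfAttention(width, heads, rng)
        self.d_out = width

    def __call__(self, x: Tensor) -> Tensor:
        h = self.pool(self.msconv(x))
        for block in self.tcn:
            h = block(h)
        if self.bilstm is not None:
            h = self.bilstm(h)
        if self.mhsa is not None:
            h = self.mhsa(h)
        return h

    def features_before_pool(self, x: Tensor) -> Tensor:
        """Pre-pooling convolutional feature map (for causality probing)."""
        return self.msconv(x)


class TemporalFusionNet(Module):
    """The assembled dual-branch regressor.

    ``forward`` returns sigmoid-bounded predictions on the [0, 1] training
    scale; :meth:`forward_bpm` maps them onto BPM via
    y = hr_min + (hr_max − hr_min) · forward(x), so raw outputs always lie
    in the physiological range.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | None = None):
        self.cfg = cfg
        rng = rng or np.random.default_rng(cfg.seed)
        self.bcg_branch = (_Branch(4, cfg.bcg_kernels, cfg.bcg_tcn_dilations,
                                   cfg, rng)
                           if cfg.modality != "ppg_only" else None)
        self.ppg_branch = (_Branch(1, cfg.ppg_kernels, cfg.ppg_tcn_dilations,
                                   cfg, rng)
                           if cfg.modality != "bcg_only" else None)
        D = cfg.d_fusion
        self.proj_bcg = Dense(self.bcg_branch.d_out, D, rng) \
            if self.bcg_branch else None
        self.proj_ppg = Dense(self.ppg_branch.d_out, D, rng) \
            if self.ppg_branch else None
        self.concat_reduce = None
        if cfg.modality == "both" and not cfg.use_dynamic_fusion:
            self.concat_reduce = Dense(2 * D, D, rng)
        self.fc1 = Dense(D, 64, rng)
        # near-zero output layer: the fused-feature scale grows with the
        # sequence length, and a fan-in init here can start the sigmoid
        # saturated; tiny init starts predictions at mid-range instead
        self.fc2 = Dense(64, 1, rng, gain=1e-3)

    # -- forward -----------------------------------------------------------
    def _split(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return x[:, :, :4], x[:, :, 4:5]

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:
        """``x`` is ``[B, T, 5]`` (4 BCG channels then PPG); returns
        ``[B]`` unit-interval predictions."""
        x = Tensor.as_tensor(x)
        x_bcg, x_ppg = self._split(x)
        cfg = self.cfg
        if cfg.modality == "bcg_only":
            fused = self.proj_bcg(self.bcg_branch(x_bcg))
        elif cfg.modality == "ppg_only":
            fused = self.proj_ppg(self.ppg_branch(x_ppg))
        else:
            p_bcg = self.proj_bcg(self.bcg_branch(x_bcg))
            p_ppg = self.proj_ppg(self.ppg_branch(x_ppg))
            if p_bcg.shape[1] != p_ppg.shape[1]:
                raise RuntimeError(
                    "branch sequence lengths differ before fusion: "
                    f"{p_bcg.shape[1]} vs {p_ppg.shape[1]}")
            if cfg.use_dynamic_fusion:
                fused = crossmodal_fuse(p_bcg, p_ppg)
            else:
                fused = self.concat_reduce(concat([p_bcg, p_ppg], axis=-1))
        pooled = fused.mean(axis=1)                # global average over time
        u = self.fc2(self.fc1(pooled).relu())
        return u.sigmoid().reshape(u.shape[0])

    def forward_bpm(self, x) -> np.ndarray:
        """Predictions in BPM (eval-mode convenience, returns ndarray)."""
        cfg = self.cfg
        y01 = self.forward(Tensor.as_tensor(np.asarray(x, dtype=float)))
        return cfg.hr_min + (cfg.hr_max - cfg.hr_min) * y01.data

    # -- label scaling -----------------------------------------------------
    def scale_labels(self, y_bpm: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        return (np.asarray(y_bpm, dtype=float) - cfg.hr_min) \
            / (cfg.hr_max - cfg.hr_min)

    def unscale(self, y01: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        return cfg.hr_min + (cfg.hr_max - cfg.hr_min) * np.asarray(y01)

    # -- (de)serialization -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(weights):
            raise ValueError("weight list does not match parameter count")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()


def build_model(cfg: ModelConfig | None = None,
                rng: np.random.Generator | None = None) -> TemporalFusionNet:
    """Construct the network; logs the trainable parameter count."""
    import logging
    cfg = cfg or ModelConfig()
    net = TemporalFusionNet(cfg, rng)
    logging.getLogger(__name__).info(
        "built temporal fusion net (%s): %d trainable parameters",
        cfg.modality, net.n_parameters())
    return net


def save_checkpoint(net: TemporalFusionNet, path) -> None:
    """Serialize weights together with the embedded config (.npz)."""
    import dataclasses
    import json
    cfg_json = json.dumps(dataclasses.asdict(net.cfg))
    arrays = {f"w{i}": w for i, w in enumerate(net.get_weights())}
    np.savez(path, config=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> TemporalFusionNet:
    import json
    with np.load(path) as data:
        cfg_dict = json.loads(bytes(data["config"]).decode())
        for key in ("bcg_kernels", "ppg_kernels", "bcg_tcn_dilations",
                    "ppg_tcn_dilations"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = TemporalFusionNet(ModelConfig(**cfg_dict))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    net.set_weights(weights)
    net.eval()
    return net
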
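"""scikit-learn style estimator facade over the fusion network.

``FusionHeartRateRegressor`` exposes the dual-branch temporal fusion model
through the familiar fit/predict interface so it composes with sklearn
pipelines and model selection (``get_params``/``set_params``/``clone`` work
out of the box).  Input windows may be passed as ``[n, T, 5]`` arrays
(4 BCG channels then PPG, z-scored) or flattened to ``[n, T*5]``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .model import ModelConfig, build_model
from .train import TrainConfig, fit_network, _predict_bpm_batched

__all__ = ["FusionHeartRateRegressor"]

_N_CHANNELS = 5


class FusionHeartRateRegressor(RegressorMixin, BaseEstimator):
    """Heart-rate regressor fusing BCG and PPG windows.

    Parameters mirror the architecture (branch widths, TCN/BiLSTM/attention
    switches, fusion dimension) and the training protocol (Huber delta,
    Nadam learning rate with plateau halving, early stopping).  Predictions
    are bounded to ``[hr_min, hr_max]`` BPM by the sigmoid output scaling.

    Attributes (after ``fit``)
    --------------------------
    network_ : the trained network
    history_ : per-epoch training loss / validation MAE / learning rate
    n_parameters_ : trainable parameter count
    window_n_ : samples per window inferred from the training data
    """

    def __init__(self, filters_per_kernel: int = 32, pool_size: int = 2,
                 tcn_channels: int = 128, tcn_kernel: int = 3,
                 lstm_hidden: int = 128, attn_heads: int = 4,
                 d_fusion: int = 128, dropout_p: float = 0.1,
                 use_tcn: bool = True, use_bilstm: bool = True,
                 use_mhsa: bool = True, use_dynamic_fusion: bool = True,
                 modality: str = "both", hr_min: float = 35.0,
                 hr_max: float = 120.0, delta: float = 1.0,
                 learning_rate: float = 1e-3, lr_factor: float = 0.5,
                 lr_patience: int = 5, early_patience: int = 15,
                 max_epochs: int = 100, batch_size: int = 32,
                 validation_fraction: float = 0.2, random_state: int = 0):
        self.filters_per_kernel = filters_per_kernel
        self.pool_size = pool_size
        self.tcn_channels = tcn_channels
        self.tcn_kernel = tcn_kernel
        self.lstm_hidden = lstm_hidden
        self.attn_heads = attn_heads
        self.d_fusion = d_fusion
        self.dropout_p = dropout_p
        self.use_tcn = use_tcn
        self.use_bilstm = use_bilstm
        self.use_mhsa = use_mhsa
        self.use_dynamic_fusion = use_dynamic_fusion
        self.modality = modality
        self.hr_min = hr_min
        self.hr_max = hr_max
        self.delta = delta
        self.learning_rate = learning_rate
        self.lr_factor = lr_factor
        self.lr_patience = lr_patience
        self.early_patience = early_patience
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- config assembly ----------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            filters_per_kernel=self.filters_per_kernel,
            pool_size=self.pool_size, tcn_channels=self.tcn_channels,
            tcn_kernel=self.tcn_kernel, lstm_hidden=self.lstm_hidden,
            attn_heads=self.attn_heads, d_fusion=self.d_fusion,
            dropout_p=self.dropout_p, use_tcn=self.use_tcn,
            use_bilstm=self.use_bilstm, use_mhsa=self.use_mhsa,
            use_dynamic_fusion=self.use_dynamic_fusion,
            modality=self.modality, hr_min=self.hr_min, hr_max=self.hr_max,
            seed=self.random_state)

    def _train_config(self, max_epochs=None) -> TrainConfig:
        return TrainConfig(
            delta=self.delta, lr0=self.learning_rate,
            lr_factor=self.lr_factor, lr_patience=self.lr_patience,
            early_patience=self.early_patience,
            max_epochs=max_epochs or self.max_epochs,
            batch_size=self.batch_size, seed=self.random_state)

    def _as_windows(self, X: np.ndarray, fit: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] % _N_CHANNELS:
                raise ValueError(
                    f"flattened windows must have a multiple of "
                    f"{_N_CHANNELS} features, got {X.shape[1]}")
            X = X.reshape(X.shape[0], X.shape[1] // _N_CHANNELS, _N_CHANNELS)
        if X.ndim != 3 or X.shape[2] != _N_CHANNELS:
            raise ValueError(
                f"expected [n, T, {_N_CHANNELS}] windows, got {X.shape}")
        if fit:
            self.window_n_ = X.shape[1]
            self.n_features_in_ = X.shape[1] * _N_CHANNELS
        elif X.shape[1] != self.window_n_:
            raise ValueError(
                f"window length {X.shape[1]} != fitted {self.window_n_}")
        return X

    # -- sklearn API ---------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        X = self._as_windows(X, fit=True)
        y = np.asarray(y, dtype=float).ravel()
        self.network_ = build_model(self._model_config())
        self.n_parameters_ = self.network_.n_parameters()
        if X_val is not None:
            X_val = self._as_windows(np.asarray(X_val))
            y_val = np.asarray(y_val, dtype=float).ravel()
        self.history_ = fit_network(
            self.network_, X, y, self._train_config(),
            X_val=X_val, y_val_bpm=y_val,
            val_fraction=self.validation_fraction)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise AttributeError("estimator is not fitted; call fit first")
        X = self._as_windows(X)
        self.network_.eval()
        return _predict_bpm_batched(self.network_, X, self.batch_size)
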
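"""Training protocol and cross-validation driver.

Protocol: Huber loss (delta = 1.0 on the [0, 1] label scale), Nadam at
1e-3, learning rate halved when the *training* loss fails to improve for 5
consecutive epochs, early stopping on *validation* MAE with patience 15 and
best-weight restoration, batch size 32, at most 100 epochs.  The plateau
scheduler and early stopper are pure functions of the loss history so the
rules are unit-testable without a model.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelConfig, TemporalFusionNet, build_model
from .nn import Nadam, Tensor, maximum

__all__ = ["TrainConfig", "TrainHistory", "huber_loss", "PlateauScheduler",
           "EarlyStopper", "fit_network", "make_folds", "cross_validate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    delta: float = 1.0
    lr0: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 5
    early_patience: int = 15
    max_epochs: int = 100
    batch_size: int = 32
    cv_folds: int = 5
    cv_mode: str = "subject"        # subject | window
    min_delta: float = 1e-4         # improvement threshold for both rules
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")
        for name in ("lr0", "lr_patience", "early_patience", "max_epochs",
                     "batch_size", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cv_mode not in ("subject", "window"):
            raise ValueError(f"unknown cv_mode {self.cv_mode!r}")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    wall_time_s: list[float] = field(default_factory=list)
    best_epoch: int = 0


def huber_loss(y, y_pred, delta: float = 1.0):
    """Mean Huber loss: quadratic (e^2/2) for |e| <= delta, linear
    delta*(|e| - delta/2) beyond.  Accepts ndarrays (returns float) or
    autodiff Tensors (returns a scalar Tensor for backprop)."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if isinstance(y, Tensor) or isinstance(y_pred, Tensor):
        y = Tensor.as_tensor(y)
        y_pred = Tensor.as_tensor(y_pred)
        e = y_pred - y
        abs_e = maximum(e, -e)
        quad_mask = (abs_e.data <= delta).astype(float)
        quad = e * e * 0.5
        lin = abs_e * delta - 0.5 * delta * delta
        return (quad * quad_mask + lin * (1.0 - quad_mask)).mean()
    e = np.abs(np.asarray(y_pred, dtype=float) - np.asarray(y, dtype=float))
    out = np.where(e <= delta, 0.5 * e ** 2, delta * (e - 0.5 * delta))
    return float(np.mean(out))


class PlateauScheduler:
    """Halve (×``factor``) the learning rate after ``patience`` consecutive
    epochs without a training-loss improvement greater than ``min_delta``."""

    def __init__(self, lr0: float, factor: float = 0.5, patience: int = 5,
                 min_delta: float = 1e-4):
        self.lr = lr0
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self._stale = 0

    def update(self, loss: float) -> float:
        """Feed one epoch's training loss; returns the lr for the next epoch."""
        if self.best - loss > self.min_delta:
            self.best = loss
            self._stale = 0
        else:
            self._stale += 1
            if self._stale >= self.patience:
                self.lr *= self.factor
                self._stale = 0
        return self.lr


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without a validation
    improvement greater than ``min_delta``; remembers the best epoch."""

    def __init__(self, patience: int = 15, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self._stale = 0

    def update(self, metric: float, epoch: int) -> bool:
        """Feed one epoch's validation metric; True means stop now."""
        if self.best - metric > self.min_delta:
            self.best = metric
            self.best_epoch = epoch
            self._stale = 0
            return False
        self._stale += 1
        return self._stale >= self.patience

    @property
    def improved(self) -> bool:
        return self._stale == 0


def fit_network(net: TemporalFusionNet, X: np.ndarray, y_bpm: np.ndarray,
                cfg: TrainConfig | None = None,
                X_val: np.ndarray | None = None,
                y_val_bpm: np.ndarray | None = None,
                val_fraction: float = 0.2) -> TrainHistory:
    """Train ``net`` in place; returns the per-epoch history.

    When no explicit validation set is given, a seeded random
    ``val_fraction`` of the windows is held out.  Weights from the epoch
    with the best validation MAE are restored at the end.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y_bpm = np.asarray(y_bpm, dtype=float)
    if X.shape[0] != y_bpm.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 2 * cfg.batch_size:
        raise ValueError(
            f"need at least {2 * cfg.batch_size} windows, got {X.shape[0]}")
    rng = np.random.default_rng(cfg.seed)
    if X_val is None:
        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = max(int(round(val_fraction * n)), 1)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_val, y_val_bpm = X[val_idx], y_bpm[val_idx]
        X, y_bpm = X[tr_idx], y_bpm[tr_idx]
    y01 = net.scale_labels(y_bpm)

    opt = Nadam(net.parameters(), lr=cfg.lr0)
    sched = PlateauScheduler(cfg.lr0, cfg.lr_factor, cfg.lr_patience,
                             cfg.min_delta)
    stopper = EarlyStopper(cfg.early_patience, cfg.min_delta)
    hist = TrainHistory()
    best_weights = net.get_weights()
    n_train = X.shape[0]
    for epoch in range(cfg.max_epochs):
        t0 = time.perf_counter()
        net.train()
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue
            pred = net.forward(Tensor(X[idx]))
            loss = huber_loss(y01[idx], pred, cfg.delta)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.data}")
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        train_loss = float(np.mean(losses))
        net.eval()
        pred_val = _predict_bpm_batched(net, X_val, cfg.batch_size)
        val_mae = float(np.mean(np.abs(pred_val - y_val_bpm)))
        hist.train_loss.append(train_loss)
        hist.val_mae.append(val_mae)
        hist.lr.append(opt.lr)
        hist.wall_time_s.append(time.perf_counter() - t0)
        opt.lr = sched.update(train_loss)
        stop = stopper.update(val_mae, epoch)
        if stopper.improved:
            best_weights = net.get_weights()
        logger.info("epoch %3d  loss %.5f  val MAE %.3f BPM  lr %.2e",
                    epoch, train_loss, val_mae, opt.lr)
        if stop:
            logger.info("early stop at epoch %d (best %d)", epoch,
                        stopper.best_epoch)
            break
    hist.best_epoch = max(stopper.best_epoch, 0)
    net.set_weights(best_weights)
    net.eval()
    return hist


def _predict_bpm_batched(net: TemporalFusionNet, X: np.ndarray,
                         batch_size: int) -> np.ndarray:
    out = []
    for start in range(0, X.shape[0], batch_size):
        out.append(net.forward_bpm(X[start:start + batch_size]))
    return np.concatenate(out)


def make_folds(subjects: np.ndarray, n_folds: int, mode: str = "subject",
               seed: int = 0) -> list[np.ndarray]:
    """Index partitions for cross-validation.

    ``subject`` mode shuffles the distinct subject ids under ``seed`` and
    assigns whole subjects to folds (no subject appears in two folds);
    ``window`` mode shuffles window indices directly.
    """
    subjects = np.asarray(subjects)
    rng = np.random.default_rng(seed)
    n = subjects.shape[0]
    if mode == "subject":
        uniq = np.unique(subjects)
        if uniq.size < n_folds:
            raise ValueError(
                f"{uniq.size} subjects < {n_folds} folds in subject mode")
        order = rng.permutation(uniq)
        groups = np.array_split(order, n_folds)
        return [np.flatnonzero(np.isin(subjects, g)) for g in groups]
    if mode == "window":
        perm = rng.permutation(n)
        return [np.sort(part) for part in np.array_split(perm, n_folds)]
    raise ValueError(f"unknown cv mode {mode!r}")


def cross_validate(X: np.ndarray, y_bpm: np.ndarray, subjects: np.ndarray,
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None):
    """K-fold cross-validation; returns (per-fold reports, pooled report).

    Each window appears in exactly one test fold; pooled metrics are
    computed over the concatenated out-of-fold predictions.
    """
    from .evaluate import report_from_arrays

    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    folds = make_folds(subjects, train_cfg.cv_folds, train_cfg.cv_mode,
                       train_cfg.seed)
    all_idx = np.concatenate(folds)
    if np.unique(all_idx).size != X.shape[0]:
        raise AssertionError("folds do not partition the windows")
    reports = []
    oof_true, oof_pred, oof_subj = [], [], []
    for k, test_idx in enumerate(folds):
        if train_cfg.cv_mode == "subject":
            leak = set(subjects[test_idx]) & set(
                np.delete(subjects, test_idx))
            if leak:
                raise AssertionError(f"subject leakage across folds: {leak}")
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        net = build_model(replace(model_cfg, seed=model_cfg.seed + k))
        fit_network(net, X[train_mask], y_bpm[train_mask], train_cfg)
        pred = _predict_bpm_batched(net, X[test_idx], train_cfg.batch_size)
        reports.append(report_from_arrays(y_bpm[test_idx], pred,
                                          subjects[test_idx]))
        oof_true.append(y_bpm[test_idx])
        oof_pred.append(pred)
        oof_subj.append(subjects[test_idx])
        logger.info("fold %d/%d test MAE %.3f BPM", k + 1, len(folds),
                    reports[-1].mae)
    pooled = report_from_arrays(np.concatenate(oof_true),
                                np.concatenate(oof_pred),
                                np.concatenate(oof_subj))
    return reports, pooled
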
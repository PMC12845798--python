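"""Agreement analysis between predicted and reference heart rates.

Three statistics: mean absolute error (MAE, BPM), Bland–Altman mean bias
with 95% limits of agreement (bias ± 1.96·SD of the differences, sample SD
with the n−1 denominator), and the Pearson correlation coefficient.
Differences are oriented predicted − reference.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

__all__ = ["EvalReport", "mae", "bland_altman", "pearson",
           "report_from_arrays", "report", "bland_altman_plot",
           "scatter_plot"]

logger = logging.getLogger(__name__)

_LOA_Z = 1.96   # two-sided 95% normal quantile


@dataclass
class EvalReport:
    mae: float
    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float | None
    n_windows: int
    per_subject: dict[str, tuple[float, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mae_bpm": self.mae,
            "bias_bpm": self.bias,
            "loa_low_bpm": self.loa_low,
            "loa_high_bpm": self.loa_high,
            "pearson_r": self.pearson_r,
            "n_windows": self.n_windows,
            "per_subject": {k: {"mae_bpm": v[0], "n": v[1]}
                            for k, v in self.per_subject.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _check_pair(y, y_pred, min_n: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {y.size}")
    return y, y_pred


def mae(y, y_pred) -> float:
    """Mean absolute error (BPM)."""
    y, y_pred = _check_pair(y, y_pred, 1)
    return float(np.mean(np.abs(y_pred - y)))


def bland_altman(y, y_pred) -> tuple[float, float, float]:
    """(bias, loa_low, loa_high) of the differences d = predicted − reference.

    bias = mean(d); limits = bias ± 1.96·sd(d) with the n−1 denominator.
    For plotting, the conventional x-axis is the pairwise mean (y+ŷ)/2.
    """
    y, y_pred = _check_pair(y, y_pred, 2)
    d = y_pred - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - _LOA_Z * sd, bias + _LOA_Z * sd


def pearson(y, y_pred) -> float | None:
    """Product-moment correlation; None (with a warning) when either
    array has zero variance."""
    y, y_pred = _check_pair(y, y_pred, 2)
    if np.std(y) == 0 or np.std(y_pred) == 0:
        warnings.warn("Pearson r undefined for zero-variance input")
        return None
    return float(scipy.stats.pearsonr(y, y_pred).statistic)


def report_from_arrays(y, y_pred, subjects=None) -> EvalReport:
    """Pooled + per-subject agreement report."""
    y, y_pred = _check_pair(y, y_pred, 2)
    per_subject: dict[str, tuple[float, int]] = {}
    if subjects is not None:
        subjects = np.asarray(subjects)
        for sid in np.unique(subjects):
            m = subjects == sid
            per_subject[str(sid)] = (mae(y[m], y_pred[m]), int(m.sum()))
    bias, lo, hi = bland_altman(y, y_pred)
    return EvalReport(mae=mae(y, y_pred), bias=bias, loa_low=lo, loa_high=hi,
                      pearson_r=pearson(y, y_pred), n_windows=y.size,
                      per_subject=per_subject)


def report(predictions: pd.DataFrame | str, out_json=None,
           plot_dir=None) -> EvalReport:
    """Build an :class:`EvalReport` from a predictions table (DataFrame or
    CSV path) with columns subject_id, hr_true, hr_pred; optionally write
    JSON and figures."""
    if isinstance(predictions, (str,)) or hasattr(predictions, "__fspath__"):
        predictions = pd.read_csv(predictions)
    if predictions.empty:
        raise ValueError("empty predictions table")
    for col in ("subject_id", "hr_true", "hr_pred"):
        if col not in predictions.columns:
            raise ValueError(f"predictions table missing column {col!r}")
    rep = report_from_arrays(predictions["hr_true"].to_numpy(),
                             predictions["hr_pred"].to_numpy(),
                             predictions["subject_id"].to_numpy())
    if out_json is not None:
        rep.to_json(out_json)
    if plot_dir is not None:
        import pathlib
        plot_dir = pathlib.Path(plot_dir)
        plot_dir.mkdir(parents=True, exist_ok=True)
        bland_altman_plot(predictions["hr_true"], predictions["hr_pred"],
                          plot_dir / "bland_altman.png")
        scatter_plot(predictions["hr_true"], predictions["hr_pred"],
                     plot_dir / "scatter.png")
    return rep


def _get_axes():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def bland_altman_plot(y, y_pred, path) -> None:
    plt = _get_axes()
    y, y_pred = _check_pair(y, y_pred, 2)
    bias, lo, hi = bland_altman(y, y_pred)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((y + y_pred) / 2, y_pred - y, s=8, alpha=0.5)
    for val, style in ((bias, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(val, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("Mean of reference and predicted HR (BPM)")
    ax.set_ylabel("Predicted − reference (BPM)")
    ax.set_title(f"Bland–Altman: bias {bias:.2f}, LoA [{lo:.2f}, {hi:.2f}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_plot(y, y_pred, path) -> None:
    plt = _get_axes()
    y, y_pred = _check_pair(y, y_pred, 2)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y, y_pred, s=8, alpha=0.5)
    lims = [min(y.min(), y_pred.min()) - 2, max(y.max(), y_pred.max()) + 2]
    ax.plot(lims, lims, "k--", linewidth=1, label="y = x")
    ax.set_xlim(lims), ax.set_ylim(lims)
    ax.set_xlabel("Reference HR (BPM)")
    ax.set_ylabel("Predicted HR (BPM)")
    r = pearson(y, y_pred)
    ax.set_title("Identity agreement" + (f" (r = {r:.3f})" if r else ""))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
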
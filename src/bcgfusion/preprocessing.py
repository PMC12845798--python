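"""Signal conditioning and window/label extraction.

Pipeline (driver :func:`preprocess_record`): linear interpolation of missing
samples → zero-phase band-pass filtering at the native rate → polyphase
downsampling to 100 Hz → ECG R-peak labelled 4 s / 1 s sliding windows →
exclusion of labels outside 35–120 BPM → per-window per-channel z-scoring.
Missing samples are repaired first because a zero-phase IIR filter would
smear NaNs across the whole record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.ndimage
import scipy.signal

from .records import SignalRecord, WindowedSample

__all__ = [
    "PreprocessConfig", "bandpass", "resample_to_target",
    "interpolate_missing", "detect_r_peaks", "r_peak_times",
    "hr_from_window", "segment_windows", "exclude_outliers", "zscore",
    "preprocess_record", "preprocess_records", "windows_to_arrays",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    fs_target: float = 100.0
    window_s: float = 4.0
    stride_s: float = 1.0
    hr_min: float = 35.0
    hr_max: float = 120.0
    bcg_band: tuple[float, float] = (0.3, 24.0)
    ecg_band: tuple[float, float] = (0.5, 40.0)
    refractory_s: float = 0.25
    zscore_scope: str = "window"    # "window" (default) or "record"

    def __post_init__(self) -> None:
        if self.zscore_scope not in ("window", "record"):
            raise ValueError(
                f"zscore_scope must be 'window' or 'record', "
                f"got {self.zscore_scope!r}")
        if self.hr_min >= self.hr_max:
            raise ValueError("hr_min must be < hr_max")
        wn = self.window_s * self.fs_target
        if abs(wn - round(wn)) > 1e-9:
            raise ValueError("window_s * fs_target must be integral")
        for band in (self.bcg_band, self.ecg_band):
            if not (0 < band[0] < band[1] < self.fs_target / 2):
                raise ValueError(
                    f"band {band} must satisfy 0 < lo < hi < fs_target/2")

    @property
    def window_n(self) -> int:
        return int(round(self.window_s * self.fs_target))


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (applied forward and
    backward, so filtering does not shift R-peak timing)."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band [{lo}, {hi}] invalid for fs={fs}")
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def resample_to_target(x: np.ndarray, fs_in: float, fs_target: float
                       ) -> np.ndarray:
    """Polyphase anti-aliased downsampling; identity when rates match."""
    if fs_in < fs_target:
        raise ValueError("upsampling not supported (fs_in < fs_target)")
    if fs_in == fs_target:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_target / fs_in).limit_denominator(10000)
    return scipy.signal.resample_poly(np.asarray(x, dtype=float),
                                      frac.numerator, frac.denominator,
                                      axis=0)


def interpolate_missing(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN runs; leading/trailing gaps take the
    nearest valid value.  Works along axis 0 for 2-D input."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        return np.column_stack([interpolate_missing(x[:, j])
                                for j in range(x.shape[1])])
    mask = np.isnan(x)
    if mask.all():
        raise ValueError("cannot interpolate an all-missing signal")
    if not mask.any():
        return x.copy()
    idx = np.arange(x.size)
    return np.interp(idx, idx[~mask], x[~mask])


def detect_r_peaks(ecg: np.ndarray, fs: float, refractory_s: float = 0.25
                   ) -> np.ndarray:
    """Pan–Tompkins-style R-peak detection.

    Chain: 0.5–40 Hz band-pass → differentiate → square → 150 ms moving
    integration → peaks above 0.5x a 2 s rolling maximum, separated by at
    least ``refractory_s``.  Detected envelope peaks are snapped to the
    nearest local maximum of the filtered ECG within ±100 ms.  Returns
    integer sample indices (strictly increasing); a flat signal yields an
    empty array.
    """
    ecg = np.asarray(ecg, dtype=float).ravel()
    n = ecg.size
    if n <= fs:
        raise ValueError("need at least one second of ECG")
    if np.ptp(ecg) == 0:
        return np.array([], dtype=int)
    hi = min(40.0, 0.45 * fs)
    filt = bandpass(ecg, fs, 0.5, hi)
    env = np.gradient(filt) ** 2
    win = max(int(0.150 * fs), 1)
    env = np.convolve(env, np.ones(win) / win, mode="same")
    roll = max(int(2.0 * fs), 1)
    local_max = scipy.ndimage.maximum_filter1d(env, size=roll, mode="nearest")
    floor = 1e-3 * env.max()
    thresh = np.maximum(0.5 * local_max, floor)
    dist = max(int(refractory_s * fs), 1)
    peaks, _ = scipy.signal.find_peaks(env, height=None, distance=dist)
    peaks = peaks[env[peaks] >= thresh[peaks]]
    # snap to the filtered-ECG local maximum (envelope lags the R wave)
    half = int(0.100 * fs)
    snapped = []
    for p in peaks:
        i0, i1 = max(p - half, 0), min(p + half + 1, n)
        snapped.append(i0 + int(np.argmax(filt[i0:i1])))
    snapped = np.array(sorted(set(snapped)), dtype=int)
    # enforce the refractory period after snapping: keep the larger peak
    keep: list[int] = []
    for p in snapped:
        if keep and p - keep[-1] < dist:
            if filt[p] > filt[keep[-1]]:
                keep[-1] = int(p)
        else:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def r_peak_times(ecg: np.ndarray, fs: float, refractory_s: float = 0.25,
                 refine: bool = True) -> np.ndarray:
    """R-peak times in seconds, with optional sub-sample refinement.

    A 3-point parabolic fit around each detected index recovers timing well
    below the sample period, which matters for labels at 100 Hz where one
    sample is 10 ms.
    """
    idx = detect_r_peaks(ecg, fs, refractory_s)
    ecg = np.asarray(ecg, dtype=float).ravel()
    times = idx.astype(float)
    if refine:
        for j, p in enumerate(idx):
            if 0 < p < ecg.size - 1:
                y0, y1, y2 = ecg[p - 1], ecg[p], ecg[p + 1]
                denom = y0 - 2 * y1 + y2
                if denom < 0:  # proper local maximum
                    times[j] = p + 0.5 * (y0 - y2) / denom
    return times / fs


def hr_from_window(peak_times: np.ndarray) -> float | None:
    """Window heart rate = 60 / mean RR over the peaks inside the window;
    ``None`` (unlabeled) when fewer than two peaks are present."""
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 2:
        return None
    return 60.0 / float(np.mean(np.diff(peak_times)))


def segment_windows(record: SignalRecord, cfg: PreprocessConfig | None = None,
                    peak_times: np.ndarray | None = None
                    ) -> list[WindowedSample]:
    """Slide a ``window_s`` window with ``stride_s`` stride over one record
    (never across subjects) and attach the ECG-derived label to each.

    Window count is floor((N/fs − window_s)/stride_s) + 1 when the record
    is at least one window long, else zero.  Windows with fewer than two
    R-peaks are dropped (logged).
    """
    cfg = cfg or PreprocessConfig()
    if record.fs != cfg.fs_target:
        raise ValueError(
            f"record fs={record.fs} != fs_target={cfg.fs_target}; "
            "resample first")
    dur = record.duration_s
    if dur < cfg.window_s:
        return []
    if peak_times is None:
        peak_times = r_peak_times(record.ecg, record.fs, cfg.refractory_s)
    n_windows = int(math.floor((dur - cfg.window_s) / cfg.stride_s)) + 1
    wn = cfg.window_n
    samples: list[WindowedSample] = []
    n_unlabeled = 0
    for w in range(n_windows):
        t0 = w * cfg.stride_s
        i0 = int(round(t0 * cfg.fs_target))
        in_win = peak_times[(peak_times >= t0) & (peak_times < t0 + cfg.window_s)]
        hr = hr_from_window(in_win)
        if hr is None:
            n_unlabeled += 1
            continue
        samples.append(WindowedSample(
            bcg=record.bcg[i0:i0 + wn].copy(),
            ppg=record.ppg[i0:i0 + wn].copy(),
            hr_bpm=hr, subject_id=record.subject_id, t_start=t0))
    if n_unlabeled:
        logger.info("%s: dropped %d windows with < 2 R-peaks",
                    record.subject_id, n_unlabeled)
    return samples


def exclude_outliers(samples: list[WindowedSample],
                     cfg: PreprocessConfig | None = None
                     ) -> list[WindowedSample]:
    """Keep windows whose label lies inside [hr_min, hr_max] (inclusive)."""
    cfg = cfg or PreprocessConfig()
    kept = [s for s in samples if cfg.hr_min <= s.hr_bpm <= cfg.hr_max]
    removed = len(samples) - len(kept)
    if removed:
        logger.info("excluded %d windows with out-of-range labels", removed)
    return kept


def zscore(x: np.ndarray) -> np.ndarray:
    """z = (x − μ)/σ with population σ; a constant signal maps to zeros."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    if x.ndim == 1:
        if sd > 0:
            out = (x - mu) / sd
        else:
            logger.warning("z-score of a constant signal: returning zeros")
    else:
        for j in range(x.shape[1]):
            if sd[j] > 0:
                out[:, j] = (x[:, j] - mu[j]) / sd[j]
            else:
                logger.warning("z-score of a constant channel %d: zeros", j)
    return out


def preprocess_record(record: SignalRecord,
                      cfg: PreprocessConfig | None = None
                      ) -> list[WindowedSample]:
    """Full conditioning of one record into normalized labelled windows."""
    cfg = cfg or PreprocessConfig()
    bcg = interpolate_missing(record.bcg)
    ppg = interpolate_missing(record.ppg)
    ecg = interpolate_missing(record.ecg)
    bcg = bandpass(bcg, record.fs, *cfg.bcg_band)
    ppg = bandpass(ppg, record.fs, *cfg.bcg_band)
    ecg = bandpass(ecg, record.fs, *cfg.ecg_band)
    if record.fs != cfg.fs_target:
        bcg = resample_to_target(bcg, record.fs, cfg.fs_target)
        ppg = resample_to_target(ppg, record.fs, cfg.fs_target)
        ecg = resample_to_target(ecg, record.fs, cfg.fs_target)
    if cfg.zscore_scope == "record":
        bcg, ppg = zscore(bcg), zscore(ppg)
    clean = SignalRecord(subject_id=record.subject_id, fs=cfg.fs_target,
                         bcg=bcg, ppg=ppg, ecg=ecg,
                         beat_times=record.beat_times, ptt_s=record.ptt_s)
    samples = segment_windows(clean, cfg)
    samples = exclude_outliers(samples, cfg)
    if cfg.zscore_scope == "window":
        for s in samples:
            s.bcg = zscore(s.bcg)
            s.ppg = zscore(s.ppg)
    return samples


def preprocess_records(records, cfg: PreprocessConfig | None = None
                       ) -> list[WindowedSample]:
    cfg = cfg or PreprocessConfig()
    out: list[WindowedSample] = []
    for rec in records:
        out.extend(preprocess_record(rec, cfg))
    return out


def windows_to_arrays(samples: list[WindowedSample]
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into ``X [n, window_n, 5]`` (4 BCG channels then PPG),
    labels ``y`` (BPM), subject ids and window start times."""
    if not samples:
        raise ValueError("no windows to stack")
    X = np.stack([np.concatenate([s.bcg, s.ppg], axis=1) for s in samples])
    y = np.array([s.hr_bpm for s in samples])
    subjects = np.array([s.subject_id for s in samples])
    t_start = np.array([s.t_start for s in samples])
    return X, y, subjects, t_start
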
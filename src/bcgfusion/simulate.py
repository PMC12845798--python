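"""Synthetic BCG/PPG/ECG cohort generator.

Emulates a bed-sensor acquisition setup: a 4-channel electromechanical-film
BCG, a finger PPG delayed by the pulse transit time (PTT), and a reference
ECG, all synchronized and sampled at a common rate.  Beat timing is the
ground truth; waveform morphology is deliberately simple (gross I-J-K shape
for BCG, a smooth unimodal pulse for PPG, a narrow R spike for ECG) — enough
to exercise filtering, R-peak labelling, windowing and the regression model,
with no claim of hemodynamic fidelity.

Kernels are evaluated analytically at each (continuous-valued) beat time, so
beat instants are not quantized to the sample grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .records import SignalRecord

__all__ = [
    "BeatProcess", "NoiseSpec", "generate_beat_times", "synthesize_record",
    "make_cohort", "HR_MIN_BPM", "HR_MAX_BPM",
]

logger = logging.getLogger(__name__)

#: Physiological resting heart-rate range (BPM); labels outside it are
#: treated as outliers downstream.
HR_MIN_BPM = 35.0
HR_MAX_BPM = 120.0

_RR_MIN_S = 0.3
_RR_MAX_S = 2.0

# I-J-K ballistocardiogram complex: (offset s, relative amplitude, sigma s).
# Three Gaussian lobes spanning ~150 ms after the R peak.
_BCG_LOBES = ((0.030, -0.4, 0.015), (0.075, 1.0, 0.018), (0.120, -0.6, 0.015))
_ECG_SIGMA_S = 0.010          # R-spike width
_PPG_WIDTH_S = 0.300          # raised-cosine full width
_RESP_AM_DEPTH = 0.2          # respiratory amplitude modulation of BCG


@dataclass(frozen=True)
class BeatProcess:
    """Ground-truth heartbeat point process."""

    beat_times: np.ndarray                 # strictly increasing, seconds
    hr_profile: Callable[[np.ndarray], np.ndarray]   # time -> BPM
    hrv_sd: float                          # per-beat RR jitter SD, seconds

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        rr = np.diff(bt)
        if rr.size and (np.any(rr <= 0)):
            raise ValueError("beat_times must be strictly increasing")

    @property
    def rr_intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive/multiplicative disturbances applied to synthetic channels.

    ``white_sd`` — Gaussian sensor noise SD (signal units; the J-wave has
    unit amplitude).  ``respiration_hz``/``respiration_amp`` — additive
    low-frequency baseline plus a fixed ±20% amplitude modulation of the
    BCG complexes.  ``artifact_rate`` (events/min) / ``artifact_amp`` —
    Poisson-timed bursts (0.5–2 s) of random-walk (colored) noise emulating
    body movement.  Same spec + same seed gives identical noise.
    """

    white_sd: float = 0.1
    respiration_hz: float = 0.25
    respiration_amp: float = 0.3
    artifact_rate: float = 2.0
    artifact_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("white_sd", "respiration_hz", "respiration_amp",
                     "artifact_rate", "artifact_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def silent(cls, seed: int = 0) -> "NoiseSpec":
        """A spec that adds nothing (for noise-free fixtures)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, seed)


def generate_beat_times(duration_s: float, mean_hr: float, hrv_sd: float = 0.0,
                        seed: int = 0, hr_drift_amp_bpm: float = 0.0,
                        hr_drift_hz: float = 0.0) -> BeatProcess:
    """Draw a heartbeat point process.

    The first beat is at t=0; each RR interval is 60/HR(t) plus Gaussian
    jitter of SD ``hrv_sd`` seconds, truncated to the physiological range
    [0.3, 2.0] s.  ``hr_drift_amp_bpm``/``hr_drift_hz`` superimpose a slow
    sinusoidal drift on the instantaneous heart rate, emulating resting
    autonomic variation; with both zero the profile is constant.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (HR_MIN_BPM <= mean_hr <= HR_MAX_BPM):
        raise ValueError(
            f"mean_hr={mean_hr} outside the physiological resting range "
            f"[{HR_MIN_BPM:.0f}, {HR_MAX_BPM:.0f}] BPM")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi) if hr_drift_amp_bpm > 0 else 0.0

    def hr_profile(t):
        t = np.asarray(t, dtype=float)
        return mean_hr + hr_drift_amp_bpm * np.sin(
            2 * np.pi * hr_drift_hz * t + phase)

    times = [0.0]
    while True:
        t = times[-1]
        rr = 60.0 / float(hr_profile(t))
        if hrv_sd > 0:
            rr = rr + rng.normal(0.0, hrv_sd)
        rr = float(np.clip(rr, _RR_MIN_S, _RR_MAX_S))
        t_next = t + rr
        if t_next >= duration_s:
            break
        times.append(t_next)
    return BeatProcess(np.asarray(times), hr_profile, hrv_sd)


def _add_pulses(signal: np.ndarray, fs: float, centers: np.ndarray,
                half_width_s: float, shape) -> None:
    """Add ``shape(t_rel)`` around each center, evaluated analytically."""
    n = signal.shape[0]
    for tc in centers:
        i0 = max(int(np.floor((tc - half_width_s) * fs)), 0)
        i1 = min(int(np.ceil((tc + half_width_s) * fs)) + 1, n)
        if i0 >= i1:
            continue
        t_rel = np.arange(i0, i1) / fs - tc
        signal[i0:i1] += shape(t_rel)


def _gauss(t: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _raised_cosine(t: np.ndarray, width: float) -> np.ndarray:
    out = 0.5 * (1.0 + np.cos(2 * np.pi * t / width))
    out[np.abs(t) > width / 2] = 0.0
    return out


def _artifact_bursts(n: int, fs: float, rate_per_min: float, amp: float,
                     rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n)
    if rate_per_min <= 0 or amp <= 0:
        return out
    duration_s = n / fs
    k = rng.poisson(rate_per_min * duration_s / 60.0)
    for _ in range(k):
        t0 = rng.uniform(0, duration_s)
        dur = rng.uniform(0.5, 2.0)
        i0, i1 = int(t0 * fs), min(int((t0 + dur) * fs), n)
        if i1 - i0 < 2:
            continue
        walk = np.cumsum(rng.normal(size=i1 - i0))
        walk -= walk.mean()
        sd = walk.std()
        if sd > 0:
            walk /= sd
        walk *= np.hanning(i1 - i0)
        out[i0:i1] += amp * walk
    return out


def synthesize_record(beats: BeatProcess, fs: float = 100.0,
                      ptt_s: float = 0.2,
                      noise: NoiseSpec | None = None,
                      channel_gains: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
                      duration_s: float | None = None,
                      subject_id: str = "synthetic",
                      ppg_noise: NoiseSpec | None = None) -> SignalRecord:
    """Render a beat process into synchronized BCG/PPG/ECG waveforms.

    ECG carries a unit Gaussian R spike at each beat; every BCG channel
    carries the I-J-K complex scaled by its gain; the PPG pulse arrives
    ``ptt_s`` seconds after the beat.  ``noise`` shapes the BCG channels
    (ECG receives only attenuated white noise), ``ppg_noise`` the PPG
    channel (defaults to ``noise`` with an offset seed so the draws are
    independent).
    """
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if not 0.0 <= ptt_s <= 0.4:
        raise ValueError("ptt_s must lie in [0, 0.4] s")
    if len(channel_gains) != 4:
        raise ValueError("channel_gains must have 4 entries")
    noise = noise or NoiseSpec.silent()
    if ppg_noise is None:
        ppg_noise = replace(noise, seed=noise.seed + 1)

    bt = beats.beat_times
    if duration_s is None:
        duration_s = (float(bt[-1]) + 1.0) if bt.size else 10.0
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if bt.size == 0:
        logger.warning("empty beat sequence: record contains noise only")

    ecg = np.zeros(n)
    _add_pulses(ecg, fs, bt, 5 * _ECG_SIGMA_S,
                lambda tr: _gauss(tr, 1.0, 0.0, _ECG_SIGMA_S))

    bcg_shape = np.zeros(n)
    for mu, amp, sigma in _BCG_LOBES:
        _add_pulses(bcg_shape, fs, bt, mu + 5 * sigma,
                    lambda tr, a=amp, m=mu, s=sigma: _gauss(tr, a, m, s))

    ppg = np.zeros(n)
    _add_pulses(ppg, fs, bt + ptt_s, _PPG_WIDTH_S / 2,
                lambda tr: _raised_cosine(tr, _PPG_WIDTH_S))

    rng = np.random.default_rng(noise.seed)
    # respiratory amplitude modulation of the mechanical complexes
    if noise.respiration_hz > 0 and noise.respiration_amp > 0:
        resp_phase = rng.uniform(0, 2 * np.pi)
        am = 1.0 + _RESP_AM_DEPTH * np.sin(
            2 * np.pi * noise.respiration_hz * t + resp_phase)
        baseline = noise.respiration_amp * np.sin(
            2 * np.pi * noise.respiration_hz * t + resp_phase)
    else:
        am = np.ones(n)
        baseline = np.zeros(n)

    bcg = np.empty((n, 4))
    for c, gain in enumerate(channel_gains):
        chan = gain * bcg_shape * am + baseline
        if noise.white_sd > 0:
            chan = chan + rng.normal(0.0, noise.white_sd, n)
        chan = chan + _artifact_bursts(n, fs, noise.artifact_rate,
                                       noise.artifact_amp, rng)
        bcg[:, c] = chan

    if noise.white_sd > 0:
        ecg = ecg + rng.normal(0.0, 0.1 * noise.white_sd, n)

    prng = np.random.default_rng(ppg_noise.seed)
    if ppg_noise.respiration_hz > 0 and ppg_noise.respiration_amp > 0:
        ppg = ppg + ppg_noise.respiration_amp * np.sin(
            2 * np.pi * ppg_noise.respiration_hz * t + prng.uniform(0, 2 * np.pi))
    if ppg_noise.white_sd > 0:
        ppg = ppg + prng.normal(0.0, ppg_noise.white_sd, n)
    ppg = ppg + _artifact_bursts(n, fs, ppg_noise.artifact_rate,
                                 ppg_noise.artifact_amp, prng)

    keep = bt[bt < n / fs]
    return SignalRecord(subject_id=subject_id, fs=fs, bcg=bcg, ppg=ppg,
                        ecg=ecg, beat_times=keep, ptt_s=ptt_s)


def make_cohort(n_subjects: int, duration_s: float = 120.0,
                hr_range: tuple[float, float] = (50.0, 100.0),
                seed: int = 0, fs: float = 100.0,
                noise: NoiseSpec | None = None,
                ppg_noise: NoiseSpec | None = None,
                hrv_sd: float = 0.02,
                hr_drift_amp_bpm: float = 5.0,
                hr_drift_hz: float = 0.02,
                out_path=None, out_format: str | None = None
                ) -> list[SignalRecord]:
    """Generate a cohort of synthetic subjects.

    Per-subject mean HR is drawn uniformly from ``hr_range`` and PTT from
    [0.15, 0.30] s.  Defaults emulate a resting bed-sensor session:
    moderate sensor noise, 0.25 Hz respiration, occasional movement
    artifacts, 20 ms RR jitter and a slow ±5 BPM heart-rate drift.
    Deterministic under ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    lo, hi = hr_range
    if not (HR_MIN_BPM <= lo <= hi <= HR_MAX_BPM):
        raise ValueError(
            f"hr_range must lie within [{HR_MIN_BPM:.0f}, {HR_MAX_BPM:.0f}] BPM")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        mean_hr = float(rng.uniform(lo, hi))
        ptt = float(rng.uniform(0.15, 0.30))
        beat_seed = int(rng.integers(0, 2 ** 31 - 1))
        noise_seed = int(rng.integers(0, 2 ** 31 - 1))
        beats = generate_beat_times(duration_s, mean_hr, hrv_sd=hrv_sd,
                                    seed=beat_seed,
                                    hr_drift_amp_bpm=hr_drift_amp_bpm,
                                    hr_drift_hz=hr_drift_hz)
        nspec = replace(noise, seed=noise_seed) if noise is not None \
            else NoiseSpec(seed=noise_seed)
        pspec = replace(ppg_noise, seed=noise_seed + 1) \
            if ppg_noise is not None else None
        records.append(synthesize_record(
            beats, fs=fs, ptt_s=ptt, noise=nspec, ppg_noise=pspec,
            duration_s=duration_s, subject_id=f"S{i:03d}"))
    if out_path is not None:
        from .io import write_signal_container
        write_signal_container(records, out_path, out_format)
    return records
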
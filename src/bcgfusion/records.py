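"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SignalRecord", "WindowedSample"]


@dataclass
class SignalRecord:
    """One subject's synchronized multi-channel recording.

    Channels: 4-channel BCG (electromechanical film bed sensor), 1-channel
    PPG and 1-channel reference ECG, all sampled at ``fs`` Hz.  When the
    record is synthetic, ``beat_times`` carries the ground-truth heartbeat
    instants (seconds from record start) and ``ptt_s`` the configured
    pulse-transit-time lag between the ECG R-peak and PPG pulse arrival.
    """

    subject_id: str
    fs: float
    bcg: np.ndarray          # [N, 4]
    ppg: np.ndarray          # [N, 1]
    ecg: np.ndarray          # [N, 1]
    beat_times: np.ndarray | None = None
    ptt_s: float = 0.0

    def __post_init__(self) -> None:
        self.bcg = np.atleast_2d(np.asarray(self.bcg, dtype=float))
        self.ppg = np.asarray(self.ppg, dtype=float).reshape(-1, 1)
        self.ecg = np.asarray(self.ecg, dtype=float).reshape(-1, 1)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.bcg.shape[1] != 4:
            raise ValueError(f"BCG must have 4 channels, got {self.bcg.shape[1]}")
        n = self.bcg.shape[0]
        if not (self.ppg.shape[0] == n and self.ecg.shape[0] == n):
            raise ValueError("all channel arrays must share the same length")
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if self.beat_times.size and (
                    self.beat_times.min() < 0
                    or self.beat_times.max() >= n / self.fs):
                raise ValueError("beat_times must lie in [0, N/fs)")
        if self.ptt_s < 0:
            raise ValueError("ptt_s must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.bcg.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class WindowedSample:
    """One 4-second analysis window: 400-sample BCG/PPG arrays at 100 Hz,
    the ECG-derived heart-rate label and provenance metadata."""

    bcg: np.ndarray          # [window_n, 4]
    ppg: np.ndarray          # [window_n, 1]
    hr_bpm: float
    subject_id: str
    t_start: float
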
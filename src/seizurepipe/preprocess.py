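"""Band-pass filtering and ECG smoothing.

Channel conditioning ahead of peak detection: 4th-order Butterworth
band-passes applied forward-backward (zero phase, so peak latencies used by
the pulse-transit-time measurement are not biased), plus a short moving
average on the ECG. Default bands: ECG 0.4-20 Hz, PPG 0.4-3 Hz,
EEG 0.5-40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    low_cut_hz: float
    high_cut_hz: float
    order: int = 4
    zero_phase: bool = True
    smoothing_window_ms: float | None = None  # ECG post-smoothing

    def __post_init__(self) -> None:
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise FilterError("need 0 < low_cut_hz < high_cut_hz")
        if self.order < 1:
            raise FilterError("order must be >= 1")


ECG_FILTER = FilterSpec(0.4, 20.0, smoothing_window_ms=12.0)
PPG_FILTER = FilterSpec(0.4, 3.0)
EEG_FILTER = FilterSpec(0.5, 40.0)


def bandpass(channel: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Butterworth band-pass; zero-phase (filtfilt) by default."""
    x = np.asarray(channel, float)
    if not np.all(np.isfinite(x)):
        raise FilterError("non-finite samples in input")
    if spec.high_cut_hz >= fs / 2:
        raise FilterError(
            f"high cutoff {spec.high_cut_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    if len(x) <= 3 * spec.order:
        raise FilterError("channel too short for the requested filter order")
    sos = signal.butter(
        spec.order, [spec.low_cut_hz, spec.high_cut_hz], btype="bandpass", fs=fs, output="sos"
    )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def smooth_ecg(channel: np.ndarray, fs: float, window_ms: float = 12.0) -> np.ndarray:
    """Moving average over an odd number of samples, reflection-padded."""
    x = np.asarray(channel, float)
    w = max(int(round(window_ms / 1000.0 * fs)), 1)
    if w % 2 == 0:
        w += 1
    if w > len(x):
        raise FilterError("smoothing window longer than the channel")
    if w == 1:
        return x.copy()
    pad = w // 2
    padded = np.pad(x, pad, mode="reflect")
    kernel = np.ones(w) / w
    return np.convolve(padded, kernel, mode="valid")


def preprocess_ecg(channel: np.ndarray, fs: float, spec: FilterSpec = ECG_FILTER) -> np.ndarray:
    out = bandpass(channel, fs, spec)
    if spec.smoothing_window_ms:
        out = smooth_ecg(out, fs, spec.smoothing_window_ms)
    return out


def preprocess_ppg(channel: np.ndarray, fs: float, spec: FilterSpec = PPG_FILTER) -> np.ndarray:
    return bandpass(channel, fs, spec)


def preprocess_eeg(channel: np.ndarray, fs: float, spec: FilterSpec = EEG_FILTER) -> np.ndarray:
    return bandpass(channel, fs, spec)
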
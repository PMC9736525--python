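"""R-peak and PPG pulse detection; HRV and PTT series.

HRV here is the beat-to-beat interval series (ms) from successive ECG R
peaks. PTT is the latency (ms) from each R peak to the next PPG pulse peak,
an inverse surrogate of arterial pressure. Both series are physiologically
gated (RR in 250-2500 ms, PTT in 50-600 ms) to discard detector glitches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

RR_GATE_MS = (250.0, 2500.0)
PTT_GATE_MS = (50.0, 600.0)


class UnusableSegmentError(ValueError):
    """The segment does not support beat analysis (too few peaks)."""


@dataclass(frozen=True)
class BeatSeries:
    """Detected beats with derived interval series.

    hrv timestamps are the time of the later R peak of each pair; ptt
    timestamps are the R-peak times themselves.
    """

    r_times: np.ndarray
    hrv_t: np.ndarray
    hrv_ms: np.ndarray
    ptt_t: np.ndarray
    ptt_ms: np.ndarray


def detect_r_peaks(ecg_filtered: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins-style QRS detection on a filtered ECG.

    Differentiate, square, integrate over a 150 ms window, then pick peaks of
    the integrated energy with an adaptive signal/noise threshold and a
    250 ms refractory period; each detection is refined to the local maximum
    of the filtered ECG within +/-50 ms.
    """
    x = np.asarray(ecg_filtered, float)
    deriv = np.gradient(x) * fs
    squared = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    integrated = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.250 * fs))
    cand, _ = signal.find_peaks(integrated, distance=refractory)
    if len(cand) == 0:
        raise UnusableSegmentError("no QRS candidates found")

    # adaptive threshold: running signal/noise peak estimates (classic rule)
    head = integrated[: int(2 * fs)] if len(integrated) > 2 * fs else integrated
    spki = float(np.max(head)) * 0.5
    npki = float(np.mean(head)) * 0.5
    accepted = []
    for idx in cand:
        peak = integrated[idx]
        threshold = npki + 0.25 * (spki - npki)
        if peak > threshold:
            accepted.append(idx)
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki
    if len(accepted) < 2:
        raise UnusableSegmentError("fewer than 2 R peaks detected")

    # refine to the local max of the filtered ECG within +/-50 ms
    half = int(round(0.050 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    return refined / fs


def detect_ppg_peaks(ppg_filtered: np.ndarray, fs: float) -> np.ndarray:
    """PPG pulse peaks: local maxima above a rolling-percentile threshold,
    300 ms refractory."""
    x = np.asarray(ppg_filtered, float)
    refractory = int(round(0.300 * fs))
    # rolling 75th percentile over ~5 s as an adaptive height floor
    import pandas as pd

    win = int(round(5.0 * fs))
    thresh = (
        pd.Series(x).rolling(win, center=True, min_periods=win // 4).quantile(0.75).to_numpy()
    )
    peaks, _ = signal.find_peaks(x, distance=refractory)
    peaks = peaks[x[peaks] > thresh[peaks]]
    if len(peaks) == 0:
        raise UnusableSegmentError("no PPG pulse peaks detected")
    return peaks / fs


def compute_hrv(r_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Successive R-R differences in ms; values outside the physiological
    gate are discarded together with their timestamps."""
    r = np.asarray(r_times, float)
    if len(r) < 2:
        raise UnusableSegmentError("need at least 2 R peaks for HRV")
    rr = np.diff(r) * 1000.0
    t = r[1:]
    keep = (rr > RR_GATE_MS[0]) & (rr < RR_GATE_MS[1])
    return t[keep], rr[keep]


def compute_ptt(r_times: np.ndarray, p_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per R peak, time to the first PPG peak strictly after it (ms).

    An R peak whose next PPG peak falls after the following R peak is
    skipped — that pulse belongs to the next beat. Values outside the
    physiological gate are discarded.
    """
    r = np.asarray(r_times, float)
    p = np.asarray(p_times, float)
    if len(r) == 0 or len(p) == 0:
        raise UnusableSegmentError("empty peak series")
    idx = np.searchsorted(p, r, side="right")
    ts, vals = [], []
    for i, (t_r, j) in enumerate(zip(r, idx)):
        if j >= len(p):
            continue
        t_p = p[j]
        if i + 1 < len(r) and t_p > r[i + 1]:
            continue  # pulse belongs to the next beat
        ptt = (t_p - t_r) * 1000.0
        if PTT_GATE_MS[0] < ptt < PTT_GATE_MS[1]:
            ts.append(t_r)
            vals.append(ptt)
    if not vals:
        raise UnusableSegmentError("no valid R-to-pulse pairs")
    return np.array(ts), np.array(vals)


def extract_beat_series(
    ecg_filtered: np.ndarray, ppg_filtered: np.ndarray, fs: float
) -> BeatSeries:
    """Full beat analysis of a preprocessed recording."""
    r_times = detect_r_peaks(ecg_filtered, fs)
    p_times = detect_ppg_peaks(ppg_filtered, fs)
    hrv_t, hrv_ms = compute_hrv(r_times)
    ptt_t, ptt_ms = compute_ptt(r_times, p_times)
    return BeatSeries(r_times=r_times, hrv_t=hrv_t, hrv_ms=hrv_ms, ptt_t=ptt_t, ptt_ms=ptt_ms)
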
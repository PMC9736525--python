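"""Windowed feature extraction: the 93-feature scheme.

The HRV/PTT interval series is cut into windows of 25 intervals with ~50%
overlap (hop of 12 intervals, so consecutive windows share 13; a window is
roughly 20 s and never splits an interval). Per window:

* 16 time-domain statistics of the HRV values,
* 16 time-domain statistics of the PTT values,
* 7 frequency-domain HRV features (VLF, LF, HF, TP, pLF, pHF, LF/HF) from a
  spline-resampled, FFT-based spectrum,
* 18 features per EEG channel x 3 channels (12 statistics + spectral power
  and spectral-entropy summaries),

for 16 + 16 + 7 + 54 = 93 named features, finally z-scored column-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .beats import BeatSeries

logger = logging.getLogger(__name__)

WINDOW_INTERVALS = 25
WINDOW_HOP = 12  # 50% overlap rounded down to an integral hop
MIN_PTT_PER_WINDOW = 5
MODE_RESOLUTION_MS = 4.0  # one sample at 250 Hz
HRV_RESAMPLE_HZ = 4.0
VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
EEG_POWER_BAND = (0.5, 40.0)

TIME_DOMAIN_STATS = (
    "mean", "median", "mode", "std", "var", "abs_dev", "p25", "p75", "iqr",
    "kurtosis", "skewness", "geometric_mean", "harmonic_mean",
    "median_diff", "nn50", "rmssd",
)
HRV_FREQ_STATS = ("vlf", "lf", "hf", "tp", "plf", "phf", "lf_hf")
EEG_STATS = (
    "mean", "median", "mode", "std", "var", "abs_dev", "p25", "p75", "iqr",
    "kurtosis", "skewness", "harmonic_mean",
    "mean_power", "max_power", "freq_at_max_power",
    "median_entropy", "max_entropy", "min_entropy",
)

FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"hrv_{s}" for s in TIME_DOMAIN_STATS)
    + tuple(f"ptt_{s}" for s in TIME_DOMAIN_STATS)
    + tuple(f"hrv_{s}" for s in HRV_FREQ_STATS)
    + tuple(f"eeg{ch}_{s}" for ch in (1, 2, 3) for s in EEG_STATS)
)
assert len(FEATURE_NAMES) == 93 and len(set(FEATURE_NAMES)) == 93


class FeatureError(ValueError):
    pass


def _shape_moments(x: np.ndarray) -> tuple[float, float]:
    """Non-excess kurtosis and Fisher skewness; both defined as 0 for a
    zero-variance sample (the moment ratios are otherwise 0/0)."""
    if np.ptp(x) == 0:
        return 0.0, 0.0
    return (
        float(stats.kurtosis(x, fisher=False, bias=True)),
        float(stats.skew(x, bias=True)),
    )


@dataclass(frozen=True)
class Window:
    """One 25-interval analysis window over the HRV series."""

    start: int  # first HRV interval index
    t_start: float  # s, timestamp of the first interval
    t_end: float  # s, timestamp of the last interval

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def make_windows(beat_series: BeatSeries) -> list[Window]:
    """Windows of 25 HRV intervals at offsets 0, 12, 24, ...; a trailing
    remainder shorter than 25 intervals is dropped."""
    n = len(beat_series.hrv_ms)
    if n < WINDOW_INTERVALS:
        logger.warning("only %d HRV intervals; no windows emitted", n)
        return []
    windows = []
    for start in range(0, n - WINDOW_INTERVALS + 1, WINDOW_HOP):
        t = beat_series.hrv_t[start : start + WINDOW_INTERVALS]
        windows.append(Window(start=start, t_start=float(t[0]), t_end=float(t[-1])))
    return windows


def time_domain_features(values: np.ndarray) -> dict[str, float]:
    """The 16 interval statistics (means, dispersion, shape, and the
    successive-difference measures NN50 and RMSSD)."""
    x = np.asarray(values, float)
    if len(x) < 2:
        raise FeatureError("need at least 2 values")
    if np.any(x <= 0):
        raise FeatureError("geometric/harmonic mean undefined for nonpositive values")
    d = np.diff(x)
    rounded = np.round(x / MODE_RESOLUTION_MS) * MODE_RESOLUTION_MS
    vals, counts = np.unique(rounded, return_counts=True)
    mode = float(vals[counts == counts.max()].min())
    kurt, skew = _shape_moments(x)
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "mode": mode,
        "std": float(np.std(x, ddof=1)),
        "var": float(np.var(x, ddof=1)),
        "abs_dev": float(np.mean(np.abs(x - np.mean(x)))),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "kurtosis": kurt,
        "skewness": skew,
        "geometric_mean": float(stats.gmean(x)),
        "harmonic_mean": float(stats.hmean(x)),
        "median_diff": float(np.median(np.abs(d))),
        "nn50": float(np.sum(np.abs(d) > 50.0)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
    }


def hrv_frequency_features(t: np.ndarray, rr_ms: np.ndarray) -> dict[str, float]:
    """Band powers of the RR tachogram.

    The unevenly sampled RR series is cubic-spline interpolated onto a 4 Hz
    uniform grid, demeaned, and a boxcar FFT periodogram is integrated
    (rectangle rule) over the VLF (<0.04 Hz), LF (0.04-0.15 Hz) and HF
    (0.15-0.4 Hz) bands. pLF/pHF are percentages of total power; the LF/HF
    ratio indexes sympathovagal balance.
    """
    t = np.asarray(t, float)
    rr = np.asarray(rr_ms, float)
    if len(t) < 2 or t[-1] - t[0] < 15.0:
        raise FeatureError("need samples spanning at least 15 s")
    spline = interpolate.CubicSpline(t, rr)
    grid = np.arange(t[0], t[-1], 1.0 / HRV_RESAMPLE_HZ)
    x = spline(grid)
    x = x - x.mean()
    freqs, psd = signal.periodogram(x, fs=HRV_RESAMPLE_HZ, window="boxcar", detrend=False)
    df = freqs[1] - freqs[0]

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        return float(np.sum(psd[mask]) * df)

    vlf = band_power(*VLF_BAND)
    lf = band_power(*LF_BAND)
    hf = band_power(*HF_BAND)
    tp = vlf + lf + hf
    plf = 100.0 * lf / tp if tp > 0 else 0.0
    phf = 100.0 * hf / tp if tp > 0 else 0.0
    if hf == 0:
        logger.warning("zero HF power; LF/HF reported as +inf")
        ratio = np.inf
    else:
        ratio = lf / hf
    return {"vlf": vlf, "lf": lf, "hf": hf, "tp": tp, "plf": plf, "phf": phf, "lf_hf": ratio}


def _spectral_entropies(subs: np.ndarray, fs: float) -> np.ndarray:
    """Normalized Shannon entropy (natural log, in [0, 1]) of each row's
    periodogram, DC bin excluded."""
    x = subs - subs.mean(axis=1, keepdims=True)
    _, psd = signal.periodogram(x, fs=fs, window="hann", detrend=False, axis=1)
    psd = psd[:, 1:]
    total = psd.sum(axis=1, keepdims=True)
    total[total <= 0] = 1.0
    p = psd / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1) / np.log(psd.shape[1])
    h[psd.sum(axis=1) <= 0] = 1.0
    return h


def _spectral_entropy(segment: np.ndarray, fs: float) -> float:
    return float(_spectral_entropies(np.asarray(segment, float)[None, :], fs)[0])


def eeg_window_features(segment: np.ndarray, fs: float) -> dict[str, float]:
    """The 18 per-channel EEG features for one window.

    12 amplitude statistics (harmonic mean on |x| + 1e-12 since EEG is
    signed), Welch spectral power summaries over 0.5-40 Hz (1 s segments,
    50% overlap, Hann), and spectral-entropy summaries over non-overlapping
    1 s sub-segments.
    """
    x = np.asarray(segment, float)
    nper = int(round(fs))
    if len(x) < 2 * nper:
        raise FeatureError("EEG segment shorter than 2 sub-segments")
    rounded = np.round(x, 2)
    vals, counts = np.unique(rounded, return_counts=True)
    mode = float(vals[counts == counts.max()].min())
    absx = np.abs(x) + 1e-12

    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    band = (freqs >= EEG_POWER_BAND[0]) & (freqs <= EEG_POWER_BAND[1])
    fb, pb = freqs[band], psd[band]
    i_max = int(np.argmax(pb))

    n_sub = len(x) // nper
    entropies = _spectral_entropies(x[: n_sub * nper].reshape(n_sub, nper), fs)
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "mode": mode,
        "std": float(np.std(x, ddof=1)),
        "var": float(np.var(x, ddof=1)),
        "abs_dev": float(np.mean(np.abs(x - np.mean(x)))),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "kurtosis": _shape_moments(x)[0],
        "skewness": _shape_moments(x)[1],
        "harmonic_mean": float(stats.hmean(absx)),
        "mean_power": float(np.mean(pb)),
        "max_power": float(pb[i_max]),
        "freq_at_max_power": float(fb[i_max]),
        "median_entropy": float(np.median(entropies)),
        "max_entropy": float(np.max(entropies)),
        "min_entropy": float(np.min(entropies)),
    }


def assemble_feature_vector(
    window: Window,
    beat_series: BeatSeries,
    eeg_channels: tuple[np.ndarray, np.ndarray, np.ndarray],
    fs: float,
) -> dict[str, float] | None:
    """One window's 93-feature vector, or None if the window lacks PTT
    values (fewer than 5 after gating) or EEG coverage."""
    hrv_t = beat_series.hrv_t[window.start : window.start + WINDOW_INTERVALS]
    hrv = beat_series.hrv_ms[window.start : window.start + WINDOW_INTERVALS]
    in_win = (beat_series.ptt_t >= window.t_start) & (beat_series.ptt_t <= window.t_end)
    ptt = beat_series.ptt_ms[in_win]
    if len(ptt) < MIN_PTT_PER_WINDOW:
        logger.info("window at %.1f s dropped: only %d PTT values", window.t_start, len(ptt))
        return None
    lo, hi = int(window.t_start * fs), int(window.t_end * fs)
    if hi > len(eeg_channels[0]):
        logger.info("window at %.1f s dropped: no EEG coverage", window.t_start)
        return None

    out: dict[str, float] = {}
    try:
        for name, val in time_domain_features(hrv).items():
            out[f"hrv_{name}"] = val
        for name, val in time_domain_features(ptt).items():
            out[f"ptt_{name}"] = val
        for name, val in hrv_frequency_features(hrv_t, hrv).items():
            out[f"hrv_{name}"] = val
    except FeatureError as exc:
        logger.info("window at %.1f s dropped: %s", window.t_start, exc)
        return None
    for ch in (1, 2, 3):
        seg = eeg_channels[ch - 1][lo:hi]
        for name, val in eeg_window_features(seg, fs).items():
            out[f"eeg{ch}_{name}"] = val
    assert list(out) == list(FEATURE_NAMES)
    return out


def extract_feature_table(
    beat_series: BeatSeries,
    eeg_channels: tuple[np.ndarray, np.ndarray, np.ndarray],
    fs: float,
) -> pd.DataFrame:
    """Feature matrix for every valid window, with window time columns
    (t_start_s, t_end_s) appended for labeling."""
    rows, t0s, t1s = [], [], []
    for w in make_windows(beat_series):
        vec = assemble_feature_vector(w, beat_series, eeg_channels, fs)
        if vec is None:
            continue
        rows.append(vec)
        t0s.append(w.t_start)
        t1s.append(w.t_end)
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    frame["t_start_s"] = t0s
    frame["t_end_s"] = t1s
    return frame


# ---------------------------------------------------------------------------
# normalization


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring with the sample (N-1) standard deviation.

    Zero-variance columns are flagged and mapped to 0. The fitted state is
    reusable on held-out rows, so validation data is standardized with
    training statistics only.
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        self.constant_features_ = self.scale_ <= 0
        if self.constant_features_.any():
            logger.info("%d zero-variance feature(s) left at 0", self.constant_features_.sum())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X)
        safe = np.where(self.constant_features_, 1.0, self.scale_)
        Z = (X - self.mean_) / safe
        Z[:, self.constant_features_] = 0.0
        return Z


def zscore_normalize(matrix: np.ndarray) -> tuple[np.ndarray, ZScoreScaler]:
    """Fit-and-apply z-scoring; returns the transformed matrix and the
    fitted scaler for later use on held-out rows."""
    scaler = ZScoreScaler().fit(matrix)
    return scaler.transform(matrix), scaler
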
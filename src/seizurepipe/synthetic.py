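"""Synthetic multimodal recordings with known ground truth.

Generates seeded 5-channel recordings (ECG, PPG, 3 ear-EEG channels at
250 Hz) following a 40-minute provocation-protocol timeline, together with
the ground-truth beat times, RR intervals, pulse transit times and state
timeline that every downstream stage is validated against.

The physiology emulated is deliberately minimal:

* heartbeats are placed iteratively with a state-dependent base RR interval
  modulated sinusoidally at the centres of the LF (0.10 Hz) and HF (0.25 Hz)
  autonomic bands — the preictal state raises the LF/HF modulation ratio
  (sympathetic dominance), the ictal state shortens RR outright;
* the PPG pulse for each beat peaks a state-dependent pulse transit time
  after the R wave;
* EEG channels carry band-limited 1/f background activity; ictal intervals
  add broadband noise and a 3 Hz transient train so that windowed spectral
  entropy rises during seizures.

Everything is a pure function of (protocol, seizures, params incl. seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FS_DEFAULT = 250.0

#: activity segments of the provocation protocol (name, duration in s);
#: totals 2400 s
DEFAULT_PROTOCOL_SEGMENTS: tuple[tuple[str, float], ...] = (
    ("eyes_open_close", 120.0),
    ("strobe", 360.0),
    ("hyperventilation", 90.0),
    ("rest", 120.0),
    ("hyperventilation", 90.0),
    ("rest", 120.0),
    ("sleeping", 1200.0),
    ("waking_up", 300.0),
)

STATES = ("N", "P", "I")


class GeneratorError(ValueError):
    """Invalid generator configuration or degenerate parameters."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Ordered activity segments (name, duration s) of a recording session."""

    segments: tuple[tuple[str, float], ...] = DEFAULT_PROTOCOL_SEGMENTS

    def __post_init__(self) -> None:
        if not self.segments:
            raise GeneratorError("protocol needs at least one segment")
        for name, dur in self.segments:
            if not dur > 0:
                raise GeneratorError(f"segment {name!r} has nonpositive duration {dur}")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.segments))


@dataclass(frozen=True)
class StateTimeline:
    """Contiguous, non-overlapping (start, end, state) intervals covering [0, T)."""

    intervals: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end, state in self.intervals:
            if state not in STATES:
                raise GeneratorError(f"unknown state {state!r}")
            if not (end > start):
                raise GeneratorError(f"empty interval [{start}, {end})")
            if abs(start - prev_end) > 1e-9:
                raise GeneratorError("timeline intervals must be contiguous")
            prev_end = end

    @property
    def total_duration(self) -> float:
        return self.intervals[-1][1]

    def state_at(self, t: float) -> str:
        """State at time t; times at or past the end map to the last interval."""
        for start, end, state in self.intervals:
            if start <= t < end:
                return state
        return self.intervals[-1][2]

    def states_at(self, times: np.ndarray) -> np.ndarray:
        starts = np.array([iv[0] for iv in self.intervals])
        labels = np.array([iv[2] for iv in self.intervals])
        idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(labels) - 1)
        return labels[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start_s", "end_s", "state"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StateTimeline":
        rows = [(float(r.start_s), float(r.end_s), str(r.state)) for r in frame.itertuples()]
        return cls(tuple(rows))


@dataclass(frozen=True)
class GeneratorParams:
    """Tunable knobs of the synthetic generator.

    RR modulation depths are fractional (dimensionless); a state's RR series is
    rr_base_ms * (1 + lf_amp sin(2π·0.10 t) + hf_amp sin(2π·0.25 t) + ε).
    """

    rr_base_ms: dict[str, float] = field(
        default_factory=lambda: {"N": 800.0, "P": 740.0, "I": 650.0}
    )
    lf_amp: dict[str, float] = field(
        default_factory=lambda: {"N": 0.03, "P": 0.06, "I": 0.07}
    )
    hf_amp: dict[str, float] = field(
        default_factory=lambda: {"N": 0.04, "P": 0.02, "I": 0.015}
    )
    ptt_mean_ms: dict[str, float] = field(
        default_factory=lambda: {"N": 250.0, "P": 235.0, "I": 215.0}
    )
    ptt_noise_sd_ms: float = 3.0
    rr_noise_sd: float = 0.005
    eeg_one_over_f_exponent: float = 1.0
    ictal_broadband_gain: float = 1.2
    ictal_transient_amp: float = 2.0
    ictal_transient_hz: float = 3.0
    ecg_noise_sd: float = 0.02
    ppg_noise_sd: float = 0.02
    ramp_s: float = 5.0  # linear RR-base ramp across state transitions
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for st in STATES:
            if self.rr_base_ms[st] <= 0:
                raise GeneratorError(f"rr_base_ms[{st}] must be positive")
            if self.lf_amp[st] < 0 or self.hf_amp[st] < 0:
                raise GeneratorError("modulation amplitudes must be nonnegative")
            if self.lf_amp[st] + self.hf_amp[st] >= 0.5:
                raise GeneratorError(f"lf_amp + hf_amp must stay below 0.5 for state {st}")
            if self.ptt_mean_ms[st] <= 0:
                raise GeneratorError(f"ptt_mean_ms[{st}] must be positive")
        ratio = lambda st: self.lf_amp[st] / max(self.hf_amp[st], 1e-12)
        if not ratio("P") > ratio("N"):
            raise GeneratorError(
                "preictal LF/HF modulation ratio must exceed the normal ratio"
            )

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, rng_seed=int(seed))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually produced, for validating the extractors."""

    beat_times: np.ndarray  # s, strictly increasing
    rr_true: np.ndarray  # ms, one per successive beat pair
    ptt_true: np.ndarray  # ms, one per beat
    timeline: StateTimeline

    def beat_states(self) -> np.ndarray:
        return self.timeline.states_at(self.beat_times)

    def to_frame(self) -> pd.DataFrame:
        rr = np.concatenate([[np.nan], self.rr_true])
        return pd.DataFrame(
            {"beat_time_s": self.beat_times, "rr_ms": rr, "ptt_ms": self.ptt_true}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, timeline: StateTimeline) -> "GroundTruth":
        return cls(
            beat_times=frame["beat_time_s"].to_numpy(float),
            rr_true=frame["rr_ms"].to_numpy(float)[1:],
            ptt_true=frame["ptt_ms"].to_numpy(float),
            timeline=timeline,
        )


@dataclass(frozen=True)
class Recording:
    """A 5-channel recording block at a fixed sampling rate."""

    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    eeg: tuple[np.ndarray, np.ndarray, np.ndarray]
    annotations: StateTimeline | None = None

    def __post_init__(self) -> None:
        n = len(self.ecg)
        channels = (self.ecg, self.ppg) + self.eeg
        if any(len(c) != n for c in channels):
            raise GeneratorError("all channels must have equal length")
        if any(not np.all(np.isfinite(c)) for c in channels):
            raise GeneratorError("channels must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.fs
        return pd.DataFrame(
            {
                "time_s": t,
                "ecg": self.ecg,
                "ppg": self.ppg,
                "eeg1": self.eeg[0],
                "eeg2": self.eeg[1],
                "eeg3": self.eeg[2],
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, annotations: StateTimeline | None = None
    ) -> "Recording":
        t = frame["time_s"].to_numpy(float)
        fs = 1.0 / np.median(np.diff(t))
        return cls(
            fs=float(np.round(fs, 6)),
            ecg=frame["ecg"].to_numpy(float),
            ppg=frame["ppg"].to_numpy(float),
            eeg=(
                frame["eeg1"].to_numpy(float),
                frame["eeg2"].to_numpy(float),
                frame["eeg3"].to_numpy(float),
            ),
            annotations=annotations,
        )


# ---------------------------------------------------------------------------
# timeline construction


def make_state_timeline(
    protocol: ProtocolSpec,
    seizures: list[tuple[float, float]],
    preictal_lead: float = 60.0,
) -> StateTimeline:
    """Build the ground-truth N/P/I timeline for a protocol run.

    Each seizure (onset, duration) becomes an ictal interval preceded by a
    preictal interval of ``preictal_lead`` seconds, truncated at time zero or
    at the end of a previous ictal interval.
    """
    total = protocol.total_duration
    seizures = sorted(seizures)
    for i, (onset, dur) in enumerate(seizures):
        if dur <= 0:
            raise GeneratorError(f"seizure at {onset} s has nonpositive duration")
        if onset < 0 or onset + dur > total:
            raise GeneratorError(f"seizure ({onset}, {dur}) outside the {total} s protocol")
        if i > 0:
            p_onset, p_dur = seizures[i - 1]
            if p_onset + p_dur > onset:
                raise GeneratorError(
                    f"overlapping seizures: ({p_onset}, {p_dur}) and ({onset}, {dur})"
                )

    marks: list[tuple[float, float, str]] = []
    prev_ictal_end = 0.0
    for onset, dur in seizures:
        p_start = max(onset - preictal_lead, prev_ictal_end, 0.0)
        if p_start < onset:
            marks.append((p_start, onset, "P"))
        marks.append((onset, onset + dur, "I"))
        prev_ictal_end = onset + dur

    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for start, end, state in marks:
        if start > cursor:
            intervals.append((cursor, start, "N"))
        intervals.append((start, end, state))
        cursor = end
    if cursor < total:
        intervals.append((cursor, total, "N"))
    return StateTimeline(tuple(intervals))


# ---------------------------------------------------------------------------
# beat train


def _rr_base_at(times: np.ndarray, timeline: StateTimeline, params: GeneratorParams) -> np.ndarray:
    """State base RR at each time, linearly ramped over ramp_s at transitions."""
    base = np.array(
        [params.rr_base_ms[s] for s in timeline.states_at(np.asarray(times, float))]
    )
    if params.ramp_s <= 0:
        return base
    out = base.copy()
    for start, _, state in timeline.intervals[1:]:
        new = params.rr_base_ms[state]
        # value in force just before this transition
        old = params.rr_base_ms[timeline.state_at(start - 1e-9)]
        in_ramp = (times >= start) & (times < start + params.ramp_s)
        frac = (np.asarray(times, float)[in_ramp] - start) / params.ramp_s
        out[in_ramp] = old + (new - old) * frac
    return out


def generate_beats(timeline: StateTimeline, params: GeneratorParams) -> GroundTruth:
    """Place heartbeats iteratively: each RR interval is the state base RR
    modulated at the LF/HF band centres plus Gaussian jitter."""
    total = timeline.total_duration
    if total <= 60:
        raise GeneratorError("timeline must cover more than 60 s")
    rng = np.random.default_rng([int(params.rng_seed), 0x42EA75])
    times = [0.0]
    t = 0.0
    while True:
        (base,) = _rr_base_at(np.array([t]), timeline, params)
        state = timeline.state_at(t)
        mod = (
            1.0
            + params.lf_amp[state] * np.sin(2 * np.pi * 0.10 * t)
            + params.hf_amp[state] * np.sin(2 * np.pi * 0.25 * t)
            + (rng.normal(0.0, params.rr_noise_sd) if params.rr_noise_sd > 0 else 0.0)
        )
        rr_s = base * mod / 1000.0
        if rr_s <= 0:
            raise GeneratorError("degenerate parameters produced a nonpositive RR interval")
        t = t + rr_s
        if t >= total:
            break
        times.append(t)
    beat_times = np.array(times)
    rr_true = np.diff(beat_times) * 1000.0

    states = timeline.states_at(beat_times)
    ptt_means = np.array([params.ptt_mean_ms[s] for s in states])
    noise = rng.normal(0.0, params.ptt_noise_sd_ms, size=len(beat_times))
    # keep every value inside the documented 6-sigma envelope of its state mean
    noise = np.clip(noise, -6 * params.ptt_noise_sd_ms, 6 * params.ptt_noise_sd_ms)
    ptt_true = ptt_means + noise
    return GroundTruth(beat_times=beat_times, rr_true=rr_true, ptt_true=ptt_true, timeline=timeline)


# ---------------------------------------------------------------------------
# channel synthesis


def _add_templates(
    n: int, fs: float, centers_s: np.ndarray, template_fn, half_width_s: float, out: np.ndarray
) -> None:
    half = int(round(half_width_s * fs))
    for c in centers_s:
        ci = int(round(c * fs))
        lo, hi = max(ci - half, 0), min(ci + half + 1, n)
        if lo >= hi:
            continue
        t_rel = (np.arange(lo, hi) / fs) - c
        out[lo:hi] += template_fn(t_rel)


def synthesize_ecg(
    beat_times: np.ndarray,
    fs: float,
    duration: float,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ECG channel: one narrow Gaussian R wave per beat plus baseline noise.

    Morphological realism (P/T waves) is out of scope; the R wave alone is
    what the peak detector needs.
    """
    beat_times = np.asarray(beat_times, float)
    if len(beat_times) > 1:
        gaps = np.diff(beat_times)
        if np.any(gaps < 0.250):
            raise GeneratorError("beats closer than 250 ms violate the refractory period")
    n = int(round(fs * duration))
    out = np.zeros(n)
    sigma = 0.008  # s; FWHM ~ 19 ms
    _add_templates(
        n, fs, beat_times, lambda t: np.exp(-0.5 * (t / sigma) ** 2), 5 * sigma, out
    )
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        out += rng.normal(0.0, noise_sd, size=n)
    return out


def synthesize_ppg(
    beat_times: np.ndarray,
    ptt_true: np.ndarray,
    fs: float,
    duration: float,
    pulse_width_s: float = 0.30,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """PPG channel: a raised-cosine pulse peaking PTT after each R wave."""
    beat_times = np.asarray(beat_times, float)
    ptt_true = np.asarray(ptt_true, float)
    if len(beat_times) != len(ptt_true):
        raise GeneratorError("need one PTT value per beat")
    if np.any(ptt_true <= 0):
        raise GeneratorError("PTT values must be positive")
    n = int(round(fs * duration))
    out = np.zeros(n)
    centers = beat_times + ptt_true / 1000.0
    w = pulse_width_s

    def pulse(t: np.ndarray) -> np.ndarray:
        return 0.5 * (1 + np.cos(2 * np.pi * t / w))

    _add_templates(n, fs, centers, pulse, w / 2, out)
    if noise_sd > 0:
        rng = rng if rng is not None else np.random.default_rng()
        out += rng.normal(0.0, noise_sd, size=n)
    return out


def _one_over_f_noise(n: int, fs: float, exponent: float, rng: np.random.Generator,
                      high_cut_hz: float = 40.0) -> np.ndarray:
    """Band-limited 1/f^exponent (power) Gaussian noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 0.5) ** (-exponent / 2.0)
    shape[freqs > high_cut_hz] = 0.0
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_eeg(
    timeline: StateTimeline,
    fs: float,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Three EEG channels sharing the state structure with independent noise.

    Baseline: 1/f activity band-limited below 40 Hz. Ictal intervals add
    broadband noise plus a 3 Hz biphasic transient train, which raises the
    windowed spectral entropy above the interictal level.
    """
    rng = rng if rng is not None else np.random.default_rng([int(params.rng_seed), 0xEE6])
    n = int(round(fs * timeline.total_duration))
    t = np.arange(n) / fs
    ictal_mask = timeline.states_at(t) == "I"

    # shared transient train: sharp biphasic spikes at 3 Hz, ictal-gated
    period = 1.0 / params.ictal_transient_hz
    phase = (t % period) / period
    spikes = np.exp(-0.5 * ((phase - 0.5) / 0.02) ** 2) - 0.6 * np.exp(
        -0.5 * ((phase - 0.58) / 0.03) ** 2
    )

    channels = []
    for _ in range(3):
        base = _one_over_f_noise(n, fs, params.eeg_one_over_f_exponent, rng)
        ch = base.copy()
        if np.any(ictal_mask):
            broadband = rng.normal(size=n)
            ch[ictal_mask] += params.ictal_broadband_gain * broadband[ictal_mask]
            ch[ictal_mask] += params.ictal_transient_amp * spikes[ictal_mask]
        channels.append(ch)
    return tuple(channels)


def generate_recording(
    protocol: ProtocolSpec | None = None,
    seizures: list[tuple[float, float]] | None = None,
    params: GeneratorParams | None = None,
    preictal_lead: float = 60.0,
) -> tuple[Recording, GroundTruth]:
    """Compose timeline, beat train and all five channels into a Recording."""
    protocol = protocol or ProtocolSpec()
    seizures = seizures if seizures is not None else []
    params = params or GeneratorParams()
    timeline = make_state_timeline(protocol, seizures, preictal_lead)
    truth = generate_beats(timeline, params)
    duration = timeline.total_duration
    fs = FS_DEFAULT
    rng_ecg = np.random.default_rng([int(params.rng_seed), 0xEC6])
    rng_ppg = np.random.default_rng([int(params.rng_seed), 0x996])
    rng_eeg = np.random.default_rng([int(params.rng_seed), 0xEE6])
    ecg = synthesize_ecg(truth.beat_times, fs, duration, params.ecg_noise_sd, rng_ecg)
    ppg = synthesize_ppg(
        truth.beat_times, truth.ptt_true, fs, duration, noise_sd=params.ppg_noise_sd, rng=rng_ppg
    )
    eeg = synthesize_eeg(timeline, fs, params, rng_eeg)
    rec = Recording(fs=fs, ecg=ecg, ppg=ppg, eeg=eeg, annotations=timeline)
    return rec, truth


def sample_seizures(
    rng: np.random.Generator,
    n_seizures: int,
    protocol: ProtocolSpec,
    duration_range_s: tuple[float, float] = (45.0, 90.0),
    margin_s: float = 180.0,
    min_gap_s: float = 300.0,
) -> list[tuple[float, float]]:
    """Draw non-overlapping seizure (onset, duration) pairs inside a protocol.

    Onsets keep ``margin_s`` clear of both protocol ends and ``min_gap_s``
    between consecutive seizures so each gets its full preictal lead.
    """
    total = protocol.total_duration
    lo, hi = margin_s, total - margin_s
    for _ in range(1000):
        onsets = np.sort(rng.uniform(lo, hi, size=n_seizures))
        durs = rng.uniform(*duration_range_s, size=n_seizures)
        ends = onsets + durs
        if np.all(onsets[1:] - ends[:-1] >= min_gap_s) and ends[-1] <= total - 60:
            return list(zip(onsets.tolist(), durs.tolist()))
    raise GeneratorError("could not place the requested seizures in the protocol")


# ---------------------------------------------------------------------------
# persistence (plain CSV)


def write_recording(rec: Recording, truth: GroundTruth | None, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec.to_frame().to_csv(out / "recording.csv", index=False, float_format="%.6f")
    if rec.annotations is not None:
        rec.annotations.to_frame().to_csv(out / "annotations.csv", index=False)
    if truth is not None:
        truth.to_frame().to_csv(out / "ground_truth.csv", index=False, float_format="%.9f")


def read_recording(in_dir: str | Path) -> tuple[Recording, GroundTruth | None]:
    src = Path(in_dir)
    ann_path = src / "annotations.csv"
    timeline = StateTimeline.from_frame(pd.read_csv(ann_path)) if ann_path.exists() else None
    rec = Recording.from_frame(pd.read_csv(src / "recording.csv"), annotations=timeline)
    gt_path = src / "ground_truth.csv"
    truth = None
    if gt_path.exists() and timeline is not None:
        truth = GroundTruth.from_frame(pd.read_csv(gt_path), timeline)
    return rec, truth
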
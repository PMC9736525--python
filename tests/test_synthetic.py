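"""Generator: timelines, beat trains, channel synthesis, determinism."""

import numpy as np
import pytest
from scipy import interpolate, signal, stats

from seizurepipe import synthetic as syn
from seizurepipe.features import _spectral_entropies


@pytest.fixture(scope="module")
def protocol():
    return syn.ProtocolSpec()


class TestTimeline:
    def test_default_protocol_lasts_40_minutes(self, protocol):
        assert protocol.total_duration == 2400.0

    def test_single_seizure_timeline(self, protocol):
        tl = syn.make_state_timeline(protocol, [(1200.0, 30.0)], 60.0)
        assert tl.intervals == (
            (0.0, 1140.0, "N"),
            (1140.0, 1200.0, "P"),
            (1200.0, 1230.0, "I"),
            (1230.0, 2400.0, "N"),
        )

    def test_no_seizures_is_all_normal(self, protocol):
        tl = syn.make_state_timeline(protocol, [], 60.0)
        assert tl.intervals == ((0.0, 2400.0, "N"),)

    def test_preictal_truncated_at_start(self, protocol):
        tl = syn.make_state_timeline(protocol, [(20.0, 30.0)], 60.0)
        assert tl.intervals[0] == (0.0, 20.0, "P")

    def test_preictal_truncated_at_prior_ictal(self, protocol):
        tl = syn.make_state_timeline(protocol, [(100.0, 50.0), (180.0, 30.0)], 60.0)
        # second preictal starts where the first seizure ended
        assert (150.0, 180.0, "P") in tl.intervals

    def test_overlapping_seizures_rejected(self, protocol):
        with pytest.raises(syn.GeneratorError, match="overlap"):
            syn.make_state_timeline(protocol, [(100.0, 50.0), (120.0, 30.0)], 60.0)

    def test_coverage_is_contiguous(self, protocol):
        tl = syn.make_state_timeline(protocol, [(600.0, 60.0), (1500.0, 75.0)], 60.0)
        ends = [iv[1] for iv in tl.intervals]
        starts = [iv[0] for iv in tl.intervals]
        assert starts[0] == 0.0 and ends[-1] == 2400.0
        assert all(a == b for a, b in zip(ends[:-1], starts[1:]))


class TestBeatTrain:
    def test_zero_modulation_gives_exact_base_rr(self, protocol):
        tl = syn.make_state_timeline(protocol, [], 60.0)
        params = syn.GeneratorParams(
            lf_amp={"N": 0.0, "P": 0.01, "I": 0.0},
            hf_amp={"N": 0.0, "P": 0.0, "I": 0.0},
            rr_noise_sd=0.0,
        )
        truth = syn.generate_beats(tl, params)
        assert np.allclose(truth.rr_true, 800.0, atol=1e-9)

    def test_same_seed_bit_identical(self, protocol):
        tl = syn.make_state_timeline(protocol, [(1200.0, 30.0)], 60.0)
        params = syn.GeneratorParams(rng_seed=3)
        a = syn.generate_beats(tl, params)
        b = syn.generate_beats(tl, params)
        assert np.array_equal(a.beat_times, b.beat_times)
        assert np.array_equal(a.ptt_true, b.ptt_true)

    def test_rr_equals_beat_time_differences(self, protocol):
        tl = syn.make_state_timeline(protocol, [], 60.0)
        truth = syn.generate_beats(tl, syn.GeneratorParams(rng_seed=2))
        assert np.allclose(truth.rr_true, np.diff(truth.beat_times) * 1000.0, atol=1e-9)

    def test_ptt_within_six_sigma_of_state_mean(self, protocol):
        tl = syn.make_state_timeline(protocol, [(1200.0, 60.0)], 60.0)
        params = syn.GeneratorParams(rng_seed=4)
        truth = syn.generate_beats(tl, params)
        states = truth.beat_states()
        for s in "NPI":
            mean = params.ptt_mean_ms[s]
            vals = truth.ptt_true[states == s]
            assert np.all(np.abs(vals - mean) <= 6 * params.ptt_noise_sd_ms)

    def test_state_encoding_mean_rr_ordering(self, default_recording):
        _, truth = default_recording
        states = truth.beat_states()[1:]
        means = {s: truth.rr_true[states == s].mean() for s in "NPI"}
        assert means["I"] < means["P"] < means["N"]

    def test_rr_spectrum_peaks_at_modulation_frequencies(self, protocol):
        """Oracle: periodogram of the spline-resampled tachogram must peak at
        the LF (0.10 Hz) and HF (0.25 Hz) band centres."""
        tl = syn.make_state_timeline(protocol, [], 60.0)
        truth = syn.generate_beats(tl, syn.GeneratorParams(rng_seed=5))
        t, rr = truth.beat_times[1:], truth.rr_true
        grid = np.arange(t[0], t[-1], 0.25)
        x = interpolate.CubicSpline(t, rr)(grid)
        freqs, psd = signal.periodogram(x - x.mean(), fs=4.0)
        lf = (freqs >= 0.04) & (freqs < 0.15)
        hf = (freqs >= 0.15) & (freqs < 0.4)
        assert abs(freqs[lf][np.argmax(psd[lf])] - 0.10) < 0.01
        assert abs(freqs[hf][np.argmax(psd[hf])] - 0.25) < 0.01

    def test_degenerate_params_rejected(self, protocol):
        tl = syn.make_state_timeline(protocol, [], 60.0)
        with pytest.raises(syn.GeneratorError):
            params = syn.GeneratorParams(rr_base_ms={"N": -5.0, "P": 740.0, "I": 650.0})
            syn.generate_beats(tl, params)


class TestECG:
    def test_three_clean_beats_peak_at_beat_samples(self):
        ecg = syn.synthesize_ecg(np.array([1.0, 2.0, 3.0]), 250.0, 4.0, noise_sd=0.0)
        peaks, _ = signal.find_peaks(ecg, height=0.5)
        assert list(peaks) == [250, 500, 750]

    def test_empty_beat_list_gives_noise_channel(self):
        ecg = syn.synthesize_ecg(np.array([]), 250.0, 4.0, noise_sd=0.01,
                                 rng=np.random.default_rng(0))
        assert len(ecg) == 1000
        assert np.max(np.abs(ecg)) < 0.2

    def test_refractory_violation_rejected(self):
        with pytest.raises(syn.GeneratorError, match="refractory"):
            syn.synthesize_ecg(np.array([1.0, 1.1]), 250.0, 4.0)


class TestPPG:
    def test_single_pulse_peaks_at_beat_plus_ptt(self):
        ppg = syn.synthesize_ppg(np.array([1.0]), np.array([250.0]), 250.0, 4.0, noise_sd=0.0)
        assert abs(np.argmax(ppg) - 1.25 * 250) <= 1

    def test_nonpositive_ptt_rejected(self):
        with pytest.raises(syn.GeneratorError, match="positive"):
            syn.synthesize_ppg(np.array([1.0]), np.array([-10.0]), 250.0, 4.0)

    def test_one_pulse_per_beat(self, default_recording):
        rec, truth = default_recording
        # beat-count conservation: every beat contributed exactly one pulse
        from seizurepipe.preprocess import preprocess_ppg
        from seizurepipe.beats import detect_ppg_peaks

        peaks = detect_ppg_peaks(preprocess_ppg(rec.ppg, rec.fs), rec.fs)
        assert len(peaks) >= 0.99 * len(truth.beat_times)


class TestEEG:
    def test_null_ictal_config_indistinguishable(self, protocol):
        tl = syn.make_state_timeline(protocol, [(300.0, 600.0)], 60.0)
        params = syn.GeneratorParams(
            ictal_broadband_gain=0.0, ictal_transient_amp=0.0, rng_seed=0
        )
        fs = 250
        eeg = syn.synthesize_eeg(tl, float(fs), params)
        ent = _spectral_entropies(eeg[0][: 2400 * fs].reshape(2400, fs), float(fs))
        states = tl.states_at(np.arange(0.5, 2400, 1.0))
        i_ent = ent[states == "I"][::4][:50]
        n_ent = ent[states == "N"][::4][:50]
        _, p = stats.mannwhitneyu(i_ent, n_ent)
        assert p > 0.01

    def test_ictal_entropy_exceeds_normal_across_seeds(self, protocol):
        tl = syn.make_state_timeline(protocol, [(300.0, 600.0)], 60.0)
        fs = 250
        wins = 0
        n_seeds = 20
        states = tl.states_at(np.arange(0.5, 2400, 1.0))
        for seed in range(n_seeds):
            params = syn.GeneratorParams(rng_seed=seed)
            eeg = syn.synthesize_eeg(tl, float(fs), params)
            ent = _spectral_entropies(eeg[0][: 2400 * fs].reshape(2400, fs), float(fs))
            if np.median(ent[states == "I"]) > np.median(ent[states == "N"]):
                wins += 1
        assert wins >= int(0.95 * n_seeds)

    def test_same_seed_bit_identical_channels(self, protocol):
        tl = syn.make_state_timeline(protocol, [(1200.0, 60.0)], 60.0)
        params = syn.GeneratorParams(rng_seed=11)
        a = syn.synthesize_eeg(tl, 250.0, params)
        b = syn.synthesize_eeg(tl, 250.0, params)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca, cb)


class TestRecording:
    def test_default_recording_shape(self, default_recording):
        rec, truth = default_recording
        assert rec.fs == 250.0
        assert rec.n_samples == 600_000
        for ch in (rec.ecg, rec.ppg) + rec.eeg:
            assert len(ch) == 600_000
            assert np.all(np.isfinite(ch))

    def test_two_seeds_differ_but_share_timeline(self):
        protocol = syn.ProtocolSpec()
        seiz = [(1200.0, 60.0)]
        rec1, t1 = syn.generate_recording(protocol, seiz, syn.GeneratorParams(rng_seed=1))
        rec2, t2 = syn.generate_recording(protocol, seiz, syn.GeneratorParams(rng_seed=2))
        assert not np.array_equal(rec1.ecg, rec2.ecg)
        assert t1.timeline.intervals == t2.timeline.intervals

    def test_round_trip_through_csv(self, tmp_path):
        protocol = syn.ProtocolSpec((("rest", 120.0),))
        rec, truth = syn.generate_recording(protocol, [], syn.GeneratorParams(rng_seed=6))
        syn.write_recording(rec, truth, tmp_path)
        rec2, truth2 = syn.read_recording(tmp_path)
        assert rec2.n_samples == rec.n_samples
        assert rec2.annotations.intervals == rec.annotations.intervals
        assert np.allclose(rec2.ecg, rec.ecg, atol=1e-5)
        assert np.allclose(truth2.beat_times, truth.beat_times, atol=1e-8)
        assert np.allclose(truth2.ptt_true, truth.ptt_true, atol=1e-8)
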
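import numpy as np
import pytest

from ppgstiff import preprocess as pp
from ppgstiff.synth_pulse import SubjectSpec, make_beat_template, render_record
from ppgstiff.experiments import beat_from_template
from ppgstiff.waveform_io import WaveformRecord


class TestBandpass:
    def test_slow_drift_attenuated_at_least_20db(self):
        fs, dur = 1000.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        drift = np.sin(2 * np.pi * 0.05 * t)
        rec = WaveformRecord({"ppg": drift}, fs)
        out = pp.bandpass(rec).channels["ppg"]
        mid = slice(int(10 * fs), int(50 * fs))  # avoid filter edge transients
        assert np.abs(out[mid]).max() <= 0.1  # -20 dB

    def test_passband_tone_preserved_within_5pct(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        tone = np.sin(2 * np.pi * 1.0 * t)
        rec = WaveformRecord({"ppg": tone}, fs)
        out = pp.bandpass(rec).channels["ppg"]
        mid = slice(int(10 * fs), int(20 * fs))
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_phase_keeps_symmetric_peak_in_place(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        pulse = np.exp(-0.5 * ((t - 10.0) / 0.05) ** 2)
        rec = WaveformRecord({"ppg": pulse}, fs)
        out = pp.bandpass(rec).channels["ppg"]
        assert int(np.argmax(out)) == int(np.argmax(pulse))

    def test_fs_below_nyquist_constraint_rejected(self):
        rec = WaveformRecord({"ppg": np.zeros(100)}, fs=30.0)
        with pytest.raises(pp.PreprocessError, match="Nyquist"):
            pp.bandpass(rec)


class TestOnsetDetection:
    def test_noiseless_record_onsets_within_5ms_of_truth(self, noiseless_record):
        filt = pp.bandpass(noiseless_record)
        det = pp.detect_ppg_onsets(filt.channels["ppg"], filt.fs)
        truth = noiseless_record.annotations["onset"]
        assert len(det) == len(truth)
        err_ms = np.array([np.min(np.abs(truth - d)) for d in det]) * 1000
        assert err_ms.max() <= 5.0

    def test_constant_signal_gives_empty_result(self):
        assert pp.detect_ppg_onsets(np.ones(5000), 1000.0).size == 0

    def test_two_identical_beats_give_two_onsets(self):
        beat = beat_from_template(make_beat_template("2", 7.0), 1000).samples
        sig = np.concatenate([beat, beat])
        det = pp.detect_ppg_onsets(sig, 1000.0)
        assert len(det) == 2


class TestRWaveDetection:
    def test_impulse_train_recovered_within_2ms(self, noiseless_record):
        filt = pp.bandpass(noiseless_record)
        det = pp.detect_r_waves(filt.channels["ecg"], filt.fs)
        truth = noiseless_record.annotations["r_wave"]
        assert len(det) == len(truth)
        err_ms = np.array([np.min(np.abs(truth - d)) for d in det]) * 1000
        assert err_ms.max() <= 2.0

    def test_flat_ecg_gives_empty_result(self):
        assert pp.detect_r_waves(np.zeros(5000), 1000.0).size == 0

    def test_duplicate_impulse_suppressed_by_refractory(self, noiseless_record):
        filt = pp.bandpass(noiseless_record)
        ecg = filt.channels["ecg"].copy()
        truth = noiseless_record.annotations["r_wave"]
        dup = int((truth[3] + 0.05) * filt.fs)  # 50 ms after a true R-wave
        t = np.arange(len(ecg)) / filt.fs
        ecg += np.exp(-0.5 * ((t - dup / filt.fs) / 0.008) ** 2)
        det = pp.detect_r_waves(ecg, filt.fs)
        assert len(det) == len(truth)


class TestBeatQuality:
    def test_clean_window_all_pass(self, clean_record):
        filt = pp.bandpass(clean_record)
        onsets = pp.detect_ppg_onsets(filt.channels["ppg"], filt.fs)
        seg = pp.beat_quality(pp.BeatSegmentation(onsets), filt.channels["ppg"], filt.fs)
        assert seg.quality.all()

    def test_inverted_beat_fails_template_correlation(self, clean_record):
        filt = pp.bandpass(clean_record)
        ppg = filt.channels["ppg"].copy()
        onsets = pp.detect_ppg_onsets(ppg, filt.fs)
        i0, i1 = int(onsets[4] * filt.fs), int(onsets[5] * filt.fs)
        ppg[i0:i1] = ppg[i0:i1].mean() * 2 - ppg[i0:i1]  # amplitude inversion
        seg = pp.beat_quality(pp.BeatSegmentation(onsets), ppg, filt.fs)
        assert not seg.quality[4]
        assert "template_corr" in seg.reasons[4]

    def test_bradycardic_intervals_fail_rate_criterion(self):
        onsets = np.arange(0, 20, 2.0)  # 30 bpm
        seg = pp.beat_quality(pp.BeatSegmentation(onsets), np.zeros(20000), 1000.0)
        assert not seg.quality.any()
        assert all("rate" in r for r in seg.reasons)

    def test_single_beat_window_flagged_with_reason(self):
        seg = pp.beat_quality(pp.BeatSegmentation(np.array([0.0, 1.0])), np.zeros(2000), 1000.0)
        assert not seg.quality.any()
        assert seg.reasons[0] == ["too_few_beats"]


class TestWindowSelection:
    def test_default_variability_yields_a_window(self, clean_record):
        beat, seg, (t0, t1) = pp.process_record(clean_record)
        assert t1 - t0 >= 20.0
        ibis = np.diff(seg.onsets)
        prv = pp.pulse_rate_variability(ibis[(seg.onsets[:-1] >= t0) & (seg.onsets[1:] <= t1)])
        assert 5.0 <= prv <= 10.0

    def test_zero_variability_has_no_stable_window(self):
        spec = SubjectSpec("s", 40, 1.7, 7.0, "2", hr_variability=0.0, seed=1)
        rec = render_record(spec, duration=40, fs=1000)
        with pytest.raises(pp.NoStableWindowError, match="no stable") as exc:
            pp.process_record(rec)
        assert exc.value.failure_counts["prv_low"] > 0

    def test_record_shorter_than_window_rejected(self):
        rec = WaveformRecord({"ppg": np.zeros(15000)}, fs=1000.0)
        seg = pp.BeatSegmentation(np.arange(0.5, 14.5, 1.0))
        with pytest.raises(pp.PreprocessError, match="shorter"):
            pp.select_window(rec, seg)


class TestEnsembleAverage:
    def _identical_beat_signal(self, n_beats=6, fs=1000.0):
        beat = beat_from_template(make_beat_template("2", 7.0), 1000).samples
        sig = np.tile(beat, n_beats)
        onsets = np.arange(n_beats + 1) * (len(beat) / fs)
        return sig, onsets[: n_beats + 1], fs

    def test_identical_beats_average_to_single_beat(self):
        sig, onsets, fs = self._identical_beat_signal()
        avg = pp.ensemble_average(sig, onsets, L=1000, fs=fs)
        beat = sig[: int(onsets[1] * fs)]
        single = (beat - beat.min()) / np.ptp(beat)  # L matches the beat length
        assert np.abs(avg.samples - single).max() < 1e-9

    def test_output_spans_exactly_unit_range(self):
        sig, onsets, fs = self._identical_beat_signal()
        avg = pp.ensemble_average(sig, onsets, L=400, fs=fs)
        assert avg.samples.min() == 0.0
        assert avg.samples.max() == 1.0

    def test_fewer_than_five_beats_rejected(self):
        sig, onsets, fs = self._identical_beat_signal(n_beats=3)
        with pytest.raises(pp.PreprocessError, match="5"):
            pp.ensemble_average(sig, onsets[:4], L=400, fs=fs)

    def test_averaging_reduces_noise_variance_as_one_over_n(self):
        rng = np.random.default_rng(7)
        beat = beat_from_template(make_beat_template("2", 7.0), 500).samples
        n_beats, sigma = 1000, 0.05
        sig = np.tile(beat, n_beats) + rng.normal(0, sigma, 500 * n_beats)
        onsets = np.arange(n_beats + 1) * (len(beat) / 500.0)
        avg = pp.ensemble_average(sig, onsets, L=500, fs=500.0)
        single = (beat - beat.min()) / np.ptp(beat)
        residual_var = np.var(avg.samples - single)
        assert residual_var < 5 * sigma**2 / n_beats  # ~1/n scaling, loose factor


class TestPipelineDeterminism:
    def test_same_record_gives_bit_identical_beat(self, clean_record):
        b1, _, _ = pp.process_record(clean_record)
        b2, _, _ = pp.process_record(clean_record)
        assert np.array_equal(b1.samples, b2.samples)
        assert np.array_equal(b1.apg, b2.apg)

    def test_averaged_beat_matches_generating_template(self, clean_record):
        beat, _, _ = pp.process_record(clean_record)
        template = make_beat_template("2", 7.0, beat_period=1.0)
        ref = beat_from_template(template, beat.length)
        corr = np.corrcoef(beat.samples, ref.samples)[0, 1]
        assert corr > 0.99
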
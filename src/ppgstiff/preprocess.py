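"""Signal conditioning: bandpass filtering, beat segmentation, quality
gating, stable-window selection and ensemble averaging.

The pipeline mirrors standard finger-PPG practice: zero-phase bandpass
(0.35-20 Hz) so fiducial timing is never phase-shifted, beat identification
by the onset of the systolic upslope (PPG/BP) and by the R-wave (ECG),
per-beat quality flags against pulse-oximetry signal-quality criteria, then
selection of the earliest 20-s span of consecutive good beats at a pulse
rate variability between 5% and 10%, whose beats are length-normalized,
amplitude-normalized and averaged into one representative pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from . import config as _cfg
from .waveform_io import WaveformRecord


class PreprocessError(ValueError):
    pass


class NoStableWindowError(PreprocessError):
    """No span satisfied the quality + pulse-rate-variability gates."""

    def __init__(self, message: str, failure_counts: dict[str, int] | None = None):
        super().__init__(message)
        self.failure_counts = failure_counts or {}


@dataclass
class BeatSegmentation:
    """Beat onsets (PPG), R-wave times (ECG) and per-beat quality flags."""

    onsets: np.ndarray
    r_times: np.ndarray = field(default_factory=lambda: np.array([]))
    quality: "np.ndarray | None" = None  # bool per inter-onset beat
    reasons: list[list[str]] | None = None

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.onsets)


@dataclass
class AveragedBeat:
    """A length- and amplitude-normalized ensemble pulse with derivatives.

    ``samples`` span exactly [0, 1]; the first sample is the beat onset.
    ``vpg``/``apg`` are the smoothed first and second derivatives in 1/s and
    1/s**2 on the true time axis (``duration`` seconds across ``len(samples)``
    points).
    """

    samples: np.ndarray
    duration: float
    vpg: np.ndarray
    apg: np.ndarray
    n_beats_averaged: int

    @property
    def length(self) -> int:
        return len(self.samples)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.length) * (self.duration / self.length)

    @classmethod
    def from_samples(
        cls,
        samples: np.ndarray,
        duration: float,
        n_beats: int = 1,
        deriv_cfg: dict | None = None,
    ) -> "AveragedBeat":
        """Normalize raw samples to [0, 1] and attach smoothed derivatives."""
        deriv_cfg = deriv_cfg or _cfg.DERIVATIVE
        samples = np.asarray(samples, dtype=float)
        rng_ = samples.max() - samples.min()
        if rng_ <= 0:
            raise PreprocessError("cannot normalize a constant beat")
        samples = (samples - samples.min()) / rng_
        dt = duration / len(samples)
        win = min(deriv_cfg["window"], len(samples) // 2 * 2 - 1)
        vpg = sps.savgol_filter(samples, win, deriv_cfg["polyorder"], deriv=1, delta=dt)
        apg = sps.savgol_filter(samples, win, deriv_cfg["polyorder"], deriv=2, delta=dt)
        return cls(samples, float(duration), vpg, apg, n_beats)


def _sos(low: float, high: float, fs: float, order: int):
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(record: WaveformRecord, low: float = 0.35, high: float = 20.0,
             cfg: dict | None = None) -> WaveformRecord:
    """Zero-phase bandpass the PPG/BP channels; the ECG gets its own band.

    Forward-backward (filtfilt) application keeps fiducial timing unshifted.
    """
    cfg = cfg or _cfg.default_config()
    if record.fs <= 2 * high:
        raise PreprocessError(
            f"fs={record.fs} Hz violates the Nyquist constraint for a "
            f"{high} Hz band edge (need fs > {2 * high} Hz)"
        )
    sos_ppg = _sos(low, high, record.fs, cfg["filter_order"])
    ecg_lo, ecg_hi = cfg["ecg_band"]
    sos_ecg = _sos(ecg_lo, ecg_hi, record.fs, cfg["filter_order"])
    channels = {}
    for name, sig in record.channels.items():
        if name == "ecg":
            channels[name] = sps.sosfiltfilt(sos_ecg, sig)
        else:
            channels[name] = sps.sosfiltfilt(sos_ppg, sig)
    return WaveformRecord(
        channels, record.fs, record.subject_id, record.visit_id,
        {k: v.copy() for k, v in record.annotations.items()},
    )


def detect_ppg_onsets(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Beat onsets: the local minimum immediately preceding each maximal
    systolic upslope, in seconds.

    The zero-phase band limit rounds the V-shaped foot and pulls its minimum
    a few milliseconds early, so the onset is refined from the valley minimum
    to the point where the smoothed upslope first reaches 5% of the beat's
    maximal upslope — the operational "onset of the systolic upslope".
    """
    ppg = np.asarray(ppg, dtype=float)
    if ppg.size < 3 or np.ptp(ppg) == 0:
        return np.array([])
    k = max(1, int(0.02 * fs))
    smooth = np.convolve(ppg, np.ones(k) / k, mode="same")
    vpg = np.gradient(smooth) * fs
    vmax = np.percentile(vpg[vpg > 0], 98) if np.any(vpg > 0) else 0.0
    if vmax <= 0:
        return np.array([])
    peaks, _ = sps.find_peaks(vpg, height=0.45 * vmax, distance=int(0.30 * fs))
    onsets = []
    look = int(0.35 * fs)
    for p in peaks:
        start = max(0, p - look)
        seg = smooth[start: p + 1]
        if seg.size < 2:
            continue
        j = start + int(np.argmin(seg))
        while j < p and vpg[j] < 0.05 * vpg[p]:
            j += 1
        onsets.append(j)
    onsets = sorted(set(onsets))
    return np.asarray(onsets, dtype=float) / fs


def detect_r_waves(ecg: np.ndarray, fs: float, refractory_s: float = 0.25) -> np.ndarray:
    """R-wave times from a (filtered) single-lead ECG, one per QRS.

    Peaks of the squared signal above an adaptive threshold, with the
    refractory period enforced through the minimal peak distance.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < 3 or np.ptp(ecg) == 0:
        return np.array([])
    energy = ecg**2
    h = 0.2 * np.percentile(energy, 99.9)
    if h <= 0:
        return np.array([])
    peaks, _ = sps.find_peaks(energy, height=h, distance=max(1, int(refractory_s * fs)))
    return peaks / fs


def _resample_beat(ppg: np.ndarray, fs: float, t0: float, t1: float, n: int) -> np.ndarray:
    src = np.arange(int(round(t0 * fs)), int(round(t1 * fs)))
    src = src[(src >= 0) & (src < len(ppg))]
    phase = np.arange(n) / n
    return np.interp(phase, (src / fs - t0) / (t1 - t0), ppg[src])


def beat_quality(
    segmentation: BeatSegmentation,
    ppg: np.ndarray,
    fs: float,
    cfg: dict | None = None,
) -> BeatSegmentation:
    """Flag each inter-onset beat pass/fail with reason codes.

    Criteria: instantaneous rate within the plausible band, inter-beat
    interval not exceeding the maximal gap, window max/min IBI ratio within
    bound, and correlation of the beat with the mean template of the other
    beats at or above the threshold.
    """
    cfg = cfg or _cfg.default_config()
    q = cfg["quality"]
    onsets = segmentation.onsets
    n_beats = len(onsets) - 1
    if n_beats < 2:
        segmentation.quality = np.zeros(max(n_beats, 0), dtype=bool)
        segmentation.reasons = [["too_few_beats"]] * max(n_beats, 0)
        return segmentation
    ibis = segmentation.ibis
    lo_bpm, hi_bpm = q["hr_range_bpm"]
    shapes = np.stack(
        [_resample_beat(ppg, fs, onsets[i], onsets[i + 1], 100) for i in range(n_beats)]
    )
    shapes = shapes - shapes.mean(axis=1, keepdims=True)
    reasons: list[list[str]] = [[] for _ in range(n_beats)]
    ratio = ibis.max() / ibis.min() if ibis.min() > 0 else np.inf
    for i in range(n_beats):
        rate = 60.0 / ibis[i]
        if not (lo_bpm <= rate <= hi_bpm):
            reasons[i].append("rate")
        if ibis[i] > q["max_ibi_s"]:
            reasons[i].append("max_ibi")
        if ratio > q["max_ibi_ratio"]:
            reasons[i].append("ibi_ratio")
        template = shapes[np.arange(n_beats) != i].mean(axis=0)
        denom = np.linalg.norm(shapes[i]) * np.linalg.norm(template)
        corr = float(shapes[i] @ template / denom) if denom > 0 else 0.0
        if corr < q["min_template_corr"]:
            reasons[i].append("template_corr")
    segmentation.quality = np.array([not r for r in reasons])
    segmentation.reasons = reasons
    return segmentation


def pulse_rate_variability(ibis: np.ndarray) -> float:
    """PRV in percent: (max IBI - min IBI) / mean IBI * 100."""
    ibis = np.asarray(ibis, dtype=float)
    return float((ibis.max() - ibis.min()) / ibis.mean() * 100.0)


def select_window(
    record: WaveformRecord,
    segmentation: BeatSegmentation,
    win: float = 20.0,
    prv_range: tuple[float, float] = (5.0, 10.0),
    cfg: dict | None = None,
) -> tuple[float, float, np.ndarray]:
    """Earliest ``win``-second span of consecutive good-quality beats whose
    pulse rate variability lies within ``prv_range`` (percent).

    Returns ``(t_start, t_end, beat_indices)``; raises
    :class:`NoStableWindowError` with per-criterion failure counts otherwise.
    """
    if record.duration < win:
        raise PreprocessError(
            f"record of {record.duration:.1f} s is shorter than the {win:.0f}-s window"
        )
    if segmentation.quality is None:
        segmentation = beat_quality(
            segmentation, record.channels["ppg"], record.fs, cfg
        )
    onsets = segmentation.onsets
    n_beats = len(onsets) - 1
    fails = {"quality": 0, "prv_low": 0, "prv_high": 0, "too_short": 0}
    for k in range(n_beats):
        # smallest j with onsets[j] - onsets[k] >= win
        j = int(np.searchsorted(onsets, onsets[k] + win))
        if j > n_beats:
            fails["too_short"] += 1
            continue
        beats = np.arange(k, j)
        if not np.all(segmentation.quality[beats]):
            fails["quality"] += 1
            continue
        prv = pulse_rate_variability(segmentation.ibis[beats])
        if prv < prv_range[0]:
            fails["prv_low"] += 1
            continue
        if prv > prv_range[1]:
            fails["prv_high"] += 1
            continue
        return float(onsets[k]), float(onsets[j]), beats
    raise NoStableWindowError(
        f"no stable {win:.0f}-s window (PRV {prv_range[0]}-{prv_range[1]}%); "
        f"failure counts: {fails}",
        fails,
    )


def ensemble_average(
    ppg: np.ndarray,
    onsets: np.ndarray,
    L: int = 1000,
    fs: float = 1000.0,
    cfg: dict | None = None,
) -> AveragedBeat:
    """Average length-normalized, per-beat min-max-normalized beats.

    Each beat (onset to next onset) is resampled to ``L`` points, normalized
    to [0, 1], and averaged pointwise; the result is re-normalized so the
    ensemble beat spans [0, 1] exactly. Derivatives are obtained by smoothed
    polynomial (Savitzky-Golay) differentiation.
    """
    cfg = cfg or _cfg.default_config()
    onsets = np.asarray(onsets, dtype=float)
    n_beats = len(onsets) - 1
    if n_beats < 5:
        raise PreprocessError(f"need at least 5 beats to average, got {n_beats}")
    stack = np.empty((n_beats, L))
    for i in range(n_beats):
        beat = _resample_beat(ppg, fs, onsets[i], onsets[i + 1], L)
        rng_ = beat.max() - beat.min()
        if rng_ <= 0:
            raise PreprocessError(f"beat {i} is constant; cannot normalize")
        stack[i] = (beat - beat.min()) / rng_
    mean_beat = stack.mean(axis=0)
    duration = float(np.mean(np.diff(onsets)))
    return AveragedBeat.from_samples(mean_beat, duration, n_beats, cfg["derivative"])


def process_record(
    record: WaveformRecord, cfg: dict | None = None
) -> tuple[AveragedBeat, BeatSegmentation, tuple[float, float]]:
    """Full conditioning chain for one record.

    Bandpass -> beat/R-wave detection -> quality gating -> stable-window
    selection -> ensemble averaging. Returns the averaged beat, the
    segmentation (with quality flags) and the selected window bounds.
    """
    cfg = cfg or _cfg.default_config()
    low, high = cfg["ppg_band"]
    filtered = bandpass(record, low, high, cfg)
    onsets = detect_ppg_onsets(filtered.channels["ppg"], filtered.fs)
    if onsets.size < 2:
        raise PreprocessError("no beats found in record")
    r_times = (
        detect_r_waves(filtered.channels["ecg"], filtered.fs)
        if "ecg" in filtered.channels
        else np.array([])
    )
    seg = BeatSegmentation(onsets=onsets, r_times=r_times)
    seg = beat_quality(seg, filtered.channels["ppg"], filtered.fs, cfg)
    t0, t1, beats = select_window(
        filtered, seg, cfg["window"]["win_s"], tuple(cfg["window"]["prv_range_pct"]), cfg
    )
    window_onsets = seg.onsets[beats[0]: beats[-1] + 2]
    beat = ensemble_average(
        filtered.channels["ppg"], window_onsets, cfg["beat_length"], filtered.fs, cfg
    )
    return beat, seg, (t0, t1)
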
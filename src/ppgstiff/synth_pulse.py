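"""Synthetic finger-PPG / single-lead-ECG / finger-BP waveform simulator.

Each pulse is modelled as a sum of two to three Gaussian wave components —
a direct (incident) systolic wave, a reflected wave, and a small dicrotic
wave — which is sufficient to reproduce the six finger-PPG morphology
classes (1, 1', 2, 3, 3', 4) while keeping closed-form ground truth for the
fiducial-point detectors. A latent stiffness parameter (a PWV-like value in
m/s) shapes the morphology monotonically: higher stiffness moves the
reflected wave earlier and makes it relatively larger, producing the fused /
anacrotic morphologies of the stiffer classes.

The ECG channel is a stylized R-wave impulse train preceding each PPG pulse
onset by the pulse arrival time (PAT); the BP channel is the same component
mixture with narrower waves, leading the PPG by a configurable 20-30 ms, as
observed between finger pressure and finger PPG onsets.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` substreams so that cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as _cfg
from .waveform_io import WaveformRecord

VALID_CLASSES = ("1", "1p", "2", "3", "3p", "4")

#: Sharpening factor of the pressure channel relative to the PPG channel.
_BP_WIDTH_SCALE = 0.80


@dataclass(frozen=True)
class BeatTemplate:
    """A single-beat waveform model with ground-truth landmarks.

    ``components`` are Gaussian ``(amplitude, center, width)`` triples in
    arbitrary units / seconds, with strictly increasing centers. ``truth``
    holds landmark times in seconds from beat onset: ``direct_peak``
    (center of the incident wave), ``reflected`` (center of the reflected
    wave, NaN for degenerate single-component templates) and ``notch`` (local
    minimum of the noiseless composite between the two waves, NaN when the
    waves are fused).
    """

    components: tuple[tuple[float, float, float], ...]
    beat_period: float
    class_label: str
    truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.class_label not in VALID_CLASSES:
            raise ValueError(
                f"unknown class_label {self.class_label!r}; valid labels: {VALID_CLASSES}"
            )
        amps = [c[0] for c in self.components]
        centers = [c[1] for c in self.components]
        widths = [c[2] for c in self.components]
        if any(a <= 0 for a in amps) or any(w <= 0 for w in widths):
            raise ValueError("component amplitudes and widths must be positive")
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("component centers must be strictly increasing")
        if self.beat_period <= centers[-1]:
            raise ValueError("beat_period must exceed the last component center")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the beat at times ``t`` (s from onset), zero at both ends.

        The raw Gaussian mixture is corrected by the chord joining its values
        at 0 and at ``beat_period`` so consecutive beats concatenate with an
        exact local minimum at every onset.
        """
        t = np.asarray(t, dtype=float)
        raw = self._mixture(t)
        v0 = self._mixture(np.array(0.0))
        v1 = self._mixture(np.array(self.beat_period))
        return raw - (v0 + (v1 - v0) * t / self.beat_period)

    def _mixture(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t, dtype=float)
        for amp, center, width in self.components:
            out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        return out


def _delay_and_amp(preset: dict, stiffness: float) -> tuple[float, float]:
    delay = preset["delay0"] - preset["delay_slope"] * (stiffness - 8.0)
    rel_amp = preset["amp0"] + preset["amp_slope"] * (stiffness - 8.0)
    return delay, rel_amp


def make_beat_template(
    class_label: str,
    stiffness: float,
    beat_period: float = 1.0,
    *,
    reflected_scale: float = 1.0,
    dicrotic_scale: float = 1.0,
    upstroke_scale: float = 1.0,
    cfg: dict | None = None,
) -> BeatTemplate:
    """Build a class-preset beat template at a given latent stiffness.

    The reflected-wave delay decreases — and its relative amplitude and the
    shoulder separation of the direct complex increase — strictly
    monotonically with ``stiffness`` within every class. Setting
    ``reflected_scale=0`` with ``upstroke_scale=0`` and ``dicrotic_scale=0``
    yields the degenerate single-Gaussian template whose direct-peak truth is
    the sole component center (the analytic anchor for fiducial tests).
    """
    cfg = cfg or _cfg.default_config()
    if class_label not in VALID_CLASSES:
        raise ValueError(
            f"unknown class_label {class_label!r}; valid labels: {VALID_CLASSES}"
        )
    if not (0.5 <= beat_period <= 1.5):
        raise ValueError("beat_period must be in [0.5, 1.5] s")
    lo, hi = cfg["stiffness_range"]
    if not (lo <= stiffness <= hi):
        raise ValueError(f"stiffness {stiffness} outside simulation range [{lo}, {hi}]")

    preset = cfg["class_presets"][class_label]
    shape = cfg["wave_shape"]
    delay, rel_amp = _delay_and_amp(preset, stiffness)

    direct_amp = preset["direct_amp"]
    c1 = shape["direct_center"]
    c2 = c1 + delay
    f_up = upstroke_scale * (
        shape["upstroke_frac0"] + shape["upstroke_frac_slope"] * (stiffness - 8.0)
    )
    d_up = shape["upstroke_offset0"] + shape["upstroke_offset_slope"] * (stiffness - 8.0)
    components = []
    if f_up > 0:
        components.append((f_up * direct_amp, c1 - d_up, shape["upstroke_width"]))
    components.append((direct_amp, c1, shape["direct_width"]))
    direct_only = tuple(components)
    if reflected_scale * rel_amp > 0:
        components.append(
            (reflected_scale * rel_amp * direct_amp, c2, shape["reflected_width"])
        )
    if dicrotic_scale > 0 and reflected_scale > 0:
        # diastolic runoff keeps the pulse decaying into the next onset
        span = beat_period - c2
        components.append(
            (dicrotic_scale * shape["runoff_amp"] * direct_amp,
             c2 + shape["runoff_center_frac"] * span,
             shape["runoff_width_frac"] * span)
        )

    truth = {
        "direct_peak": _complex_peak(direct_only, c1),
        "reflected": c2 if len(components) > len(direct_only) else math.nan,
        "notch": math.nan,
    }
    template = BeatTemplate(tuple(components), beat_period, class_label, truth)
    if not math.isnan(truth["reflected"]):
        truth["notch"] = _notch_time(template, truth["direct_peak"], c2)
    return template


def _complex_peak(components: tuple[tuple[float, float, float], ...], c1: float) -> float:
    """Peak time of the direct systolic complex alone (fine-grid argmax)."""
    if len(components) == 1:
        return components[0][1]
    grid = np.arange(0.0, c1 + 0.2, 2.5e-4)
    v = np.zeros_like(grid)
    for amp, center, width in components:
        v += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return float(grid[np.argmax(v)])


def _notch_time(template: BeatTemplate, t_lo: float, t_hi: float) -> float:
    """Interior local minimum of the noiseless beat between two wave centers."""
    grid = np.arange(t_lo, t_hi, 1e-3)
    if grid.size < 3:
        return math.nan
    v = template.waveform(grid)
    interior = np.arange(1, grid.size - 1)
    is_min = (v[interior] < v[interior - 1]) & (v[interior] <= v[interior + 1])
    idx = interior[is_min]
    return float(grid[idx[0]]) if idx.size else math.nan


def sample_template(template: BeatTemplate, n: int) -> np.ndarray:
    """Sample one beat on ``n`` evenly spaced points across its period."""
    t = np.arange(n) * (template.beat_period / n)
    return template.waveform(t)


@dataclass(frozen=True)
class SubjectSpec:
    """Everything needed to render one subject's record deterministically."""

    subject_id: str
    age: float
    height: float
    stiffness: float
    class_label: str = "2"
    hr_mean: float = _cfg.SUBJECT_DEFAULTS["hr_mean"]
    hr_variability: float = _cfg.SUBJECT_DEFAULTS["hr_variability"]
    pat: float = _cfg.SUBJECT_DEFAULTS["pat"]
    noise_sd: float = _cfg.SUBJECT_DEFAULTS["noise_sd"]
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.hr_variability < 0.5):
            raise ValueError("hr_variability must be in [0, 0.5)")
        if self.pat <= 0:
            raise ValueError("pat must be positive")
        lo, hi = _cfg.STIFFNESS_RANGE
        if not (lo <= self.stiffness <= hi):
            raise ValueError(f"stiffness outside simulation range [{lo}, {hi}]")


def render_record(
    subject: SubjectSpec,
    duration: float = 40.0,
    fs: float = 1000.0,
    visit_id: int = 1,
    cfg: dict | None = None,
) -> WaveformRecord:
    """Render a multichannel record for one subject.

    The PPG channel concatenates per-beat templates with beat periods drawn
    around ``60/hr_mean`` with the stated relative variability, plus additive
    white noise and (when noisy) slow baseline wander. The ECG channel is an
    R-wave impulse train preceding each PPG onset by ``subject.pat``; the BP
    channel is the sharper pressure-shaped mixture leading the PPG by the
    configured 20-30 ms. Ground-truth beat onsets, R-wave times and per-beat
    landmark times are attached as annotations.
    """
    cfg = cfg or _cfg.default_config()
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    mean_period = 60.0 / subject.hr_mean
    if duration < mean_period + subject.pat:
        raise ValueError(
            f"duration {duration} s too short to fit one beat "
            f"(period {mean_period:.2f} s + PAT)"
        )
    rng = np.random.default_rng([subject.seed, visit_id, 0xBEA7])

    template = make_beat_template(
        subject.class_label, subject.stiffness, beat_period=min(mean_period, 1.5), cfg=cfg
    )
    bp_template = BeatTemplate(
        tuple((a, c, w * _BP_WIDTH_SCALE) for a, c, w in template.components),
        template.beat_period,
        template.class_label,
        dict(template.truth),
    )

    # beat grid
    t0 = subject.pat + 0.01
    onsets, periods = [], []
    t = t0
    while True:
        eps = float(np.clip(rng.standard_normal(), -3.0, 3.0))
        period = mean_period * (1.0 + subject.hr_variability * eps)
        if t + period > duration:
            break
        onsets.append(t)
        periods.append(period)
        t += period
    onsets_arr = np.array(onsets)
    periods_arr = np.array(periods)

    n = int(round(duration * fs))
    time = np.arange(n) / fs
    ppg = np.zeros(n)
    bp = np.zeros(n)
    scale = template.beat_period  # template defined on its own period
    for tau, period in zip(onsets, periods):
        i0 = int(math.ceil(tau * fs))
        i1 = min(n, int(math.ceil((tau + period) * fs)))
        local = (time[i0:i1] - tau) * (scale / period)
        ppg[i0:i1] += template.waveform(local)
        local_bp = (time[i0:i1] - tau) * (scale / period) + cfg["bp_lead_s"]
        bp[i0:i1] += bp_template.waveform(np.clip(local_bp, 0.0, scale))

    # stylized R-wave impulses (narrow Gaussians)
    ecg = np.zeros(n)
    r_times = onsets_arr - subject.pat
    for r in r_times:
        j0 = max(0, int((r - 0.04) * fs))
        j1 = min(n, int((r + 0.04) * fs))
        ecg[j0:j1] += np.exp(-0.5 * ((time[j0:j1] - r) / 0.008) ** 2)

    if subject.noise_sd > 0:
        wander = 2.0 * subject.noise_sd * np.sin(
            2 * np.pi * 0.18 * time + rng.uniform(0, 2 * np.pi)
        )
        ppg += wander + rng.normal(0.0, subject.noise_sd, n)
        bp += rng.normal(0.0, subject.noise_sd * 0.5, n)
        ecg += rng.normal(0.0, subject.noise_sd * 0.2, n)

    stretch = periods_arr / scale  # landmark times scale with the beat period
    annotations = {
        "onset": onsets_arr,
        "r_wave": r_times,
        "direct_peak": onsets_arr + template.truth["direct_peak"] * stretch,
        "reflected": onsets_arr + template.truth["reflected"] * stretch,
        "notch": onsets_arr + template.truth["notch"] * stretch,
    }
    annotations = {
        k: v[np.isfinite(v)] if np.isnan(v).any() else v for k, v in annotations.items()
    }
    return WaveformRecord(
        {"ppg": ppg, "ecg": ecg, "bp": bp},
        fs,
        subject_id=subject.subject_id,
        visit_id=visit_id,
        annotations=annotations,
    )


def default_stiffness_to_pwv(stiffness: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map latent stiffness to noiseless cfPWV-like and aoPWV-like outcomes.

    cfPWV is the latent value itself; aoPWV is an affine transform of it
    (aortic estimates run slightly higher than carotid-femoral tonometry in
    the emulated cohort).
    """
    stiffness = np.asarray(stiffness, dtype=float)
    return stiffness, 0.9 + 1.05 * stiffness


def make_cohort(
    n_subjects: int = 33,
    seed: int = 0,
    stiffness_to_pwv=default_stiffness_to_pwv,
    two_visits: bool = True,
    *,
    outcome_noise_sd: float = 0.3,
    duration: float = 40.0,
    fs: float = 1000.0,
    class_labels: tuple[str, ...] | None = None,
    noise_sd: float | None = None,
    cfg: dict | None = None,
) -> tuple[list[WaveformRecord], pd.DataFrame]:
    """Simulate a two-visit cohort of records plus a metadata table.

    Ages are uniform over 21-66 years and the latent stiffness rises with age
    (plus between-subject scatter), emulating vascular ageing. Waveform
    classes are drawn uniformly unless ``class_labels`` pins them. Visit 2 is
    a small within-subject perturbation of heart rate and stiffness. The
    metadata contains the noisy cfPWV-like / aoPWV-like outcomes
    (``outcome_noise_sd`` in m/s; 0 gives an exact monotone function of
    stiffness) alongside the latent truth.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    cfg = cfg or _cfg.default_config()
    rng = np.random.default_rng([seed, 0xC080])
    lo, hi = cfg["stiffness_range"]

    age = rng.uniform(21, 66, n_subjects)
    stiffness = np.clip(
        lo + (age - 21) / 45.0 * 6.0 + rng.normal(0, 0.8, n_subjects), lo + 0.1, hi - 0.1
    )
    if class_labels is None:
        classes = rng.choice(VALID_CLASSES, n_subjects)
    else:
        classes = np.resize(np.asarray(class_labels), n_subjects)
    height = np.clip(rng.normal(1.76, 0.10, n_subjects), 1.50, 2.05)
    hr = np.clip(rng.normal(60, 6, n_subjects), 45, 90)
    sbp = 95 + 2.0 * stiffness + rng.normal(0, 6, n_subjects)
    dbp = np.minimum(60 + 1.0 * stiffness + rng.normal(0, 5, n_subjects), sbp - 10)
    pat = np.clip(0.26 - 0.007 * stiffness + rng.normal(0, 0.008, n_subjects), 0.12, 0.35)

    cf_true, ao_true = stiffness_to_pwv(stiffness)
    cfpwv = cf_true + rng.normal(0, outcome_noise_sd, n_subjects)
    aopwv = ao_true + rng.normal(0, outcome_noise_sd * 1.2, n_subjects)

    base_noise = cfg["subject_defaults"]["noise_sd"] if noise_sd is None else noise_sd
    records: list[WaveformRecord] = []
    rows = []
    visits = (1, 2) if two_visits else (1,)
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        for visit in visits:
            d_hr = 0.0 if visit == 1 else float(rng.normal(0, 2))
            d_st = 0.0 if visit == 1 else float(rng.normal(0, 0.15))
            spec = SubjectSpec(
                subject_id=sid,
                age=float(age[i]),
                height=float(height[i]),
                stiffness=float(np.clip(stiffness[i] + d_st, lo, hi)),
                class_label=str(classes[i]),
                hr_mean=float(np.clip(hr[i] + d_hr, 40, 180)),
                pat=float(pat[i]),
                noise_sd=base_noise,
                seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
            )
            records.append(render_record(spec, duration=duration, fs=fs, visit_id=visit, cfg=cfg))
        rows.append(
            {
                "subject_id": sid,
                "age": float(age[i]),
                "height": float(height[i]),
                "sbp": float(sbp[i]),
                "dbp": float(dbp[i]),
                "hr": float(hr[i]),
                "class_label": str(classes[i]),
                "stiffness": float(stiffness[i]),
                "pat_true": float(pat[i]),
                "cfpwv": float(cfpwv[i]),
                "aopwv": float(aopwv[i]),
            }
        )
    meta = pd.DataFrame(rows).set_index("subject_id")
    return records, meta
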
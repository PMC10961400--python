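"""Default configuration for the PPG stiffness pipeline.

Every tunable threshold used by the pipeline lives here so that a run can be
reproduced from a single config mapping. Values can be overridden from a TOML
file via :func:`load_config`; unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import copy
import tomllib
from pathlib import Path
from typing import Any

#: Bandpass edges for PPG/BP conditioning (Hz). The low edge removes baseline
#: wander and the high edge removes high-frequency noise while preserving the
#: pulse morphology and its first two derivatives.
PPG_BAND = (0.35, 20.0)

#: Band used for R-wave enhancement on the single-lead ECG (Hz).
ECG_BAND = (5.0, 30.0)

#: Butterworth order per pass (applied forward-backward, zero phase).
FILTER_ORDER = 2

#: Beat-quality thresholds (signal-quality criteria for pulse oximetry beats:
#: plausible rate band, maximal inter-beat gap, maximal ratio of adjacent
#: inter-beat intervals, and minimal correlation with the running template).
QUALITY = {
    "hr_range_bpm": (40.0, 180.0),
    "max_ibi_s": 3.0,
    "max_ibi_ratio": 2.2,
    "min_template_corr": 0.86,
}

#: Stable-window search: window length and the accepted pulse-rate-variability
#: band in percent. PRV is (max IBI - min IBI) / mean IBI * 100 in the window.
WINDOW = {
    "win_s": 20.0,
    "prv_range_pct": (5.0, 10.0),
}

#: Ensemble-average length in samples. 1000 keeps 1 ms granularity for a
#: typical ~1 s beat sampled at 1000 Hz.
BEAT_LENGTH = 1000

#: Savitzky-Golay differentiation settings for the velocity (VPG) and
#: acceleration (APG) plethysmograms of the averaged beat.
DERIVATIVE = {"window": 31, "polyorder": 3}

#: p1 detection method: "tangent-at-b" anchors the tangent at the APG minimum
#: b; "ls-fallback" fits a least-squares line over the maximal span after w
#: where the APG stays within ``band_tol`` of APG(b).
P1 = {"method": "tangent-at-b", "band_tol": 0.10}

#: Repeatability filter: keep features whose within-subject coefficient of
#: variation is strictly below this threshold (percent).
WSCV_MAX_PCT = 20.0

#: Extreme-outlier rule: flag cells beyond Q3 + k*IQR or Q1 - k*IQR.
OUTLIER_IQR_K = 3.0

#: Modelling defaults: participant-level split proportion, the repeated
#: k-fold resampling scheme used for hyperparameter tuning, and algorithm
#: settings. ``cv_repeats`` may be lowered for quick runs; the default mirrors
#: the reference analysis protocol (10-fold, 50 repeats).
MODEL = {
    "train_prop": 0.8,
    "cv_folds": 10,
    "cv_repeats": 50,
    "lasso_alphas": 16,  # points on a log grid, 1e-3..1e1
    "rf_n_trees": 1000,
    "rf_mtry_grid": (0.33, 1.0),  # fraction of features per split
    "rf_min_leaf_grid": (2, 5),
    "max_missing_frac": 0.10,
}

#: Estimated-PWV equation for a normal population without cardiovascular risk
#: factors. ePWV = c0 + c_age*age + c_age2*age^2 + c_age2_mbp*age^2*MBP
#: + c_age_mbp*age*MBP + c_mbp*MBP with MBP = DBP + 0.4*(SBP - DBP) in mmHg,
#: age in years, result in m/s.
EPWV_COEF = {
    "c0": 9.587,
    "c_age": -0.402,
    "c_age2": 4.560e-3,
    "c_age2_mbp": -2.621e-5,
    "c_age_mbp": 3.176e-3,
    "c_mbp": -1.832e-2,
}
EPWV_MBP_WEIGHT = 0.4  # MBP = DBP + 0.4*(SBP-DBP)

# ---------------------------------------------------------------------------
# Simulator presets
# ---------------------------------------------------------------------------

#: Latent stiffness range used by the simulator (a PWV-like value in m/s,
#: spanning a healthy-to-stiff adult cohort).
STIFFNESS_RANGE = (4.0, 12.0)

#: Per-class beat-morphology presets. Each beat is a sum of a direct systolic
#: complex (a narrow upstroke Gaussian plus a broader body Gaussian — a pure
#: Gaussian would put the maximal deceleration exactly at the peak, whereas
#: real pulses decelerate hardest on the late upslope), a reflected wave and
#: a small dicrotic wave. The latent stiffness s (m/s) shapes the beat
#: monotonically:
#:
#:     delay(s)      = delay0 - delay_slope * (s - 8)      (reflection delay)
#:     rel_amp(s)    = amp0  + amp_slope   * (s - 8)       (reflection size)
#:     upstroke_frac = upstroke_frac0 + upstroke_frac_slope * (s - 8)
#:     upstroke_off  = upstroke_offset0 + upstroke_offset_slope * (s - 8)
#:
#: i.e. higher stiffness brings an earlier, relatively larger reflection and
#: an augmentation-coupled shoulder (the maximal-deceleration point separates
#: further from, and sits relatively lower than, the effective first peak).
#: Class regimes: 1/1' distinct direct peak and separate diastolic wave; 2 a
#: shallower notch; 3/3' fused waves, 3' with an anacrotic notch (inflection
#: on the upslope, direct complex smaller than the fused reflection); 4 an
#: almost single hump.
CLASS_PRESETS = {
    "1": {"direct_amp": 1.00, "delay0": 0.26, "delay_slope": 0.012,
          "amp0": 0.42, "amp_slope": 0.030, "dicrotic_amp": 0.06},
    "1p": {"direct_amp": 1.00, "delay0": 0.28, "delay_slope": 0.012,
           "amp0": 0.32, "amp_slope": 0.030, "dicrotic_amp": 0.05},
    "2": {"direct_amp": 1.00, "delay0": 0.21, "delay_slope": 0.011,
          "amp0": 0.55, "amp_slope": 0.030, "dicrotic_amp": 0.05},
    "3": {"direct_amp": 0.95, "delay0": 0.155, "delay_slope": 0.009,
          "amp0": 0.72, "amp_slope": 0.028, "dicrotic_amp": 0.04},
    "3p": {"direct_amp": 0.80, "delay0": 0.14, "delay_slope": 0.008,
           "amp0": 0.95, "amp_slope": 0.025, "dicrotic_amp": 0.04},
    "4": {"direct_amp": 0.90, "delay0": 0.105, "delay_slope": 0.006,
          "amp0": 0.85, "amp_slope": 0.025, "dicrotic_amp": 0.03},
}

#: Shared wave-shape constants (seconds, relative to beat onset).
WAVE_SHAPE = {
    "direct_center": 0.16,
    "direct_width": 0.065,
    "upstroke_width": 0.030,
    "upstroke_frac0": 0.55,
    "upstroke_frac_slope": -0.02,
    "upstroke_offset0": 0.065,
    "upstroke_offset_slope": 0.0025,
    "reflected_width": 0.070,
    # diastolic runoff: a broad wave filling diastole so the pulse decays
    # into a V-shaped foot at the next onset (fractions of the span from the
    # reflected-wave center to the end of the beat)
    "runoff_amp": 0.16,
    "runoff_center_frac": 0.45,
    "runoff_width_frac": 0.50,
}

#: Subject-level simulator defaults, matching a supine resting cohort:
#: mean heart rate 60 bpm, inter-beat-interval SD 2% of the mean (which puts
#: the 20-s-window pulse-rate variability in the accepted 5-10% band), pulse
#: arrival time 206 ms, additive noise SD 0.02 of unit pulse amplitude.
SUBJECT_DEFAULTS = {
    "hr_mean": 60.0,
    "hr_variability": 0.02,
    "pat": 0.206,
    "noise_sd": 0.02,
    "height": 1.76,
}

#: Lead of the pressure channel over the PPG channel, seconds (configurable
#: within 0.020-0.030).
BP_LEAD_S = 0.025

DEFAULTS: dict[str, Any] = {
    "ppg_band": PPG_BAND,
    "ecg_band": ECG_BAND,
    "filter_order": FILTER_ORDER,
    "quality": QUALITY,
    "window": WINDOW,
    "beat_length": BEAT_LENGTH,
    "derivative": DERIVATIVE,
    "p1": P1,
    "wscv_max_pct": WSCV_MAX_PCT,
    "outlier_iqr_k": OUTLIER_IQR_K,
    "model": MODEL,
    "epwv_coef": EPWV_COEF,
    "epwv_mbp_weight": EPWV_MBP_WEIGHT,
    "stiffness_range": STIFFNESS_RANGE,
    "class_presets": CLASS_PRESETS,
    "wave_shape": WAVE_SHAPE,
    "subject_defaults": SUBJECT_DEFAULTS,
    "bp_lead_s": BP_LEAD_S,
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the default configuration mapping."""
    return copy.deepcopy(DEFAULTS)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a TOML config overlaid on the defaults.

    Only keys present in the defaults may be overridden; nested mappings are
    merged one level deep.
    """
    cfg = default_config()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        user = tomllib.load(fh)
    for key, value in user.items():
        if key not in cfg:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(cfg[key], dict) and isinstance(value, dict):
            for sub, subval in value.items():
                if sub not in cfg[key]:
                    raise KeyError(f"unknown config key: {key}.{sub}")
                cfg[key][sub] = subval
        else:
            cfg[key] = value
    return cfg
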
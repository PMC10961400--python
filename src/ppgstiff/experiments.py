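"""Self-contained validation experiments on simulated data.

These routines exercise the package end to end at desk scale: the analytic
p1 anchor, fiducial robustness across the six morphology classes, the
monotone link between the key amplitude ratio and the latent stiffness, the
noise-floor recovery of outcome prediction, and a train-only-processing
leakage canary. They are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import config as _cfg
from . import features, models, synth_pulse
from .fiducials import detect_all
from .preprocess import AveragedBeat
from .pipeline import build_panels, prepare_model_inputs

_ORDER_CHAINS = (("a", "b", "c", "d", "e"), ("w", "p1"), ("x", "y"))


def beat_from_template(
    template: synth_pulse.BeatTemplate, L: int = 1000, cfg: dict | None = None
) -> AveragedBeat:
    """Sample a noiseless template into a normalized averaged beat."""
    cfg = cfg or _cfg.default_config()
    samples = synth_pulse.sample_template(template, L)
    return AveragedBeat.from_samples(samples, template.beat_period, 1, cfg["derivative"])


def template_features(
    class_label: str,
    stiffness: float,
    hr: float = 60.0,
    L: int = 1000,
    cfg: dict | None = None,
) -> dict[str, float]:
    """Noiseless single-beat feature row for one class/stiffness point."""
    cfg = cfg or _cfg.default_config()
    template = synth_pulse.make_beat_template(
        class_label, stiffness, beat_period=60.0 / hr, cfg=cfg
    )
    beat = beat_from_template(template, L, cfg)
    fset = detect_all(beat, cfg)
    return features.extract(beat, fset, hr)


def p1_anchor_error_ms(fs: float = 1000.0, sigma: float = 0.05, mu: float = 0.30,
                       period: float = 1.0) -> float:
    """p1 error (ms) of the tangent construction on a single-Gaussian pulse.

    For a Gaussian the APG minimum sits at the peak where the VPG is zero, so
    the tangent's zero-crossing equals the peak time analytically; any
    residual error is grid/smoothing resolution.
    """
    template = synth_pulse.BeatTemplate(
        ((1.0, mu, sigma),), period, "1", {"direct_peak": mu}
    )
    beat = beat_from_template(template, int(round(period * fs)))
    fset = detect_all(beat)
    if not fset.has("p1"):
        return math.inf
    return abs(fset.t("p1") - mu) * 1000.0


def fiducial_robustness(
    n_per_class: int = 200, seed: int = 0, L: int = 1000
) -> dict[str, float]:
    """p1 success rate and ordering-invariant violations across random
    parameterizations of all six class presets.

    Random draws cover the full stiffness range, beat periods 0.7-1.2 s and
    sampled lengths; returns the fraction of beats with p1 detected and the
    count of ordering violations among detected landmark chains.
    """
    rng = np.random.default_rng(seed)
    lo, hi = _cfg.STIFFNESS_RANGE
    total = 0
    p1_found = 0
    order_violations = 0
    for label in synth_pulse.VALID_CLASSES:
        for _ in range(n_per_class):
            stiffness = rng.uniform(lo + 0.05, hi - 0.05)
            period = rng.uniform(0.7, 1.2)
            template = synth_pulse.make_beat_template(label, stiffness, period)
            beat = beat_from_template(template, L)
            fset = detect_all(beat)
            total += 1
            if fset.has("p1"):
                p1_found += 1
            for chain in _ORDER_CHAINS:
                present = [p for p in chain if fset.has(p)]
                times = [fset.t(p) for p in present]
                if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                    order_violations += 1
    return {
        "n_beats": total,
        "p1_success_rate": p1_found / total,
        "ordering_violations": order_violations,
    }


def ambp1_stiffness_grid(
    class_label: str, n_grid: int = 20, cfg: dict | None = None
) -> np.ndarray:
    """"Am b/Am p1" evaluated over an even stiffness grid for one class."""
    lo, hi = _cfg.STIFFNESS_RANGE
    grid = np.linspace(lo + 0.1, hi - 0.1, n_grid)
    return np.array(
        [template_features(class_label, s, cfg=cfg)["Am b/Am p1"] for s in grid]
    )


def ambp1_monotone_all_classes(n_grid: int = 20) -> dict[str, bool]:
    """Is Am b/Am p1 strictly decreasing in stiffness for every class?"""
    return {
        label: bool(np.all(np.diff(ambp1_stiffness_grid(label, n_grid)) < 0))
        for label in synth_pulse.VALID_CLASSES
    }


def slope_sign_replicates(
    n_replicates: int = 100, n_subjects: int = 15, seed: int = 0
) -> float:
    """Fraction of synthetic cohorts with a negative Am b/Am p1 -> stiffness
    regression slope.

    Each replicate draws subjects across classes and the stiffness range,
    computes the feature from noiseless beats, adds observation noise to the
    stiffness-derived outcome, and fits a univariate linear regression.
    """
    rng = np.random.default_rng(seed)
    lo, hi = _cfg.STIFFNESS_RANGE
    negatives = 0
    for _ in range(n_replicates):
        stiff = rng.uniform(lo + 0.1, hi - 0.1, n_subjects)
        labels = rng.choice(synth_pulse.VALID_CLASSES, n_subjects)
        feat = np.array(
            [template_features(lab, s, L=500)["Am b/Am p1"] for lab, s in zip(labels, stiff)]
        )
        outcome = stiff + rng.normal(0, 0.3, n_subjects)
        ok = ~np.isnan(feat)
        slope = np.polyfit(feat[ok], outcome[ok], 1)[0]
        if slope < 0:
            negatives += 1
    return negatives / n_replicates


def wscv_oracle_max_dev(n_panels: int = 1000, seed: int = 0) -> float:
    """Maximal absolute deviation (percentage points) of the WSCV routine
    from a direct evaluation of 100*sqrt(sum d_i^2 / 2n)/grand-mean on random
    two-visit panels."""
    from .cohort_stats import wscv

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_panels):
        n = int(rng.integers(2, 40))
        pairs = rng.normal(rng.uniform(5, 100), rng.uniform(0.5, 10), size=(n, 2))
        d2 = 0.0
        total = 0.0
        for a, b in pairs:  # deliberately scalar arithmetic, no vectorization
            d2 += (a - b) ** 2
            total += a + b
        expected = 100.0 * math.sqrt(d2 / (2 * n)) / (total / (2 * n))
        worst = max(worst, abs(wscv(pairs) - expected))
    return worst


def noise_floor_experiment(
    n_seeds: int = 20,
    n_subjects: int = 200,
    outcome_noise_sd: float = 0.5,
    seed: int = 0,
    duration: float = 35.0,
    fs: float = 500.0,
    cv_repeats: int = 3,
    algorithms: tuple[str, ...] = ("lasso", "linear"),
) -> pd.DataFrame:
    """Best-model test RMSE against the outcome noise floor.

    Simulates single-visit cohorts whose cfPWV-like outcome is the latent
    stiffness plus Gaussian noise of SD ``outcome_noise_sd`` (m/s), runs the
    full record -> features -> model pipeline, and records each algorithm's
    held-out RMSE. With noiseless waveforms the features carry the stiffness
    signal, so the best test RMSE should approach the noise floor sigma.
    """
    cfg = _cfg.default_config()
    rows = []
    for k in range(n_seeds):
        rep_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        records, meta = synth_pulse.make_cohort(
            n_subjects,
            seed=rep_seed,
            two_visits=False,
            outcome_noise_sd=outcome_noise_sd,
            duration=duration,
            fs=fs,
            noise_sd=0.0,
            cfg=cfg,
        )
        panels, _errors = build_panels(records, meta, cfg)
        X, _aux, _rep, _audit = prepare_model_inputs(panels, cfg)
        y = meta.loc[X.index, "cfpwv"].astype(float)
        row = {"seed": rep_seed}
        for algo in algorithms:
            spec = models.ModelSpec(algorithm=algo, outcome="cfpwv", seed=rep_seed)
            if algo == "linear":
                X_m = X[[c for c in ("Am b/Am p1",) if c in X.columns]].dropna()
            else:
                X_m = X
            y_m = y.loc[X_m.index]
            (X_tr, y_tr), (X_te, y_te) = models.split(X_m, y_m, 0.8, rep_seed)
            fitted = models.tune_fit(X_tr, y_tr, spec, cfg, cv_repeats=cv_repeats)
            report = models.evaluate(fitted, X_te, y_te)
            row[f"rmse_{algo}"] = report.test_rmse
        row["rmse_best"] = min(v for k_, v in row.items() if k_.startswith("rmse_"))
        rows.append(row)
    return pd.DataFrame(rows)


def leakage_canary(
    seed: int = 0,
    n_subjects: int = 80,
    outcome_noise_sd: float = 0.5,
    duration: float = 35.0,
    fs: float = 500.0,
    cv_repeats: int = 3,
) -> dict[str, float]:
    """Test RMSE with and without a canary feature equal to the outcome on
    test rows only (constant on training rows).

    A pipeline whose scaling, filtering or tuning saw the test split could
    exploit the canary; train-only processing cannot, so the canary must not
    improve the held-out RMSE.
    """
    cfg = _cfg.default_config()
    records, meta = synth_pulse.make_cohort(
        n_subjects, seed=seed, two_visits=False, outcome_noise_sd=outcome_noise_sd,
        duration=duration, fs=fs, noise_sd=0.0, cfg=cfg,
    )
    panels, _errors = build_panels(records, meta, cfg)
    X, _aux, _rep, _audit = prepare_model_inputs(panels, cfg)
    y = meta.loc[X.index, "cfpwv"].astype(float)
    spec = models.ModelSpec(algorithm="lasso", outcome="cfpwv", seed=seed)

    (X_tr, y_tr), (X_te, y_te) = models.split(X, y, 0.8, seed)
    fitted = models.tune_fit(X_tr, y_tr, spec, cfg, cv_repeats=cv_repeats)
    rmse_without = models.evaluate(fitted, X_te, y_te).test_rmse

    # the canary is constant on training rows and equals the outcome on test
    # rows: processing restricted to the training split must discard it
    # (zero training variance), leaving predictions bit-identical; only a
    # pipeline whose scaling, filtering or tuning touches the test rows can
    # pick it up and change the held-out RMSE
    canary = pd.Series(0.0, index=X.index, name="canary")
    canary.loc[y_te.index] = y_te  # oracle values only where held out
    X_canary = X.join(canary)
    (Xc_tr, yc_tr), (Xc_te, yc_te) = models.split(X_canary, y, 0.8, seed)
    fitted_c = models.tune_fit(Xc_tr, yc_tr, spec, cfg, cv_repeats=cv_repeats)
    rmse_with = models.evaluate(fitted_c, Xc_te, yc_te).test_rmse
    return {"rmse_without_canary": rmse_without, "rmse_with_canary": rmse_with}
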
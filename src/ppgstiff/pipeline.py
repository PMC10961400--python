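"""End-to-end orchestration: records -> averaged beats -> fiducials ->
feature panels -> repeatability QC -> prediction models, with a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _cfg
from . import cohort_stats, features, models, synth_pulse
from .fiducials import detect_all
from .preprocess import PreprocessError, process_record
from .waveform_io import WaveformRecord

logger = logging.getLogger(__name__)


def features_for_record(
    record: WaveformRecord, height: float, cfg: dict | None = None
) -> dict[str, float]:
    """One feature-panel row for one record.

    Runs conditioning, fiducial detection and feature extraction; appends
    the window heart rate, PAT and height-normalized PAT.
    """
    cfg = cfg or _cfg.default_config()
    beat, seg, (t0, t1) = process_record(record, cfg)
    hr = 60.0 / beat.duration
    fset = detect_all(beat, cfg)
    row = features.extract(beat, fset, hr)
    row["hr"] = hr
    in_win = (seg.onsets >= t0) & (seg.onsets <= t1)
    try:
        pat_ms, npat = features.pat_npat(seg.r_times, seg.onsets[in_win], height)
    except ValueError:
        pat_ms, npat = math.nan, math.nan
    row["pat"] = pat_ms
    row["npat"] = npat
    row["_window_start"] = t0
    row["_window_end"] = t1
    row["_n_beats"] = beat.n_beats_averaged
    return row


def build_panels(
    records: list[WaveformRecord],
    meta: pd.DataFrame,
    cfg: dict | None = None,
) -> tuple[dict[int, pd.DataFrame], list[dict]]:
    """Per-visit feature panels (one row per subject) and an error table."""
    cfg = cfg or _cfg.default_config()
    rows: dict[int, dict[str, dict]] = {}
    errors: list[dict] = []
    for record in records:
        height = float(meta.loc[record.subject_id, "height"])
        try:
            row = features_for_record(record, height, cfg)
        except PreprocessError as exc:
            errors.append(
                {"subject_id": record.subject_id, "visit_id": record.visit_id,
                 "error": str(exc)}
            )
            continue
        rows.setdefault(record.visit_id, {})[record.subject_id] = row
    panels = {
        visit: pd.DataFrame.from_dict(visit_rows, orient="index").rename_axis("subject_id")
        for visit, visit_rows in rows.items()
    }
    return panels, errors


_AUX_COLS = ("hr", "pat", "npat", "_window_start", "_window_end", "_n_beats")


def prepare_model_inputs(
    panels: dict[int, pd.DataFrame],
    cfg: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Visit-averaged, repeatability-filtered feature matrix.

    Returns (features X, auxiliary columns, repeatability report, audit log).
    Filtering (zero variance, WSCV) is computed from the visit panels; note
    the models module re-learns scaling on its training split only.
    """
    cfg = cfg or _cfg.default_config()
    if set(panels) >= {1, 2}:
        rep = cohort_stats.repeatability_report(panels[1], panels[2])
        averaged = cohort_stats.average_visits(panels[1], panels[2])
    else:
        only = panels[next(iter(panels))]
        rep = pd.DataFrame(index=only.columns)
        averaged = only
    aux = averaged[[c for c in _AUX_COLS if c in averaged.columns]]
    feats = averaged.drop(columns=[c for c in averaged.columns if c in _AUX_COLS])
    filtered, _flags, audit = cohort_stats.filter_features(
        feats, rep, cfg["wscv_max_pct"], cfg["outlier_iqr_k"]
    )
    return filtered, aux, rep, audit


def run_all(
    out_dir: str | Path,
    n_subjects: int = 33,
    two_visits: bool = True,
    seed: int = 7,
    algorithms: tuple[str, ...] = ("lasso", "random_forest", "linear"),
    outcome: str = "cfpwv",
    include_npat: bool = False,
    drop_outcome_outliers: bool = False,
    cv_repeats: int | None = None,
    duration: float = 40.0,
    fs: float = 1000.0,
    cfg: dict | None = None,
) -> dict:
    """Simulate a cohort and run the full analysis, writing all reports.

    The linear model uses only the key amplitude ratio "Am b/Am p1". Outputs
    under ``out_dir``: the visit panels, the averaged/filtered panel, the
    repeatability report, the filter audit log, one model report per
    algorithm and a manifest (config hash + seeds) sufficient to reproduce
    the run.
    """
    cfg = cfg or _cfg.default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, meta = synth_pulse.make_cohort(
        n_subjects, seed=seed, two_visits=two_visits, duration=duration, fs=fs, cfg=cfg
    )
    meta.to_csv(out / "meta.csv")
    panels, errors = build_panels(records, meta, cfg)
    for visit, panel in panels.items():
        panel.to_csv(out / f"panel_v{visit}.csv")
    if errors:
        pd.DataFrame(errors).to_csv(out / "errors.csv", index=False)

    X, aux, rep, audit = prepare_model_inputs(panels, cfg)
    X.to_csv(out / "panel_filtered.csv")
    rep.to_csv(out / "repeatability.csv")
    with open(out / "filter_audit.jsonl", "w") as fh:
        for entry in audit:
            fh.write(json.dumps(entry) + "\n")

    y = meta.loc[X.index, outcome].astype(float)
    if drop_outcome_outliers:
        q1, q3 = y.quantile([0.25, 0.75])
        iqr = q3 - q1
        keep = (y >= q1 - cfg["outlier_iqr_k"] * iqr) & (y <= q3 + cfg["outlier_iqr_k"] * iqr)
        if (~keep).any():
            logger.info("dropping outcome outliers: %s", list(y.index[~keep]))
        X, y = X.loc[keep], y.loc[keep]
    if include_npat and "npat" in aux.columns:
        X = X.join(aux["npat"])

    reports = {}
    for algo in algorithms:
        spec = models.ModelSpec(
            algorithm=algo, feature_set="updated", include_npat=include_npat,
            outcome=outcome, seed=seed,
        )
        if algo == "linear":
            sub = [c for c in ("Am b/Am p1",) if c in X.columns]
            if include_npat and "npat" in X.columns:
                sub.append("npat")
            X_model = X[sub].dropna()
        else:
            X_model = X
        y_model = y.loc[X_model.index]
        (X_tr, y_tr), (X_te, y_te) = models.split(
            X_model, y_model, cfg["model"]["train_prop"], seed
        )
        fitted = models.tune_fit(X_tr, y_tr, spec, cfg, cv_repeats=cv_repeats)
        imp = (
            models.importance(fitted, X_tr, y_tr)
            if algo == "random_forest"
            else models.importance(fitted)
        )
        report = models.evaluate(fitted, X_te, y_te, imp)
        reports[algo] = report
        with open(out / f"model_{algo}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        report.predictions.to_csv(out / f"predictions_{algo}.csv")

    manifest = {
        "seed": seed,
        "n_subjects": n_subjects,
        "two_visits": two_visits,
        "outcome": outcome,
        "duration_s": duration,
        "fs_hz": fs,
        "cv_repeats": cv_repeats if cv_repeats is not None else cfg["model"]["cv_repeats"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_record_errors": len(errors),
        "n_features_after_filter": int(X.shape[1]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"reports": reports, "panels": panels, "X": X, "meta": meta,
            "manifest": manifest, "errors": errors}
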
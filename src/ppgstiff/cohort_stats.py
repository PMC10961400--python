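"""Two-visit aggregation, repeatability statistics, feature filtering,
scaling and agreement analyses.

Repeatability uses the within-subject coefficient of variation by the
root-mean-square-error method: WSCV = 100 * sqrt(sum(d_i^2) / 2n) / grand
mean, where d_i is the visit-1 minus visit-2 difference for subject i. The
coefficient of variation keeps the sign of the mean (negative-mean features
report negative CV). Agreement between paired measurements is summarized by
Bland-Altman bias and limits of agreement at +/- 1.96 SD of the errors,
together with RMSE and R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class AgreementReport:
    """Bland-Altman bias and limits of agreement, plus RMSE and R^2."""

    bias: float
    loa_low: float
    loa_high: float
    rmse: float
    r2: float
    n: int


def average_visits(panel_v1: pd.DataFrame, panel_v2: pd.DataFrame) -> pd.DataFrame:
    """Cellwise mean of the two visit panels.

    A value present for only one visit passes through as the average;
    both-missing stays missing. Subjects present in only one panel are
    excluded (the protocol requires both visits).
    """
    common = panel_v1.index.intersection(panel_v2.index)
    dropped = set(panel_v1.index).symmetric_difference(panel_v2.index)
    if dropped:
        import warnings

        warnings.warn(f"subjects present in only one visit excluded: {sorted(dropped)}")
    cols = panel_v1.columns.intersection(panel_v2.columns)
    a = panel_v1.loc[common, cols]
    b = panel_v2.loc[common, cols]
    stacked = pd.concat([a, b])
    return stacked.groupby(level=0).mean().loc[common]


def cv(values: np.ndarray) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean.

    The sign follows the mean; a zero mean is undefined (NaN)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        raise ValueError("cv requires at least 2 values")
    mean = values.mean()
    if mean == 0:
        return math.nan
    return float(100.0 * values.std(ddof=1) / mean)


def wscv(pairs: np.ndarray) -> float:
    """Within-subject CV (RMSE method) in percent for two-visit pairs.

    ``pairs`` is (n, 2). WSCV = 100 * sqrt(sum d_i^2 / (2n)) / grand mean,
    with d_i the per-subject visit difference. Pairs with any missing value
    are dropped; a zero grand mean is undefined (NaN).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    pairs = pairs[~np.isnan(pairs).any(axis=1)]
    n = len(pairs)
    if n < 2:
        raise ValueError("wscv requires at least 2 complete pairs")
    d = pairs[:, 0] - pairs[:, 1]
    grand_mean = pairs.mean()
    if grand_mean == 0:
        return math.nan
    within_sd = math.sqrt(float(np.sum(d**2)) / (2 * n))
    return float(100.0 * within_sd / grand_mean)


def repeatability_report(panel_v1: pd.DataFrame, panel_v2: pd.DataFrame) -> pd.DataFrame:
    """Per-feature dispersion and repeatability across the two visits.

    Columns: mean/sd/cv per visit, Pearson r and p between visits, and WSCV.
    """
    common = panel_v1.index.intersection(panel_v2.index)
    rows = {}
    for col in panel_v1.columns.intersection(panel_v2.columns):
        v1 = panel_v1.loc[common, col].to_numpy(dtype=float)
        v2 = panel_v2.loc[common, col].to_numpy(dtype=float)
        paired = ~np.isnan(v1) & ~np.isnan(v2)
        row = {
            "mean_v1": np.nanmean(v1), "sd_v1": np.nanstd(v1, ddof=1),
            "mean_v2": np.nanmean(v2), "sd_v2": np.nanstd(v2, ddof=1),
        }
        row["cv_v1"] = cv(v1[~np.isnan(v1)]) if (~np.isnan(v1)).sum() >= 2 else math.nan
        row["cv_v2"] = cv(v2[~np.isnan(v2)]) if (~np.isnan(v2)).sum() >= 2 else math.nan
        if paired.sum() >= 3 and np.std(v1[paired]) > 0 and np.std(v2[paired]) > 0:
            r, p = sstats.pearsonr(v1[paired], v2[paired])
            row["pearson_r"], row["p_value"] = float(r), float(p)
        else:
            row["pearson_r"], row["p_value"] = math.nan, math.nan
        row["wscv"] = (
            abs(wscv(np.column_stack([v1, v2]))) if paired.sum() >= 2 else math.nan
        )
        rows[col] = row
    return pd.DataFrame(rows).T


def filter_features(
    panel: pd.DataFrame,
    wscv_report: pd.DataFrame,
    wscv_max: float = 20.0,
    iqr_k: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Drop zero-variance and poorly repeatable features; flag extreme cells.

    Features with zero variance are excluded first, then features with
    WSCV >= ``wscv_max`` percent. Extreme outliers (beyond Q3 + k*IQR or
    Q1 - k*IQR) are flagged, not dropped. Returns the filtered panel, a
    boolean outlier-flag frame aligned to it, and an audit log with one entry
    per action. The audit log plus surviving columns exactly partition the
    input columns.
    """
    audit: list[dict] = []
    keep: list[str] = []
    for col in panel.columns:
        vals = panel[col].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size == 0 or np.ptp(finite) == 0:
            audit.append({"feature": col, "action": "drop", "reason": "zero variance"})
            continue
        w = wscv_report["wscv"].get(col, math.nan) if "wscv" in wscv_report else math.nan
        if not math.isnan(w) and w >= wscv_max:
            audit.append(
                {"feature": col, "action": "drop",
                 "reason": f"WSCV {w:.2f}% >= {wscv_max}%"}
            )
            continue
        keep.append(col)
    filtered = panel[keep].copy()
    flags = pd.DataFrame(False, index=filtered.index, columns=keep)
    for col in keep:
        vals = filtered[col].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        q1, q3 = np.percentile(finite, [25, 75])
        iqr = q3 - q1
        mask = (vals > q3 + iqr_k * iqr) | (vals < q1 - iqr_k * iqr)
        if np.any(mask):
            flags[col] = mask
            audit.append(
                {"feature": col, "action": "flag",
                 "reason": f"{int(mask.sum())} extreme outlier cell(s) (3xIQR rule)"}
            )
    return filtered, flags, audit


class Scaler:
    """Center/scale transform with training statistics frozen for test data."""

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.sd_: pd.Series | None = None

    def fit(self, panel: pd.DataFrame) -> "Scaler":
        self.mean_ = panel.mean()
        self.sd_ = panel.std(ddof=0)
        if (self.sd_ == 0).any():
            bad = list(self.sd_[self.sd_ == 0].index)
            raise ValueError(f"zero-sd columns reached scaling (should be filtered): {bad}")
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise RuntimeError("Scaler is not fitted")
        return (panel[self.mean_.index] - self.mean_) / self.sd_

    def fit_transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        return self.fit(panel).transform(panel)


def center_scale(panel: pd.DataFrame) -> tuple[pd.DataFrame, Scaler]:
    """Center each column to mean 0 and scale to SD 1; returns the scaler so
    test data can reuse the training statistics."""
    scaler = Scaler()
    return scaler.fit_transform(panel), scaler


def bland_altman(x: np.ndarray, y: np.ndarray) -> AgreementReport:
    """Agreement of ``y`` against ``x``: bias = mean(y - x), limits of
    agreement at bias +/- 1.96 SD of the errors, plus RMSE and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("bland_altman requires at least 3 pairs")
    err = y - x
    bias = float(err.mean())
    sd = float(err.std(ddof=1))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else math.nan
    return AgreementReport(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        rmse=rmse, r2=r2, n=x.size,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("pearson requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)
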
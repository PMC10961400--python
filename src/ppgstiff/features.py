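"""Waveform feature registry and extraction, plus clinical index formulas.

The baseline registry holds 136 established pulse-waveform features in the
conventional PPG/VPG/APG vocabulary (times, amplitudes, derivative values,
amplitude ratios, time ratios, widths, areas, slopes and pulse statistics);
the updated registry adds 17 engineered features, 13 of which use the new
tangent-derived first systolic peak p1. The exact composition of the
established catalogue is pinned by this module's machine-readable manifest
(:func:`manifest`); every formula is documented on its definition.

Feature values are computed on the normalized averaged beat: amplitudes are
in normalized units (pulse spans [0, 1]), times in seconds, derivative
values in 1/s and 1/s**2. Features whose required fiducials are absent
evaluate to NaN — landmarks are never fabricated. Heart-rate-adjusted
variants (plain division by HR in bpm, suffix " HR") are appended to every
base feature at extraction time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import config as _cfg
from .fiducials import FiducialSet
from .preprocess import AveragedBeat

# phase of the waveform each landmark belongs to
_POINT_PHASE = {
    "O": "early", "a": "early", "b": "early", "w": "early", "S": "early",
    "p1": "early", "x": "early",
    "c": "mixed", "d": "mixed", "y": "mixed", "z": "mixed",
    "e": "late", "f": "late", "N": "late", "D": "late",
}

_WIDTH_LEVELS = (10, 25, 33, 50, 66, 75, 90)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    formula: str
    ftype: str  # amplitude | amplitude-ratio | time | time-ratio | area | area-ratio | slope | derived-index
    phase: str  # early | late | mixed
    requires: tuple[str, ...]
    fn: Callable[["EvalContext"], float]
    is_new: bool = False
    uses_p1: bool = False


class EvalContext:
    """Cached beat quantities a feature formula may reference."""

    def __init__(self, beat: AveragedBeat, fset: FiducialSet):
        self.beat = beat
        self.fset = fset
        self.T = beat.duration
        self._dt = beat.duration / beat.length

    def t(self, name: str) -> float:
        return self.fset.t(name)

    def amp(self, name: str) -> float:
        return self.fset.amp(name)

    def _idx(self, name: str) -> int:
        return min(self.beat.length - 1, int(round(self.t(name) / self._dt)))

    def vpg_at(self, name: str) -> float:
        return float(np.interp(self.t(name), self.beat.time, self.beat.vpg))

    def apg_at(self, name: str) -> float:
        return float(np.interp(self.t(name), self.beat.time, self.beat.apg))

    def amp_at_time(self, t: float) -> float:
        return float(np.interp(t, self.beat.time, self.beat.samples))

    def width(self, level_pct: int) -> tuple[float, float]:
        """(systolic, diastolic) width of the pulse at ``level_pct``% height."""
        frac = level_pct / 100.0
        s = self.beat.samples
        i_s = int(np.argmax(s))
        t = self.beat.time
        up = np.nonzero(s[: i_s + 1] < frac)[0]
        down = np.nonzero(s[i_s:] < frac)[0]
        if up.size == 0 or down.size == 0:
            return math.nan, math.nan
        i0 = up[-1]  # last sample below level before the peak
        t_up = float(np.interp(frac, [s[i0], s[i0 + 1]], [t[i0], t[i0 + 1]]))
        j0 = i_s + down[0]
        t_down = float(np.interp(frac, [s[j0], s[j0 - 1]], [t[j0], t[j0 - 1]]))
        return t[i_s] - t_up, t_down - t[i_s]

    def area(self, t0: float, t1: float) -> float:
        """Trapezoidal area under the normalized pulse between two times."""
        mask = (self.beat.time >= t0) & (self.beat.time <= t1)
        if mask.sum() < 2:
            return math.nan
        return float(np.trapezoid(self.beat.samples[mask], self.beat.time[mask]))


def _q(a: float, b: float) -> float:
    return a / b if b not in (0.0, -0.0) and not math.isnan(b) else math.nan


def _phase_of(points: tuple[str, ...]) -> str:
    phases = {_POINT_PHASE.get(p, "mixed") for p in points}
    if phases == {"early"}:
        return "early"
    if phases == {"late"}:
        return "late"
    return "mixed"


def _pt_features() -> list[FeatureDef]:
    """Times, amplitudes and derivative values at named landmarks."""
    defs: list[FeatureDef] = []
    pts = ("S", "N", "D", "w", "y", "z", "a", "b", "c", "d", "e", "f")
    for p in pts:
        defs.append(FeatureDef(
            f"Tm {p}", f"t({p})", "time", _phase_of((p,)), (p,),
            lambda c, p=p: c.t(p)))
    for p in pts:
        defs.append(FeatureDef(
            f"Am {p}", f"ppg(t({p}))", "amplitude", _phase_of((p,)), (p,),
            lambda c, p=p: c.amp(p)))
    for p in ("w", "y", "z"):
        defs.append(FeatureDef(
            f"Vpg {p}", f"vpg(t({p}))", "derived-index", _phase_of((p,)), (p,),
            lambda c, p=p: c.vpg_at(p)))
    for p in ("a", "b", "c", "d", "e", "f"):
        defs.append(FeatureDef(
            f"Apg {p}", f"apg(t({p}))", "derived-index", _phase_of((p,)), (p,),
            lambda c, p=p: c.apg_at(p)))
    return defs  # 12 + 12 + 3 + 6 = 33


def _apg_ratio_features() -> list[FeatureDef]:
    """Classic APG amplitude ratios, including ageing-type indices."""
    defs = []
    simple = ("b", "c", "d", "e")
    for p in simple:
        defs.append(FeatureDef(
            f"{p}/a", f"apg({p})/apg(a)", "amplitude-ratio", _phase_of((p, "a")),
            (p, "a"), lambda c, p=p: _q(c.apg_at(p), c.apg_at("a"))))
    combos = {
        "(b-c-d-e)/a": ("b", "c", "d", "e"),
        "(b-e)/a": ("b", "e"),
        "(b-c-d)/a": ("b", "c", "d"),
        "(b-d)/a": ("b", "d"),
    }
    for name, pts in combos.items():
        def fn(c, pts=pts):
            val = c.apg_at(pts[0]) - sum(c.apg_at(p) for p in pts[1:])
            return _q(val, c.apg_at("a"))
        defs.append(FeatureDef(
            name, name.replace("/a", "/apg(a)"), "amplitude-ratio",
            _phase_of(pts + ("a",)), pts + ("a",), fn))
    return defs  # 8


def _amp_ratio_features() -> list[FeatureDef]:
    defs = []
    for p in ("N", "D", "w", "y", "b", "c", "d", "e"):
        defs.append(FeatureDef(
            f"Am {p}/Am S", f"ppg({p})/ppg(S)", "amplitude-ratio",
            _phase_of((p, "S")), (p, "S"),
            lambda c, p=p: _q(c.amp(p), c.amp("S"))))
    for p in ("N", "b"):
        defs.append(FeatureDef(
            f"Am {p}/Am D", f"ppg({p})/ppg(D)", "amplitude-ratio",
            _phase_of((p, "D")), (p, "D"),
            lambda c, p=p: _q(c.amp(p), c.amp("D"))))
    return defs  # 10


def _time_ratio_features() -> list[FeatureDef]:
    defs = []
    for p in ("S", "N", "D", "w", "y", "z", "a", "b", "c", "d", "e", "f"):
        defs.append(FeatureDef(
            f"Tm {p}/Tm ss", f"t({p})/T", "time-ratio", _phase_of((p,)), (p,),
            lambda c, p=p: _q(c.t(p), c.T)))
    return defs  # 12


_INTERVALS = (("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
              ("a", "e"), ("w", "S"), ("S", "N"))


def _interval_features() -> list[FeatureDef]:
    defs = []
    for p, q in _INTERVALS:
        defs.append(FeatureDef(
            f"Tm {p}{q}", f"t({q})-t({p})", "time", _phase_of((p, q)), (p, q),
            lambda c, p=p, q=q: c.t(q) - c.t(p)))
    for p, q in _INTERVALS:
        defs.append(FeatureDef(
            f"Tm {p}{q}/Tm ss", f"(t({q})-t({p}))/T", "time-ratio",
            _phase_of((p, q)), (p, q),
            lambda c, p=p, q=q: _q(c.t(q) - c.t(p), c.T)))
    return defs  # 14


def _width_features() -> list[FeatureDef]:
    defs = []
    for lv in _WIDTH_LEVELS:
        defs.append(FeatureDef(
            f"W{lv}", f"pulse width at {lv}% height", "time", "mixed", ("S",),
            lambda c, lv=lv: sum(c.width(lv))))
        defs.append(FeatureDef(
            f"SW{lv}", f"systolic width at {lv}% height", "time", "early", ("S",),
            lambda c, lv=lv: c.width(lv)[0]))
        defs.append(FeatureDef(
            f"DW{lv}", f"diastolic width at {lv}% height", "time", "late", ("S",),
            lambda c, lv=lv: c.width(lv)[1]))
    for lv in _WIDTH_LEVELS:
        defs.append(FeatureDef(
            f"DW{lv}/SW{lv}", f"diastolic/systolic width ratio at {lv}%",
            "time-ratio", "mixed", ("S",),
            lambda c, lv=lv: _q(c.width(lv)[1], c.width(lv)[0])))
    return defs  # 28


def _area_features() -> list[FeatureDef]:
    defs = [
        FeatureDef("AUC", "area under pulse over beat", "area", "mixed", (),
                   lambda c: c.area(0.0, c.T)),
        FeatureDef("A1", "area onset->N", "area", "mixed", ("N",),
                   lambda c: c.area(0.0, c.t("N"))),
        FeatureDef("A2", "area N->end", "area", "late", ("N",),
                   lambda c: c.area(c.t("N"), c.T)),
        FeatureDef("A2/A1", "inflection point area ratio", "area-ratio", "mixed",
                   ("N",), lambda c: _q(c.area(c.t("N"), c.T), c.area(0.0, c.t("N")))),
        FeatureDef("A1/AUC", "systolic area fraction", "area-ratio", "mixed", ("N",),
                   lambda c: _q(c.area(0.0, c.t("N")), c.area(0.0, c.T))),
        FeatureDef("A2/AUC", "diastolic area fraction", "area-ratio", "mixed", ("N",),
                   lambda c: _q(c.area(c.t("N"), c.T), c.area(0.0, c.T))),
        FeatureDef("Asys", "area onset->S", "area", "early", ("S",),
                   lambda c: c.area(0.0, c.t("S"))),
        FeatureDef("Adia", "area S->end", "area", "late", ("S",),
                   lambda c: c.area(c.t("S"), c.T)),
        FeatureDef("Adia/Asys", "diastolic/systolic area ratio", "area-ratio",
                   "mixed", ("S",),
                   lambda c: _q(c.area(c.t("S"), c.T), c.area(0.0, c.t("S")))),
    ]
    return defs  # 9


def _slope_stat_features() -> list[FeatureDef]:
    from scipy import stats as sstats

    defs = [
        FeatureDef("slope OS", "(ppg(S)-ppg(O))/t(S)", "slope", "early", ("S",),
                   lambda c: _q(c.amp("S") - c.amp("O"), c.t("S"))),
        FeatureDef("slope SN", "(ppg(N)-ppg(S))/(t(N)-t(S))", "slope", "mixed",
                   ("S", "N"),
                   lambda c: _q(c.amp("N") - c.amp("S"), c.t("N") - c.t("S"))),
        FeatureDef("slope ND", "(ppg(D)-ppg(N))/(t(D)-t(N))", "slope", "late",
                   ("N", "D"),
                   lambda c: _q(c.amp("D") - c.amp("N"), c.t("D") - c.t("N"))),
        FeatureDef("ppg mean", "mean of normalized pulse", "derived-index",
                   "mixed", (), lambda c: float(np.mean(c.beat.samples))),
        FeatureDef("ppg sd", "sd of normalized pulse", "derived-index", "mixed",
                   (), lambda c: float(np.std(c.beat.samples))),
        FeatureDef("ppg skew", "skewness of normalized pulse", "derived-index",
                   "mixed", (), lambda c: float(sstats.skew(c.beat.samples))),
        FeatureDef("ppg kurt", "kurtosis of normalized pulse", "derived-index",
                   "mixed", (), lambda c: float(sstats.kurtosis(c.beat.samples))),
        FeatureDef("vpg sd", "sd of VPG", "derived-index", "mixed", (),
                   lambda c: float(np.std(c.beat.vpg))),
        FeatureDef("apg sd", "sd of APG", "derived-index", "mixed", (),
                   lambda c: float(np.std(c.beat.apg))),
    ]
    return defs  # 9


def _deriv_at_ppg_points() -> list[FeatureDef]:
    defs = []
    for p in ("S", "N", "D"):
        defs.append(FeatureDef(
            f"Apg {p}", f"apg(t({p}))", "derived-index", _phase_of((p,)), (p,),
            lambda c, p=p: c.apg_at(p)))
    for p in ("N", "D"):
        defs.append(FeatureDef(
            f"Vpg {p}", f"vpg(t({p}))", "derived-index", _phase_of((p,)), (p,),
            lambda c, p=p: c.vpg_at(p)))
    return defs  # 5


def _phase_amp_features() -> list[FeatureDef]:
    defs = []
    for frac, label in ((0.25, "T/4"), (0.50, "T/2"), (0.75, "3T/4")):
        defs.append(FeatureDef(
            f"Am@{label}", f"ppg({label})", "amplitude", "mixed", (),
            lambda c, f=frac: c.amp_at_time(f * c.T)))
    return defs  # 3


def _vpg_apg_cross_ratios() -> list[FeatureDef]:
    defs = [
        FeatureDef("Vpg y/Vpg w", "vpg(y)/vpg(w)", "amplitude-ratio", "mixed",
                   ("y", "w"), lambda c: _q(c.vpg_at("y"), c.vpg_at("w"))),
        FeatureDef("Vpg z/Vpg w", "vpg(z)/vpg(w)", "amplitude-ratio", "mixed",
                   ("z", "w"), lambda c: _q(c.vpg_at("z"), c.vpg_at("w"))),
    ]
    for p in ("c", "d", "e"):
        defs.append(FeatureDef(
            f"{p}/b", f"apg({p})/apg(b)", "amplitude-ratio", _phase_of((p, "b")),
            (p, "b"), lambda c, p=p: _q(c.apg_at(p), c.apg_at("b"))))
    return defs  # 5


def _new_features() -> list[FeatureDef]:
    """17 engineered features; 13 reference the tangent-derived p1."""
    p1_defs = [
        FeatureDef("Tm p1", "t(p1)", "time", "early", ("p1",),
                   lambda c: c.t("p1"), is_new=True, uses_p1=True),
        FeatureDef("Am p1", "ppg(t(p1))", "amplitude", "early", ("p1",),
                   lambda c: c.amp("p1"), is_new=True, uses_p1=True),
        FeatureDef("Am b/Am p1", "ppg(b)/ppg(p1)", "amplitude-ratio", "early",
                   ("b", "p1"), lambda c: _q(c.amp("b"), c.amp("p1")),
                   is_new=True, uses_p1=True),
        FeatureDef("Am c/Am p1", "ppg(c)/ppg(p1)", "amplitude-ratio", "mixed",
                   ("c", "p1"), lambda c: _q(c.amp("c"), c.amp("p1")),
                   is_new=True, uses_p1=True),
        FeatureDef("Am a/Am p1", "ppg(a)/ppg(p1)", "amplitude-ratio", "early",
                   ("a", "p1"), lambda c: _q(c.amp("a"), c.amp("p1")),
                   is_new=True, uses_p1=True),
        FeatureDef("Am w/Am p1", "ppg(w)/ppg(p1)", "amplitude-ratio", "early",
                   ("w", "p1"), lambda c: _q(c.amp("w"), c.amp("p1")),
                   is_new=True, uses_p1=True),
        FeatureDef("Am y/Am p1", "ppg(y)/ppg(p1)", "amplitude-ratio", "mixed",
                   ("y", "p1"), lambda c: _q(c.amp("y"), c.amp("p1")),
                   is_new=True, uses_p1=True),
        FeatureDef("Am p1/Am S", "ppg(p1)/ppg(S)", "amplitude-ratio", "early",
                   ("p1", "S"), lambda c: _q(c.amp("p1"), c.amp("S")),
                   is_new=True, uses_p1=True),
        FeatureDef("Tm x/Tm ss", "t(x)/T", "time-ratio", "early", ("x",),
                   lambda c: _q(c.t("x"), c.T), is_new=True, uses_p1=True),
        FeatureDef("Tm wp1", "t(p1)-t(w)", "time", "early", ("w", "p1"),
                   lambda c: c.t("p1") - c.t("w"), is_new=True, uses_p1=True),
        FeatureDef("Tm xy", "t(y)-t(x)", "time", "mixed", ("x", "y"),
                   lambda c: c.t("y") - c.t("x"), is_new=True, uses_p1=True),
        FeatureDef("ms", "mean systolic upslope: ppg(p1)/t(p1)", "slope", "early",
                   ("p1",), lambda c: _q(c.amp("p1"), c.t("p1")),
                   is_new=True, uses_p1=True),
        FeatureDef("k v2", "spring-constant index at p1: -apg(p1)*T^2/ppg(p1)",
                   "derived-index", "early", ("p1",),
                   lambda c: _q(-c.apg_at("p1") * c.T**2, c.amp("p1")),
                   is_new=True, uses_p1=True),
    ]
    other = [
        FeatureDef("Tm SD", "t(D)-t(S)", "time", "mixed", ("S", "D"),
                   lambda c: c.t("D") - c.t("S"), is_new=True),
        FeatureDef("Tm ND", "t(D)-t(N)", "time", "late", ("N", "D"),
                   lambda c: c.t("D") - c.t("N"), is_new=True),
        FeatureDef("Tm SD/Tm ss", "(t(D)-t(S))/T", "time-ratio", "mixed",
                   ("S", "D"), lambda c: _q(c.t("D") - c.t("S"), c.T), is_new=True),
        FeatureDef("Tm ND/Tm ss", "(t(D)-t(N))/T", "time-ratio", "late",
                   ("N", "D"), lambda c: _q(c.t("D") - c.t("N"), c.T), is_new=True),
    ]
    return p1_defs + other


_REGISTRY_CACHE: dict[bool, tuple[FeatureDef, ...]] = {}


def registry(baseline_only: bool = False) -> tuple[FeatureDef, ...]:
    """The feature registry: 136 established definitions, plus 17 new ones
    (13 using p1) unless ``baseline_only``."""
    if baseline_only not in _REGISTRY_CACHE:
        baseline = (
            _pt_features() + _apg_ratio_features() + _amp_ratio_features()
            + _time_ratio_features() + _interval_features() + _width_features()
            + _area_features() + _slope_stat_features() + _deriv_at_ppg_points()
            + _phase_amp_features() + _vpg_apg_cross_ratios()
        )
        if len(baseline) != 136:
            raise RuntimeError(
                f"baseline registry has {len(baseline)} entries, expected 136"
            )
        names = [d.name for d in baseline]
        if len(set(names)) != len(names):
            dup = {n for n in names if names.count(n) > 1}
            raise RuntimeError(f"duplicate baseline feature names: {dup}")
        new = _new_features()
        if len(new) != 17 or sum(d.uses_p1 for d in new) != 13:
            raise RuntimeError("new feature block must be 17 entries, 13 using p1")
        _REGISTRY_CACHE[True] = tuple(baseline)
        _REGISTRY_CACHE[False] = tuple(baseline + new)
    return _REGISTRY_CACHE[baseline_only]


def manifest(baseline_only: bool = False) -> list[dict]:
    """Machine-readable registry manifest."""
    return [
        {
            "name": d.name,
            "formula": d.formula,
            "ftype": d.ftype,
            "phase": d.phase,
            "requires": list(d.requires),
            "is_new": d.is_new,
            "uses_p1": d.uses_p1,
        }
        for d in registry(baseline_only)
    ]


def extract(
    beat: AveragedBeat,
    fset: FiducialSet,
    hr: float,
    baseline_only: bool = False,
) -> dict[str, float]:
    """Evaluate every registered feature on one averaged beat.

    Returns a flat mapping including the HR-adjusted variant (``value / hr``,
    suffix " HR") of every base feature. Features whose required fiducials
    are absent are NaN.
    """
    if hr <= 0:
        raise ValueError("hr must be positive")
    ctx = EvalContext(beat, fset)
    out: dict[str, float] = {}
    for d in registry(baseline_only):
        if all(fset.has(p) for p in d.requires):
            try:
                val = float(d.fn(ctx))
            except (ValueError, ZeroDivisionError):
                val = math.nan
        else:
            val = math.nan
        out[d.name] = val
        out[f"{d.name} HR"] = val / hr
    return out


def pat_npat(
    r_times: np.ndarray,
    ppg_onsets: np.ndarray,
    height: float,
    max_lag_s: float = 0.6,
) -> tuple[float, float]:
    """Pulse arrival time and its height-normalized variant.

    PAT is the median over beats of (PPG onset - preceding R-wave) in ms;
    NPAT = PAT / height in ms/m. Onsets without a preceding R-wave within
    ``max_lag_s`` are unpaired; >20% unpaired emits a warning, no pairs at
    all is an error.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    r_times = np.asarray(r_times, dtype=float)
    onsets = np.asarray(ppg_onsets, dtype=float)
    lags = []
    unpaired = 0
    for onset in onsets:
        prior = r_times[r_times < onset]
        if prior.size and onset - prior[-1] <= max_lag_s:
            lags.append(onset - prior[-1])
        else:
            unpaired += 1
    if not lags:
        raise ValueError("no R-wave/onset pairs found")
    if onsets.size and unpaired / onsets.size > 0.2:
        warnings.warn(f"{unpaired}/{onsets.size} PPG onsets had no preceding R-wave")
    pat_ms = float(np.median(lags)) * 1000.0
    return pat_ms, pat_ms / height


def map_bp(sbp: float, dbp: float) -> float:
    """Mean arterial pressure: DBP + (SBP - DBP) / 3, mmHg."""
    if sbp <= dbp:
        raise ValueError(f"require sbp > dbp, got {sbp} <= {dbp}")
    return dbp + (sbp - dbp) / 3.0


def epwv(
    age: float,
    sbp: float,
    dbp: float,
    coef: dict | None = None,
    mbp_weight: float | None = None,
) -> float:
    """Estimated PWV (m/s) from age and brachial BP.

    Uses the published normal-population (no cardiovascular risk factors)
    equation with mean BP = DBP + 0.4 (SBP - DBP); the coefficients live in
    :mod:`ppgstiff.config` so they can be re-validated against their source
    without touching code.
    """
    if sbp <= dbp:
        raise ValueError(f"require sbp > dbp, got {sbp} <= {dbp}")
    if not (16 <= age <= 90):
        warnings.warn(f"age {age} outside the equation's validated range [16, 90]")
    coef = coef or _cfg.EPWV_COEF
    w = _cfg.EPWV_MBP_WEIGHT if mbp_weight is None else mbp_weight
    mbp = dbp + w * (sbp - dbp)
    return (
        coef["c0"]
        + coef["c_age"] * age
        + coef["c_age2"] * age**2
        + coef["c_age2_mbp"] * age**2 * mbp
        + coef["c_age_mbp"] * age * mbp
        + coef["c_mbp"] * mbp
    )
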
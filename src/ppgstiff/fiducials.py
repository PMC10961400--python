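"""Fiducial-point detection on the ensemble-averaged pulse.

Established landmarks follow the conventional PPG/VPG/APG vocabulary:
O (onset), S (systolic peak), N (dicrotic notch) and D (diastolic peak) on
the pulse itself; w (first maximum), y (first minimum after the systolic
complex) and z (subsequent maximum) on the velocity plethysmogram (VPG);
and the alternating a-f extrema on the acceleration plethysmogram (APG).

The first systolic peak ``p1`` is estimated with a tangent construction:
after the VPG maximum w the VPG falls along an initially linear downslope;
a straight line through that linear portion — anchored at the APG minimum b,
where the VPG slope is locally constant — crosses zero at the time of the
first (direct) systolic peak, even when the reflected wave has fused with it
and the pulse itself shows no distinct peak there. ``x`` shares the p1
timestamp and ``y`` is the first VPG local minimum after ``x``.

Landmarks that do not exist on a given morphology (e.g. no dicrotic notch on
a fully fused beat) are reported absent with a reason, never fabricated; all
dependent features then become missing values. Times are seconds from beat
onset (O.t = 0); equal-height extrema resolve to the earliest (determinism).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import config as _cfg
from .preprocess import AveragedBeat

PPG_POINTS = ("O", "S", "N", "D")
VPG_POINTS = ("w", "y", "z")
APG_POINTS = ("a", "b", "c", "d", "e", "f")
NEW_POINTS = ("p1", "x")
ALL_POINTS = PPG_POINTS + VPG_POINTS + APG_POINTS + NEW_POINTS


@dataclass(frozen=True)
class Fiducial:
    """One landmark: time (s from onset), normalized time, PPG amplitude."""

    t: float
    t_norm: float
    amp: float


@dataclass
class FiducialSet:
    """Named landmarks on one averaged beat, with absence reasons."""

    duration: float
    points: dict[str, Fiducial] = field(default_factory=dict)
    absent: dict[str, str] = field(default_factory=dict)

    def has(self, name: str) -> bool:
        return name in self.points

    def t(self, name: str) -> float:
        return self.points[name].t

    def amp(self, name: str) -> float:
        return self.points[name].amp

    def mark_absent(self, name: str, reason: str) -> None:
        self.absent[name] = reason

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            name: {"t_s": p.t, "t_norm": p.t_norm, "amp": p.amp}
            for name, p in self.points.items()
        }
        payload["_absent"] = dict(self.absent)
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _interp_amp(beat: AveragedBeat, t: float) -> float:
    return float(np.interp(t, beat.time, beat.samples))


def _first_peak(x: np.ndarray, start: int, stop: int, minimum: bool = False,
                prominence_frac: float = 1e-3) -> int | None:
    """Index of the first strict local extremum of ``x`` in [start, stop)."""
    if stop - start < 3:
        return None
    seg = -x[start:stop] if minimum else x[start:stop]
    prom = prominence_frac * np.ptp(x) if np.ptp(x) > 0 else None
    peaks, _ = sps.find_peaks(seg, prominence=prom)
    return int(start + peaks[0]) if peaks.size else None


def _refine(x: np.ndarray, idx: int) -> float:
    """Sub-sample extremum location by a parabola through three samples.

    Continuous landmark times keep amplitude ratios free of sample-grid
    staircase artefacts.
    """
    if idx <= 0 or idx >= len(x) - 1:
        return float(idx)
    denom = x[idx - 1] - 2 * x[idx] + x[idx + 1]
    if denom == 0:
        return float(idx)
    shift = 0.5 * (x[idx - 1] - x[idx + 1]) / denom
    return float(idx) + float(np.clip(shift, -0.5, 0.5))


def detect_established(beat: AveragedBeat, cfg: dict | None = None) -> FiducialSet:
    """Locate O, S, N, D, w, y, z and the APG a-f sequence.

    S is the global pulse maximum, O the first sample. The APG landmarks are
    detected sequentially as alternating extrema after onset (a max, b min,
    c max, d min, e max, f min); any missing extremum is marked absent. The
    notch N is the first strict pulse local minimum after S (located via the
    derivative's upward zero-crossing), cross-checkable against the APG
    e-wave neighbourhood; D is the first pulse local maximum after N.
    """
    ppg, vpg, apg = beat.samples, beat.vpg, beat.apg
    L = beat.length
    dt = beat.duration / L
    fs = FiducialSet(duration=beat.duration)

    def add(name: str, idx: int, series: np.ndarray | None = None) -> None:
        frac = _refine(series, idx) if series is not None else float(idx)
        t = frac * dt
        fs.points[name] = Fiducial(t, t / beat.duration, _interp_amp(beat, t))

    add("O", 0)
    i_s = int(np.argmax(ppg))
    add("S", i_s, ppg)

    # w: first VPG local maximum on the systolic upslope
    i_w = _first_peak(vpg, 1, max(i_s + 2, 3), prominence_frac=0.02)
    if i_w is None:
        i_w = int(np.argmax(vpg[: max(i_s + 1, 2)]))
        if vpg[i_w] <= 0:
            fs.mark_absent("w", "no rising VPG segment")
            i_w = None
    if i_w is not None:
        add("w", i_w, vpg)

    # APG alternating sequence
    cursor = 1
    prev = None
    for name, minimum in zip(APG_POINTS, (False, True, False, True, False, True)):
        idx = _first_peak(apg, cursor, L, minimum=minimum)
        if idx is None:
            fs.mark_absent(name, "no such APG extremum")
            break
        if prev is not None and idx <= prev:
            fs.mark_absent(name, "APG ordering violated")
            break
        add(name, idx, apg)
        prev = idx
        cursor = idx + 1

    # N: first strict PPG local minimum after S; D: first local max after N
    i_n = _first_peak(ppg, i_s + 1, L, minimum=True)
    if i_n is None:
        fs.mark_absent("N", "no pulse local minimum after S (fused beat)")
        fs.mark_absent("D", "requires N")
    else:
        add("N", i_n, ppg)
        i_d = _first_peak(ppg, i_n + 1, L)
        if i_d is None:
            fs.mark_absent("D", "no pulse local maximum after N")
        else:
            add("D", i_d, ppg)

    # VPG y/z relative to w (refined after p1 by detect_y)
    if i_w is not None:
        i_y = _first_peak(vpg, i_w + 1, L, minimum=True)
        if i_y is None:
            fs.mark_absent("y", "no VPG local minimum after w")
        else:
            add("y", i_y, vpg)
            i_z = _first_peak(vpg, i_y + 1, L)
            if i_z is None:
                fs.mark_absent("z", "no VPG local maximum after y")
            else:
                add("z", i_z, vpg)
    else:
        fs.mark_absent("y", "requires w")
        fs.mark_absent("z", "requires w")
    return fs


def detect_p1_tangent(
    beat: AveragedBeat, fset: FiducialSet, cfg: dict | None = None
) -> FiducialSet:
    """Estimate the first systolic peak p1 (and x) by the tangent method.

    A straight line is fitted to the initial linear portion of the VPG
    downslope after w — by default the tangent at the APG minimum b, where
    the VPG slope is locally constant; the ``ls-fallback`` variant fits a
    least-squares line over the maximal contiguous span around b where the
    APG stays within a tolerance band of APG(b). The line's zero crossing is
    the p1 timestamp; its amplitude is the pulse value there.
    """
    cfg = cfg or _cfg.default_config()
    method = cfg["p1"]["method"]
    band_tol = cfg["p1"]["band_tol"]
    vpg, apg = beat.vpg, beat.apg
    dt = beat.duration / beat.length

    if not fset.has("w"):
        fset.mark_absent("p1", "requires w")
        fset.mark_absent("x", "requires p1")
        return fset
    i_w = int(round(fset.t("w") / dt))
    if not np.any(vpg[i_w:] < 0):
        fset.mark_absent("p1", "no VPG downslope after w")
        fset.mark_absent("x", "requires p1")
        return fset

    # anchor: first APG minimum after w (= landmark b)
    i_b = _first_peak(apg, i_w + 1, beat.length, minimum=True)
    if i_b is None or apg[i_b] >= 0:
        fset.mark_absent("p1", "no APG minimum after w")
        fset.mark_absent("x", "requires p1")
        return fset
    t_b_frac = _refine(apg, i_b) * dt
    vpg_b = float(np.interp(t_b_frac, beat.time, vpg))
    apg_b = float(np.interp(t_b_frac, beat.time, apg))

    if method == "ls-fallback":
        inside = np.abs(apg - apg[i_b]) <= band_tol * abs(apg[i_b])
        lo = i_b
        while lo - 1 > i_w and inside[lo - 1]:
            lo -= 1
        hi = i_b
        while hi + 1 < beat.length and inside[hi + 1]:
            hi += 1
        idx = np.arange(lo, hi + 1)
        slope, intercept = np.polyfit(idx * dt, vpg[idx], 1)
        if slope >= 0:
            fset.mark_absent("p1", "tangent slope not negative")
            fset.mark_absent("x", "requires p1")
            return fset
        t_star = -intercept / slope
    else:  # tangent-at-b
        t_star = t_b_frac - vpg_b / apg_b

    if not (fset.t("w") <= t_star <= beat.duration):
        fset.mark_absent("p1", "tangent zero-crossing outside beat")
        fset.mark_absent("x", "requires p1")
        return fset
    point = Fiducial(float(t_star), float(t_star) / beat.duration,
                     _interp_amp(beat, float(t_star)))
    fset.points["p1"] = point
    fset.points["x"] = point
    return fset


def detect_y(beat: AveragedBeat, fset: FiducialSet) -> FiducialSet:
    """y: first strict VPG local minimum after x; absent when the VPG is
    monotone to the end of the beat."""
    if not fset.has("x"):
        return fset
    dt = beat.duration / beat.length
    i_x = int(np.ceil(fset.t("x") / dt))
    i_y = _first_peak(beat.vpg, i_x + 1, beat.length, minimum=True)
    fset.points.pop("y", None)
    fset.absent.pop("y", None)
    if i_y is None:
        fset.mark_absent("y", "no VPG local minimum after x")
        return fset
    t = i_y * dt
    fset.points["y"] = Fiducial(t, t / beat.duration, _interp_amp(beat, t))
    return fset


def detect_all(beat: AveragedBeat, cfg: dict | None = None) -> FiducialSet:
    """Established landmarks plus the tangent-based p1/x and the refined y."""
    fset = detect_established(beat, cfg)
    fset = detect_p1_tangent(beat, fset, cfg)
    fset = detect_y(beat, fset)
    return fset
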
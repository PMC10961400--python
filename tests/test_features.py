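import math

import numpy as np
import pytest

from ppgstiff import features as ft
from ppgstiff.experiments import beat_from_template, template_features
from ppgstiff.fiducials import ALL_POINTS, Fiducial, FiducialSet, detect_all
from ppgstiff.preprocess import AveragedBeat
from ppgstiff.synth_pulse import VALID_CLASSES, make_beat_template


class TestRegistry:
    def test_baseline_has_136_definitions(self):
        assert len(ft.registry(baseline_only=True)) == 136

    def test_updated_adds_17_of_which_13_use_p1(self):
        base = {d.name for d in ft.registry(baseline_only=True)}
        updated = ft.registry()
        new = [d for d in updated if d.name not in base]
        assert len(new) == 17
        assert sum(d.uses_p1 for d in new) == 13
        assert all(d.is_new for d in new)

    def test_requires_resolve_against_fiducial_vocabulary(self):
        for d in ft.registry():
            assert set(d.requires) <= set(ALL_POINTS), d.name

    def test_named_definitions_present(self):
        names = {d.name for d in ft.registry()}
        for expected in ("b/a", "(b-e)/a", "(b-c-d-e)/a", "Am b/Am S",
                         "Am b/Am p1", "Am c/Am p1", "Tm x/Tm ss",
                         "Tm SD/Tm ss", "Tm ND", "ms", "k v2"):
            assert expected in names

    def test_manifest_is_machine_readable(self):
        man = ft.manifest()
        assert len(man) == 153
        assert all({"name", "formula", "ftype", "phase", "uses_p1"} <= set(m) for m in man)


class TestExtraction:
    def test_amplitude_ratio_is_direct_quotient(self, class1_beat):
        _, beat = class1_beat
        fset = detect_all(beat)
        # overwrite amplitudes with the documented worked example
        fset.points["b"] = Fiducial(fset.t("b"), fset.points["b"].t_norm, 0.6)
        fset.points["p1"] = Fiducial(fset.t("p1"), fset.points["p1"].t_norm, 0.78)
        row = ft.extract(beat, fset, hr=60)
        assert row["Am b/Am p1"] == pytest.approx(0.769, abs=1e-3)

    def test_b_over_a_uses_apg_values(self, class1_beat):
        _, beat = class1_beat
        fset = detect_all(beat)
        row = ft.extract(beat, fset, hr=60)
        ctx = ft.EvalContext(beat, fset)
        assert row["b/a"] == pytest.approx(ctx.apg_at("b") / ctx.apg_at("a"))
        assert row["b/a"] < 0  # deceleration over acceleration

    def test_absent_notch_leaves_dependent_features_missing(self, gaussian_beat):
        _, beat = gaussian_beat
        fset = detect_all(beat)
        assert not fset.has("N")
        row = ft.extract(beat, fset, hr=60)
        assert math.isnan(row["Tm N"])
        assert math.isnan(row["A2/A1"])
        assert not math.isnan(row["Tm S"])

    def test_hr_variant_appended_for_every_feature(self, class1_beat):
        _, beat = class1_beat
        fset = detect_all(beat)
        row = ft.extract(beat, fset, hr=72)
        base = [k for k in row if not k.endswith(" HR")]
        for name in base:
            assert f"{name} HR" in row
            if not math.isnan(row[name]):
                assert row[f"{name} HR"] == pytest.approx(row[name] / 72)

    def test_nonpositive_hr_rejected(self, class1_beat):
        _, beat = class1_beat
        with pytest.raises(ValueError):
            ft.extract(beat, detect_all(beat), hr=0)

    def test_amplitude_ratios_scale_invariant(self):
        raw = beat_from_template(make_beat_template("2", 7.0), 800).samples
        rows = []
        for k in (1.0, 37.5):
            beat = AveragedBeat.from_samples(k * raw, 1.0)
            rows.append(ft.extract(beat, detect_all(beat), hr=60))
        for d in ft.registry():
            if d.ftype == "amplitude-ratio" and not math.isnan(rows[0][d.name]):
                assert rows[0][d.name] == pytest.approx(rows[1][d.name], rel=1e-9)

    def test_time_features_scale_with_duration_and_ratios_do_not(self):
        raw = beat_from_template(make_beat_template("2", 7.0), 800).samples
        b1 = AveragedBeat.from_samples(raw, 1.0)
        b2 = AveragedBeat.from_samples(raw, 1.3)
        r1 = ft.extract(b1, detect_all(b1), hr=60)
        r2 = ft.extract(b2, detect_all(b2), hr=60)
        for d in ft.registry():
            v1, v2 = r1[d.name], r2[d.name]
            if math.isnan(v1) or abs(v1) < 1e-12:
                continue
            if d.ftype == "time":
                assert v2 == pytest.approx(1.3 * v1, rel=1e-6), d.name
            elif d.ftype == "time-ratio":
                assert v2 == pytest.approx(v1, rel=1e-6), d.name


class TestAmBp1StiffnessLink:
    @pytest.mark.parametrize("label", VALID_CLASSES)
    def test_ratio_decreases_monotonically_with_stiffness(self, label):
        grid = np.linspace(4.1, 11.9, 20)
        vals = [template_features(label, s)["Am b/Am p1"] for s in grid]
        assert np.all(np.diff(vals) < 0)


class TestPatNpat:
    def test_worked_example(self):
        r = np.array([0.0, 1.0, 2.0])
        onsets = r + 0.206
        pat, npat = ft.pat_npat(r, onsets, height=1.76)
        assert pat == pytest.approx(206.0)
        assert npat == pytest.approx(117.0, abs=0.1)

    def test_median_of_identical_beats(self):
        r = np.arange(10.0)
        pat, _ = ft.pat_npat(r, r + 0.25, height=1.8)
        assert pat == pytest.approx(250.0)

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError):
            ft.pat_npat(np.array([0.0]), np.array([0.2]), height=0.0)

    def test_no_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="no R-wave"):
            ft.pat_npat(np.array([5.0]), np.array([0.2]), height=1.7)

    def test_mostly_unpaired_warns(self):
        r = np.array([0.0])
        onsets = np.array([0.2, 3.0, 4.0, 5.0, 6.0])
        with pytest.warns(UserWarning, match="no preceding"):
            ft.pat_npat(r, onsets, height=1.7)


class TestClinicalFormulas:
    def test_map_cohort_example(self):
        assert ft.map_bp(119, 71) == pytest.approx(87.0)

    def test_map_direct_evaluation(self):
        assert ft.map_bp(120, 80) == pytest.approx(93.333, abs=1e-3)

    def test_map_degenerate_inputs(self):
        with pytest.raises(ValueError):
            ft.map_bp(80, 80)
        assert ft.map_bp(83, 80) == pytest.approx(81.0)

    def test_epwv_increasing_in_age_at_fixed_bp(self):
        # the published equation is quadratic in age with a shallow vertex in
        # the mid-20s; it rises strictly from age 30 up
        ages = np.linspace(30, 70, 21)
        vals = [ft.epwv(a, 119, 71) for a in ages]
        assert np.all(np.diff(vals) > 0)

    def test_epwv_deterministic_and_plausible(self):
        v1 = ft.epwv(44, 119, 71)
        assert v1 == ft.epwv(44, 119, 71)
        assert 5.0 < v1 < 9.0  # near the cohort's measured aortic PWV range

    def test_epwv_out_of_range_age_warns_but_computes(self):
        with pytest.warns(UserWarning, match="age"):
            v = ft.epwv(95, 119, 71)
        assert np.isfinite(v)
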
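import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgstiff import cohort_stats as cs


class TestAverageVisits:
    def setup_method(self):
        idx = ["S1", "S2"]
        self.v1 = pd.DataFrame({"f": [10.0, np.nan]}, index=idx)
        self.v2 = pd.DataFrame({"f": [12.0, np.nan]}, index=idx)

    def test_cellwise_mean(self):
        out = cs.average_visits(self.v1, self.v2)
        assert out.loc["S1", "f"] == 11.0

    def test_single_visit_value_passes_through(self):
        v2 = self.v2.copy()
        v2.loc["S2", "f"] = 10.0
        out = cs.average_visits(self.v1, v2)
        assert out.loc["S2", "f"] == 10.0

    def test_both_missing_stays_missing(self):
        out = cs.average_visits(self.v1, self.v2)
        assert math.isnan(out.loc["S2", "f"])

    def test_subject_in_one_panel_excluded_with_warning(self):
        v2 = self.v2.drop(index="S2")
        with pytest.warns(UserWarning, match="S2"):
            out = cs.average_visits(self.v1, v2)
        assert list(out.index) == ["S1"]


class TestCV:
    def test_constant_values_give_zero(self):
        assert cs.cv(np.array([10.0, 10.0, 10.0])) == 0.0

    def test_worked_example(self):
        assert cs.cv(np.array([8.0, 12.0])) == pytest.approx(28.28, abs=0.01)

    def test_sign_follows_mean(self):
        vals = np.array([8.0, 12.0])
        assert cs.cv(-vals) == -cs.cv(vals)

    def test_zero_mean_undefined(self):
        assert math.isnan(cs.cv(np.array([-1.0, 1.0])))

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            cs.cv(np.array([1.0]))


class TestWSCV:
    def test_identical_visits_give_exact_zero(self):
        pairs = np.column_stack([np.arange(5.0) + 1, np.arange(5.0) + 1])
        assert cs.wscv(pairs) == 0.0

    def test_worked_example(self):
        pairs = np.array([[10.0, 12.0], [20.0, 18.0]])
        # within-SD = sqrt(8/4) = 1.414, grand mean 15 -> 9.43
        assert cs.wscv(pairs) == pytest.approx(9.43, abs=0.01)

    def test_shift_toward_infinity_shrinks_wscv(self):
        pairs = np.array([[10.0, 12.0], [20.0, 18.0]])
        values = [cs.wscv(pairs + c) for c in (0.0, 100.0, 10000.0)]
        assert values[0] > values[1] > values[2]
        assert values[2] < 0.05

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 30)
        pairs = rng.normal(50, 10, size=(n, 2))
        d2 = sum((a - b) ** 2 for a, b in pairs)
        expected = 100.0 * math.sqrt(d2 / (2 * n)) / (pairs.sum() / (2 * n))
        assert cs.wscv(pairs) == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_subject_relabeling_and_visit_swap(self):
        rng = np.random.default_rng(3)
        pairs = rng.normal(20, 4, size=(8, 2))
        base = cs.wscv(pairs)
        assert cs.wscv(pairs[::-1]) == pytest.approx(base, abs=1e-12)
        swapped = pairs.copy()
        swapped[[1, 4]] = swapped[[1, 4]][:, ::-1]
        assert cs.wscv(swapped) == pytest.approx(base, abs=1e-12)


class TestFilterFeatures:
    def _panel(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "const": np.ones(12),
                "good": rng.normal(10, 1, 12),
                "noisy": rng.normal(10, 1, 12),
            },
            index=[f"S{i}" for i in range(12)],
        )

    def _report(self, wscv_noisy):
        return pd.DataFrame({"wscv": {"const": 0.0, "good": 19.0, "noisy": wscv_noisy}})

    def test_constant_column_dropped_for_zero_variance(self):
        filtered, _, audit = cs.filter_features(self._panel(), self._report(5.0))
        assert "const" not in filtered.columns
        reasons = {a["feature"]: a["reason"] for a in audit if a["action"] == "drop"}
        assert reasons["const"] == "zero variance"

    def test_wscv_threshold_is_strict(self):
        filtered, _, _ = cs.filter_features(self._panel(), self._report(25.0))
        assert "noisy" not in filtered.columns and "good" in filtered.columns
        filtered, _, _ = cs.filter_features(self._panel(), self._report(19.0))
        assert "noisy" in filtered.columns

    def test_extreme_outlier_flagged_not_dropped(self):
        panel = self._panel()
        vals = np.concatenate([np.tile([0.0, 1.0], 5), [0.5, 4.1]])  # Q1=0, Q3=1
        panel["spiky"] = vals
        report = pd.DataFrame({"wscv": {c: 5.0 for c in panel.columns}})
        filtered, flags, audit = cs.filter_features(panel, report)
        assert "spiky" in filtered.columns
        assert flags["spiky"].sum() == 1
        assert any(a["feature"] == "spiky" and a["action"] == "flag" for a in audit)

    def test_audit_and_survivors_partition_columns(self):
        panel = self._panel()
        filtered, _, audit = cs.filter_features(panel, self._report(25.0))
        dropped = {a["feature"] for a in audit if a["action"] == "drop"}
        assert dropped | set(filtered.columns) == set(panel.columns)
        assert dropped.isdisjoint(filtered.columns)


class TestCenterScale:
    def test_columns_standardized(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.normal(5, 3, size=(30, 4)), columns=list("abcd"))
        scaled, _ = cs.center_scale(panel)
        assert np.allclose(scaled.mean(), 0.0, atol=1e-12)
        assert np.allclose(scaled.std(ddof=0), 1.0, atol=1e-12)

    def test_zero_sd_column_is_an_error(self):
        panel = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-sd"):
            cs.center_scale(panel)

    def test_test_data_transformed_with_train_params(self):
        rng = np.random.default_rng(2)
        train = pd.DataFrame({"a": rng.normal(0, 1, 20)})
        test = pd.DataFrame({"a": rng.normal(5, 1, 10)})
        _, scaler = cs.center_scale(train)
        out1 = scaler.transform(test)
        out2 = scaler.transform(test)
        assert out1.equals(out2)
        assert abs(out1["a"].mean()) > 1  # train stats, not re-centered


class TestBlandAltman:
    def test_identity_agreement(self):
        x = np.arange(10.0)
        rep = cs.bland_altman(x, x)
        assert rep.bias == 0 and rep.loa_low == 0 and rep.loa_high == 0
        assert rep.rmse == 0 and rep.r2 == 1.0

    def test_constant_offset(self):
        x = np.arange(10.0)
        rep = cs.bland_altman(x, x + 1)
        assert rep.bias == pytest.approx(1.0)
        assert rep.loa_low == pytest.approx(1.0)
        assert rep.loa_high == pytest.approx(1.0)

    def test_loa_width_matches_error_sd(self):
        rng = np.random.default_rng(5)
        sigma = 0.7
        x = rng.normal(7, 1, 10_000)
        y = x + rng.normal(0, sigma, 10_000)
        rep = cs.bland_altman(x, y)
        assert rep.loa_high - rep.loa_low == pytest.approx(2 * 1.96 * sigma, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cs.bland_altman(np.zeros(5), np.zeros(6))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert cs.pearson(x, 2 * x)[0] == pytest.approx(1.0)
        assert cs.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged_undefined(self):
        r, p = cs.pearson(np.ones(5), np.arange(5.0))
        assert math.isnan(r) and math.isnan(p)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(size=50), rng.normal(size=50)
            _, p = cs.pearson(x, y)
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07
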
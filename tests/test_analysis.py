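"""Unit transforms, outlier rule, Bland-Altman agreement, composites."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partkit.analysis import (
    bland_altman,
    composite_scores,
    eq1_convert,
    loa_plot_data,
    notch_separation,
    reject_outliers,
    test_retest_report,
    to_analysis_units,
)


class TestEq1Convert:
    @pytest.mark.parametrize(
        "m, expected",
        [(0.95, -19.26), (1.52, -15.23), (1.49, -15.40)],
    )
    def test_printed_depth_conversions(self, m, expected):
        assert eq1_convert(m) == pytest.approx(expected, abs=0.005)

    def test_matches_independent_formulation_to_1e9(self):
        """The dB-ratio formula equals 20*log10(tanh(m*ln10/20)) exactly;
        the two routes agree to 1e-9 across the adaptive range."""
        m = np.linspace(0.2, 40.0, 10_001)
        via_tanh = 20.0 * np.log10(np.tanh(m * np.log(10.0) / 20.0))
        assert np.max(np.abs(eq1_convert(m) - via_tanh)) < 1e-9

    def test_strictly_increasing_and_negative(self):
        m = np.linspace(0.2, 40.0, 1001)
        out = eq1_convert(m)
        assert np.all(np.diff(out) > 0)
        assert np.all(out < 0)

    def test_asymptotes(self):
        assert eq1_convert(1e-6) < -100.0
        assert eq1_convert(1e3) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            eq1_convert(0.0)

    def test_jensen_gap_converted_mean_exceeds_mean_converted(self):
        """eq1 is concave for m > 0, so converting the cohort mean gives a
        higher (less negative) value than averaging converted thresholds."""
        rng = np.random.default_rng(0)
        depths = np.clip(rng.normal(0.95, 0.5, 500), 0.2, 40.0)
        assert eq1_convert(depths.mean()) >= eq1_convert(depths).mean()


class TestToAnalysisUnits:
    def test_transforms(self):
        data = pd.DataFrame(
            {
                "assessment": ["gap", "no_notch", "srm_colocated", "tm"],
                "value": [4.0, 56.85, 2.5, 1.5],
            }
        )
        out = to_analysis_units(data)
        assert out["analysis_value"].tolist() == pytest.approx(
            [2.0, -11.85, 2.5, 1.5]
        )
        assert out["analysis_units"].tolist() == [
            "log2 (ms)", "TMR (dB)", "TMR (dB)", "M (dB)"
        ]

    def test_nonpositive_log_flagged_not_dropped(self):
        data = pd.DataFrame({"assessment": ["gap"], "value": [0.0]})
        out = to_analysis_units(data)
        assert len(out) == 1
        assert out["excluded"].iloc[0] != ""
        assert np.isnan(out["analysis_value"].iloc[0])


class TestRejectOutliers:
    def test_single_large_deviant_excluded(self):
        values = np.zeros(100)
        values[-1] = 9.9  # sample SD ~1.0, deviation ~9.8 SD
        mask = reject_outliers(values)
        assert mask[:-1].all() and not mask[-1]

    def test_all_equal_none_excluded(self):
        assert reject_outliers(np.full(10, 3.3)).all()

    def test_value_at_exactly_three_sd_included(self):
        # construct a sample where one point sits at exactly 3 sample SDs
        values = np.array([-1.0, 1.0] * 10 + [0.0])
        sd = values.std(ddof=1)
        values2 = np.concatenate([values, [values.mean() + 3 * sd]])
        # recompute: the appended point shifts mean/SD, so check the rule
        mask = reject_outliers(values2)
        deviations = np.abs(values2 - values2.mean()) / values2.std(ddof=1)
        assert np.array_equal(mask, deviations <= 3.0)

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            reject_outliers(np.array([1.0, 2.0]))


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0
        assert (res.loa_low, res.loa_high) == (0.0, 0.0)
        assert res.d == 0.0
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_loa(self):
        res = bland_altman([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])
        diffs = np.array([1.0, -1.0, 0.0])
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(diffs.std(ddof=1))
        assert res.loa_high == pytest.approx(1.96 * diffs.std(ddof=1))
        assert res.loa_low == pytest.approx(-1.96 * diffs.std(ddof=1))

    def test_two_pair_example_from_hand_computation(self):
        # n=2 pairs: diffs [1, -1], sample SD sqrt(2), LoA +/- 2.77
        with pytest.raises(ValueError):
            bland_altman([0.0, 2.0], [1.0, 1.0])

    def test_pure_shift(self):
        s1 = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(s1, s1 + 0.7)
        assert res.bias == pytest.approx(0.7)
        assert res.loa_low == pytest.approx(0.7)
        assert res.loa_high == pytest.approx(0.7)
        assert res.r == pytest.approx(1.0)

    def test_df_is_pairs_minus_one(self):
        res = bland_altman(np.arange(12.0), np.arange(12.0) + 1)
        assert res.df == 11

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        s1 = rng.normal(0, 1, 20)
        s2 = s1 + rng.normal(0.2, 0.5, 20)
        fwd, rev = bland_altman(s1, s2), bland_altman(s2, s1)
        assert fwd.bias == pytest.approx(-rev.bias)
        assert fwd.loa_high - fwd.loa_low == pytest.approx(
            rev.loa_high - rev.loa_low
        )
        assert fwd.r == pytest.approx(rev.r)


class TestComposite:
    def test_subject_at_column_means_scores_zero(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        data.iloc[0] = data.iloc[1:].mean()  # then recenter subject 0 exactly
        data.iloc[0] = data.mean()
        # one fixed-point iteration is enough at this tolerance
        res = composite_scores(data)
        assert abs(res.composite.iloc[0]) < 0.05

    def test_z_columns_standardized(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(rng.normal(3, 2, (50, 4)))
        res = composite_scores(data)
        assert np.allclose(res.z_matrix.mean(), 0.0, atol=1e-12)
        assert np.allclose(res.z_matrix.std(ddof=1), 1.0, atol=1e-12)

    def test_perfectly_correlated_columns_give_alpha_one(self):
        base = pd.Series(np.linspace(0, 1, 30))
        data = pd.DataFrame({"a": base, "b": 2 * base + 1})
        res = composite_scores(data)
        assert res.cronbach_alpha == pytest.approx(1.0, abs=1e-9)

    def test_alpha_matches_standardized_closed_form(self):
        """Covariance alpha on z-scores equals k*rbar / (1 + (k-1)*rbar)."""
        rng = np.random.default_rng(3)
        k, n, rho = 10, 400, 0.23
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        data = pd.DataFrame(rng.multivariate_normal(np.zeros(k), cov, size=n))
        res = composite_scores(data)
        corr = data.corr().to_numpy()
        rbar = corr[np.triu_indices(k, 1)].mean()
        closed_form = k * rbar / (1 + (k - 1) * rbar)
        assert res.cronbach_alpha == pytest.approx(closed_form, abs=1e-9)

    def test_zero_variance_column_named_in_error(self):
        data = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            composite_scores(data)


class TestReport:
    @staticmethod
    def small_dataset(n=30, seed=4):
        rng = np.random.default_rng(seed)
        rows = []
        for name, mean in (("gap", 1.3), ("tm", 1.5), ("srm_colocated", 2.0)):
            base = rng.normal(mean, 1.0, n)
            for session in (1, 2):
                vals = base + rng.normal(0, 0.5, n) - 0.1 * (session == 2)
                for i in range(n):
                    rows.append(
                        {
                            "subject": f"S{i}",
                            "session": session,
                            "assessment": name,
                            "analysis_value": vals[i],
                        }
                    )
        return pd.DataFrame(rows)

    def test_table_structure(self):
        report = test_retest_report(self.small_dataset())
        table = report["table"]
        assert list(table.columns) == [
            "bias", "loa_low", "loa_high", "units", "r", "r_p", "t", "t_p",
            "cohens_d", "df",
        ]
        # one row per assessment plus the composite row
        assert len(table) == 4
        assert "composite" in table.index
        assert (table["df"] == 29).all()

    def test_plot_data_mean_vs_difference(self):
        report = test_retest_report(self.small_dataset())
        pd_gap = report["plot_data"]["gap"]
        assert list(pd_gap.columns) == ["mean", "diff"]
        assert len(pd_gap) == 30

    def test_injected_shift_recovered_in_bias(self):
        rng = np.random.default_rng(5)
        rows = []
        base = rng.normal(0, 1.0, 200)
        for session in (1, 2):
            vals = base + rng.normal(0, 0.4, 200) + (-0.5 if session == 2 else 0)
            rows += [
                {"subject": f"S{i}", "session": session, "assessment": "tm",
                 "analysis_value": vals[i]}
                for i in range(200)
            ]
        report = test_retest_report(pd.DataFrame(rows))
        bias = report["table"].loc["tm", "bias"]
        se = report["table"].loc["tm"].pipe(lambda r: 0.4 * np.sqrt(2) / np.sqrt(200))
        assert bias == pytest.approx(-0.5, abs=4 * se)

    def test_subject_with_single_session_dropped_and_logged(self):
        data = self.small_dataset()
        data = data[~((data.subject == "S0") & (data.session == 2))]
        report = test_retest_report(data)
        assert any(entry.endswith(":S0") for entry in report["dropped"])
        assert report["table"].loc["gap", "df"] == 28


def test_notch_separation_is_absolute_distance():
    assert notch_separation(-11.85, -32.06) == pytest.approx(20.21)
    assert notch_separation(-32.06, -11.85) == pytest.approx(20.21)


def test_loa_plot_data_columns():
    out = loa_plot_data([1.0, 2.0], [2.0, 1.0])
    assert out["mean"].tolist() == [1.5, 1.5]
    assert out["diff"].tolist() == [1.0, -1.0]
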
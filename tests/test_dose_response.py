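import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import t_tail_two_sided
from lipiddose.dose_response import (
    STUDY_DOSES,
    compare_groups,
    fit_trend,
    flag_biomarker,
    group_stats,
    screen_table,
    slope_p_value,
    successive_change,
)
from lipiddose.synthetic_data import TrendSpec, simulate_concentrations


class TestGroupStats:
    def test_mean_sd_n(self):
        stats = group_stats(
            per_sample={"a": 1.0, "b": 2.0, "c": 3.0, "d": 5.0, "e": 5.0},
            groups={"a": "g1", "b": "g1", "c": "g1", "d": "g2", "e": "g2"},
            doses={"g1": 3.6, "g2": 6.3},
        )
        assert stats[0].mean == 2.0 and stats[0].sd == 1.0 and stats[0].n == 3
        assert stats[1].mean == 5.0 and stats[1].sd == 0.0

    def test_singleton_group_warns(self):
        with pytest.warns(UserWarning, match="n=1"):
            stats = group_stats({"a": 1.0}, {"a": "g1"}, {"g1": 3.6})
        assert stats[0].sd == 0.0


class TestFitTrend:
    def test_ceramide_row_reproduces_printed_fit(self):
        """A decreasing odd-chain ceramide's printed trendline and R²."""
        fit = fit_trend(STUDY_DOSES, [2.29, 1.68, 1.48, 1.27])
        assert fit.slope == pytest.approx(-0.121, abs=5e-4)
        assert fit.intercept == pytest.approx(2.6, abs=5e-3)
        assert round(fit.r2, 2) == 0.92
        assert fit.df == 2
        assert fit.p_value == pytest.approx(0.0430, abs=5e-5)

    def test_degenerate_all_equal_means(self):
        fit = fit_trend(STUDY_DOSES, [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.r2 == 0.0 and fit.p_value == 1.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_trend([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            fit_trend([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_r2_equals_squared_pearson(self, table1, doses):
        mean_cols = [f"mean{i}" for i in range(1, 5)]
        complete = table1[mean_cols].dropna()
        for _lipid, row in complete.iloc[::7].iterrows():
            y = row.to_numpy(dtype=float)
            if np.ptp(y) == 0:
                continue
            fit = fit_trend(doses, y)
            r = np.corrcoef(doses, y)[0, 1]
            assert abs(fit.r2 - r**2) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        c=st.floats(1e-3, 1e6),
        y=st.lists(st.floats(0.1, 1e4), min_size=4, max_size=4),
    )
    def test_scale_invariance(self, c, y):
        """Rescaling all means by c > 0 preserves r2, t, p and direction;
        the slope scales by c."""
        if np.ptp(y) == 0:
            return
        f1 = fit_trend(STUDY_DOSES, y)
        f2 = fit_trend(STUDY_DOSES, [c * v for v in y])
        assert f2.slope == pytest.approx(c * f1.slope, rel=1e-9)
        assert f2.r2 == pytest.approx(f1.r2, rel=1e-9, abs=1e-12)
        assert f2.p_value == pytest.approx(f1.p_value, rel=1e-9, abs=1e-12)
        assert successive_change(y) == successive_change([c * v for v in y])


class TestSlopePValue:
    def test_figure_caption_values(self):
        """Slope ± SE pairs for the odd/even-chain totals reproduce the printed
        significance levels (df = 2)."""
        assert float(f"{slope_p_value(0.183, 0.0962, 2):.3g}") == 0.197
        # even-chain and combined totals: printed 0.0189 / 0.0195 arise from
        # unrounded slope/SE; recomputation from the printed pairs agrees to 1%
        assert slope_p_value(-41.0, 5.71, 2) == pytest.approx(0.0189, rel=0.01)
        assert slope_p_value(-40.8, 5.79, 2) == pytest.approx(0.0195, rel=0.01)
        assert slope_p_value(0.0604, 0.00203, 2) == pytest.approx(0.0011, rel=0.03)

    def test_zero_slope_gives_one(self):
        assert slope_p_value(0.0, 1.0, 2) == 1.0

    @pytest.mark.parametrize("df", range(1, 11))
    @pytest.mark.parametrize("t", [0.5, 1.902, 4.666, 7.18])
    def test_matches_numerical_integration_oracle(self, df, t):
        oracle = t_tail_two_sided(t, df)
        assert slope_p_value(t, 1.0, df) == pytest.approx(oracle, abs=1e-6)


class TestSuccessiveChange:
    @pytest.mark.parametrize(
        "means, expected",
        [
            ([3430, 3590, 3760, 3830], "increasing"),
            ([99100, 90200, 126000, 92400], "none"),
            ([1, 1, 2], "none"),
            ([4, 3, 2, 1], "decreasing"),
            ([1, np.nan, 3, 4], "none"),  # an ND group breaks the succession
        ],
    )
    def test_direction(self, means, expected):
        assert successive_change(means) == expected


class TestFlagBiomarker:
    def test_three_criteria(self):
        fit = fit_trend(STUDY_DOSES, [2.29, 1.68, 1.48, 1.27])
        call = flag_biomarker(fit, "decreasing")
        assert call.passes and call.direction == "decreasing"

    def test_nonsignificant_slope_fails(self):
        """Monotone, high-R² row whose slope misses significance stays unflagged."""
        fit = fit_trend(STUDY_DOSES, [54.5, 55.4, 59.7, 71.7])
        assert fit.r2 > 0.75
        assert fit.p_value == pytest.approx(0.088, abs=5e-4)
        call = flag_biomarker(fit, "increasing")
        assert not call.passes
        assert "slope_not_significant" in call.reasons

    def test_r2_threshold_is_strict(self):
        from lipiddose.dose_response import RegressionFit

        fit = RegressionFit(1.0, 0.0, 0.1, 0.75, 10.0, 0.01, 2)
        assert not flag_biomarker(fit, "increasing").passes
        fit = RegressionFit(1.0, 0.0, 0.1, 0.7501, 10.0, 0.01, 2)
        assert flag_biomarker(fit, "increasing").passes


class TestScreenTable:
    def test_null_table_flag_rate_low(self):
        """Zero-slope synthetic lipids are flagged at well under 10%."""
        specs = [
            TrendSpec(f"L{i}", intercept=100.0, slope=0.0, noise_sd=20.0)
            for i in range(1000)
        ]
        matrix, groups = simulate_concentrations(specs, STUDY_DOSES, n_per_group=9,
                                                 seed=20260920)
        means = matrix.groupby(groups).mean().T
        means.columns = [f"mean{i}" for i in range(1, 5)]
        means.index.name = "lipid"
        _report, summary = screen_table(means)
        assert summary["n_flagged"] / summary["n_tested"] <= 0.10

    def test_rows_with_too_few_points_excluded(self):
        table = pd.DataFrame(
            {"mean1": [1.0, np.nan], "mean2": [2.0, np.nan], "mean3": [3.0, 1.0],
             "mean4": [4.0, 2.0]},
            index=pd.Index(["ok", "sparse"], name="lipid"),
        )
        report, summary = screen_table(table)
        assert summary["n_excluded"] == 1 and summary["excluded"] == ["sparse"]
        assert not report.loc["sparse", "flagged"]


class TestCompareGroups:
    def test_identical_groups(self):
        out = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["percent_difference"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)
        assert out["stars"] == ""

    def test_doubling_is_plus_hundred_percent(self):
        b = [1.0, 2.0, 3.0]
        out = compare_groups([2 * v for v in b], b)
        assert out["percent_difference"] == pytest.approx(100.0)

    def test_five_sigma_shift_highly_significant(self):
        """At the study's two-arm size (n = 34), a 5-sigma separation earns ***."""
        rng = np.random.default_rng(7)
        a = rng.normal(10.0, 1.0, 34)
        b = rng.normal(15.0, 1.0, 34)
        out = compare_groups(b, a)
        assert out["p_value"] < 0.001
        assert out["stars"] == "***"

    def test_zero_reference_mean_flagged(self):
        out = compare_groups([1.0, 2.0], [1.0, -1.0])
        assert not out["percent_difference_defined"]
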
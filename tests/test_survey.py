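"""Survey reading, weighted moments, heaping and digit diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anthrobias import (
    InsufficientDataError,
    InvalidInputError,
    SchemaError,
    SurveyTable,
    UndefinedCorrelationError,
    age_heaping_ratio,
    assess_indicator,
    assess_survey,
    digit_preference_test,
    estimate_bias,
    heaping_sd_correlation,
    read_survey,
    weighted_moments,
)


def make_table(ages, haz=None, wt=None, survey_id="t"):
    n = len(ages)
    df = pd.DataFrame(
        {
            "age": ages,
            "haz": haz if haz is not None else np.zeros(n),
            "whz": np.zeros(n),
            "waz": np.zeros(n),
            "wt": wt if wt is not None else np.ones(n),
        }
    )
    return SurveyTable(data=df, survey_id=survey_id)


class TestReadSurvey:
    def test_reads_valid_file_preserving_missing(self, survey_csv):
        table = read_survey(survey_csv)
        assert table.n == 3
        assert table.survey_id == "tiny"
        assert math.isnan(table.data.loc[1, "whz"])
        assert table.data.loc[1, "age"] == 36.5

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("age,haz,whz,waz\n24,-1,-1,-1\n")
        with pytest.raises(SchemaError, match="wt"):
            read_survey(p)

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("age,haz,whz,waz,wt\n24,-1,0,0,1\n25,oops,0,0,1\n")
        with pytest.raises(SchemaError, match="row 1"):
            read_survey(p)

    def test_nonpositive_weight_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("age,haz,whz,waz,wt\n24,-1,0,0,0\n")
        with pytest.raises(SchemaError, match="weight"):
            read_survey(p)

    def test_age_eligibility_filter(self, tmp_path):
        p = tmp_path / "ages.csv"
        p.write_text("age,haz,whz,waz,wt\n24,-1,0,0,1\n72,-1,0,0,1\n-1,-1,0,0,1\n")
        assert read_survey(p).n == 1
        assert read_survey(p, filter_age=False).n == 3

    def test_plausibility_filter_blanks_extreme_scores(self, tmp_path):
        p = tmp_path / "ext.csv"
        p.write_text("age,haz,whz,waz,wt\n24,-7.5,0,0,1\n25,-1,0,0,1\n")
        table = read_survey(p, plausibility_filter=True)
        assert math.isnan(table.data.loc[0, "haz"])
        assert table.data.loc[1, "haz"] == -1


class TestWeightedMoments:
    def test_two_point_hand_computation(self):
        table = make_table([24, 25], haz=[0.0, 2.0], wt=[1.0, 3.0])
        mean, sd, n_used = weighted_moments(table, "haz")
        assert mean == pytest.approx(1.5)
        assert sd == pytest.approx(math.sqrt(0.75))
        assert n_used == 2

    def test_uniform_weights_reduce_to_population_moments(self, rng):
        z = rng.normal(-1, 1.2, 500)
        table = make_table(np.full(500, 30), haz=z)
        mean, sd, _ = weighted_moments(table, "haz")
        assert mean == pytest.approx(z.mean())
        assert sd == pytest.approx(z.std(ddof=0))

    @given(scale=st.floats(0.01, 100, allow_nan=False))
    def test_weight_rescaling_invariance(self, scale):
        z = [-2.5, -1.0, 0.5, -3.0]
        w = [1.0, 2.0, 0.5, 4.0]
        base = weighted_moments(make_table([20] * 4, haz=z, wt=w), "haz")
        scaled = weighted_moments(
            make_table([20] * 4, haz=z, wt=[x * scale for x in w]), "haz"
        )
        assert base[0] == pytest.approx(scaled[0])
        assert base[1] == pytest.approx(scaled[1])

    def test_missing_dropped_per_indicator(self):
        table = make_table([20, 21, 22], haz=[np.nan, -1.0, -2.0])
        _, _, n_used = weighted_moments(table, "haz")
        assert n_used == 2
        with pytest.raises(InsufficientDataError):
            weighted_moments(make_table([20, 21], haz=[np.nan, -1.0]), "haz")


class TestAssessIndicator:
    def test_reference_sd_gives_zero_bias(self, rng):
        z = rng.normal(-1.5, 1.0, 4000)
        z = (z - z.mean()) / z.std(ddof=0) - 1.5  # standardise to exact moments
        summary = assess_indicator(make_table(np.full(4000, 30), haz=z), "haz")
        assert summary.weighted_sd == pytest.approx(1.0, abs=1e-9)
        assert summary.bias_point == pytest.approx(0.0, abs=1e-9)

    def test_bias_point_matches_map_at_measured_moments(self, rng):
        z = rng.normal(-1.0, 1.4, 5000)
        summary = assess_indicator(make_table(np.full(5000, 30), haz=z), "haz")
        assert summary.bias_point == pytest.approx(
            estimate_bias(summary.weighted_mean, summary.weighted_sd)
        )
        lo, hi = summary.bias_interval
        assert lo <= summary.bias_point <= hi

    def test_all_missing_is_insufficient(self):
        table = make_table([20, 21, 22], haz=[np.nan] * 3)
        with pytest.raises(InsufficientDataError):
            assess_indicator(table, "haz")


class TestAgeHeaping:
    def test_uniform_integer_ages_give_exact_baseline(self):
        table = make_table(np.arange(60))
        res = age_heaping_ratio(table)
        assert res.ratio == pytest.approx(9 / 60)
        assert res.uniform_expectation == pytest.approx(0.15)
        assert res.qualifying_count == 9
        assert res.total_count == 60

    def test_complete_heaping_and_no_heaping(self):
        assert age_heaping_ratio(make_table([24.0] * 10)).ratio == 1.0
        assert age_heaping_ratio(make_table([5, 10, 30, 55])).ratio == 0.0

    def test_window_is_inclusive_on_rounded_months(self):
        # 22.6 rounds to 23, inside [23,25]; 22.4 rounds to 22, outside
        assert age_heaping_ratio(make_table([22.6])).ratio == 1.0
        assert age_heaping_ratio(make_table([22.4])).ratio == 0.0

    def test_ignores_weights(self):
        a = age_heaping_ratio(make_table([24, 30], wt=[10.0, 0.1]))
        b = age_heaping_ratio(make_table([24, 30], wt=[1.0, 1.0]))
        assert a.ratio == b.ratio == 0.5

    def test_excluded_ages_drop_from_both_sides(self):
        table = make_table([12, 24, 30, 11])
        res = age_heaping_ratio(table, excluded_ages=(12,))
        assert res.total_count == 2  # 12 and 11 fall in the excluded window
        assert res.ratio == 0.5

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            age_heaping_ratio(make_table([]))


class TestDigitPreference:
    def test_uniform_decimals_not_flagged(self, rng):
        heights = 80 + rng.integers(0, 10, 2000) / 10 + rng.integers(0, 20, 2000)
        res = digit_preference_test(heights, kind="terminal_digit")
        assert sum(res.counts.values()) == 2000
        assert res.p_value > 0.001

    def test_total_rounding_is_flagged(self):
        res = digit_preference_test(np.arange(100, 200, dtype=float), kind="terminal_digit")
        assert res.p_value < 1e-10

    def test_integer_month_counts_conserved(self, rng):
        ages = rng.integers(0, 60, 500).astype(float)
        res = digit_preference_test(ages, kind="integer_month")
        assert sum(res.counts.values()) == 500

    def test_empty_rejected_small_warned(self):
        with pytest.raises(InvalidInputError):
            digit_preference_test([], kind="terminal_digit")
        with pytest.warns(UserWarning):
            digit_preference_test([1.1] * 10, kind="terminal_digit")


class TestHeapingSdCorrelation:
    @staticmethod
    def pair(ratio, sd):
        from anthrobias import HeapingResult, IndicatorSummary

        h = HeapingResult(ratio, int(ratio * 100), 100, (24, 36, 48), 1, 0.15)
        s = IndicatorSummary("haz", -1.5, sd, 0.3, 0.05, (0.0, 0.1), 100, 0)
        return h, s

    def test_collinear_points_give_unit_rho(self):
        pairs = [self.pair(r, 1.0 + 2 * r) for r in (0.1, 0.2, 0.3, 0.4)]
        res = heaping_sd_correlation(pairs)
        assert res.rho == pytest.approx(1.0)
        assert res.n_surveys == 4

    def test_permutation_invariance(self):
        pairs = [self.pair(r, sd) for r, sd in [(0.1, 1.0), (0.3, 1.5), (0.2, 1.1), (0.5, 1.4)]]
        assert heaping_sd_correlation(pairs).rho == pytest.approx(
            heaping_sd_correlation(pairs[::-1]).rho
        )

    def test_too_few_or_degenerate(self):
        with pytest.raises(InsufficientDataError):
            heaping_sd_correlation([self.pair(0.1, 1.0), self.pair(0.2, 1.1)])
        with pytest.raises(UndefinedCorrelationError):
            heaping_sd_correlation([self.pair(0.2, 1.0 + 0.1 * i) for i in range(4)])


def test_full_survey_report_structure(survey_csv):
    report = assess_survey(read_survey(survey_csv))
    assert report["n_children"] == 3
    assert set(report["indicators"]) == {"haz", "whz", "waz"}
    assert report["indicators"]["whz"]["n_missing"] == 1  # computed on 2 of 3 rows
    assert "ratio" in report["age_heaping"]
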
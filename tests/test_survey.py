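"""Loading, recoding, filtering and marginal-association diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivdirect.datasets import portal_use_by_internet_savvy
from ivdirect.errors import ConfigurationError, DegenerateTableError, InputError
from ivdirect.simulate import generate_dataset, preset, synthetic_variable_map
from ivdirect.survey import (
    VariableMap,
    chi_square_test,
    crosstab,
    derive_internet_savvy,
    filter_population,
    load_study_table,
)


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadStudyTable:
    def test_recode_and_missing_codes(self, tmp_path):
        path = _write(tmp_path, "portal,savvy\n0,1\n2,0\n9,1\n")
        vmap = VariableMap(
            intervention="portal", iv="savvy", missing_codes={"portal": [9]}
        )
        table = load_study_table(path, vmap)
        got = table.df["T"].tolist()
        assert got[0] == 0 and got[1] == 2 and np.isnan(got[2])
        assert table.load_report.missing_counts["T"] == 1

    def test_negative_sentinels_become_missing(self, tmp_path):
        path = _write(tmp_path, "portal,savvy,inc\n-9,1,2\n1,-5,1\n3,0,-1\n")
        vmap = VariableMap(
            intervention="portal", iv="savvy", confounders={"income": "inc"}
        )
        table = load_study_table(path, vmap)
        assert table.df["T"].isna().tolist() == [True, False, False]
        assert table.df["Z"].isna().tolist() == [False, True, False]
        assert table.df["income"].isna().tolist() == [False, False, True]

    def test_absent_mapped_column_is_configuration_error(self, tmp_path):
        path = _write(tmp_path, "portal,savvy\n0,1\n")
        vmap = VariableMap(
            intervention="portal", iv="savvy", confounders={"income": "inc"}
        )
        with pytest.raises(ConfigurationError, match="inc"):
            load_study_table(path, vmap)

    def test_unparseable_file_is_input_error(self, tmp_path):
        path = tmp_path / "nope.csv"
        with pytest.raises(InputError):
            load_study_table(path, VariableMap(intervention="T", iv="Z"))

    def test_round_trip_of_synthetic_table(self, tmp_path):
        table, _ = generate_dataset(
            preset("forward_strong", n=300, seed=11, missing_rate=0.15)
        )
        path = tmp_path / "synth.csv"
        table.to_csv(path)
        again = load_study_table(path, synthetic_variable_map(table))
        assert again.equals(table)

    def test_double_bound_column_rejected(self):
        with pytest.raises(ConfigurationError):
            VariableMap(intervention="col", iv="col")


class TestInternetSavvy:
    # venue codes: 1 = Daily, larger = less often, NaN = unanswered
    @pytest.mark.parametrize(
        "items, expected",
        [
            ((1, np.nan, np.nan, np.nan), 1.0),
            ((2, 5, np.nan, np.nan), 0.0),
            ((np.nan, np.nan, np.nan, np.nan), np.nan),
            ((3, 3, 3, 1), 1.0),
        ],
    )
    def test_any_daily_rule(self, items, expected):
        frame = pd.DataFrame([items], dtype=float)
        got = derive_internet_savvy(frame, daily_code=1).iloc[0]
        assert got == expected or (np.isnan(expected) and np.isnan(got))


class TestFilterPopulation:
    def test_keeps_cancer_rows_with_defined_instrument(self, small_table):
        df = small_table.df.copy()
        df.loc[1, "cancer"] = 0.0
        df.loc[2, "Z"] = np.nan
        table = small_table.with_df(df)
        out = filter_population(table)
        assert out.n == 6
        assert (out.df["cancer"] == 1).all() and out.df["Z"].notna().all()
        assert out.filter_report == {"kept": 6, "dropped": 2}

    def test_all_dropped_warns_not_raises(self, small_table):
        df = small_table.df.copy()
        df["cancer"] = 0.0
        with pytest.warns(UserWarning):
            out = filter_population(small_table.with_df(df))
        assert out.n == 0

    def test_generator_bookkeeping_at_known_prevalence(self):
        table, _ = generate_dataset(
            preset("forward_strong", n=1000, seed=5, cancer_prevalence=0.4)
        )
        out = filter_population(table)
        assert out.n == int((table.df["cancer"] == 1).sum())


class TestCrosstab:
    def test_counts_conserved(self, rng):
        a = pd.Series(rng.integers(0, 3, 200).astype(float))
        b = pd.Series(rng.integers(0, 4, 200).astype(float))
        a[rng.choice(200, 20, replace=False)] = np.nan
        tab = crosstab(a, b)
        assert tab.to_numpy().sum() == int((a.notna() & b.notna()).sum())

    def test_missing_category_retained_when_requested(self):
        a = pd.Series([0, 0, 1, np.nan])
        b = pd.Series([1.0, np.nan, 2.0, 1.0])
        tab = crosstab(a, b, drop_missing=False)
        assert tab.to_numpy().sum() == 4

    def test_degenerate_single_level(self):
        c = pd.Series([1.0] * 10)
        with pytest.raises(DegenerateTableError):
            crosstab(c, c)

    def test_reference_stratum_percentages(self):
        tab = portal_use_by_internet_savvy()
        savvy = tab.loc[1]
        nonsavvy = tab.loc[0]
        assert round(100 * savvy["t0"] / savvy.sum(), 1) == 44.4
        assert round(100 * nonsavvy["t0"] / nonsavvy.sum(), 1) == 78.2


class TestChiSquare:
    def test_proportional_rows_give_zero_statistic(self):
        tab = np.array([[10, 20, 30], [20, 40, 60]])
        res = chi_square_test(tab)
        assert abs(res.statistic) < 1e-9 and res.p_value == pytest.approx(1.0)

    def test_hand_computed_perfect_association(self):
        # X² = sum (obs-exp)^2/exp = 4 * (10-5)^2/5 = 20, df 1
        res = chi_square_test(np.array([[10, 0], [0, 10]]))
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(7.744216e-6, rel=1e-4)
        assert res.cramers_v == pytest.approx(1.0)

    def test_reference_instrument_association_is_strong(self):
        tab = portal_use_by_internet_savvy(include_nonresponse=False)
        res = chi_square_test(tab)
        assert res.p_value < 0.001

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square_test(np.array([[0, 0], [3, 4]]))


@given(
    st.lists(
        st.sampled_from([0.0, 1.0, 2.0, 9.0, -9.0]), min_size=1, max_size=30
    )
)
def test_recoding_is_idempotent(values):
    """Applying the sentinel/range recode twice equals applying it once."""
    s = pd.Series(values)
    vmap = VariableMap(intervention="T", iv="Z", missing_codes={"c": [9.0]})
    from ivdirect.survey import _apply_missing

    once = _apply_missing(s, vmap, "c")
    twice = _apply_missing(once, vmap, "c")
    pd.testing.assert_series_equal(once, twice)
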
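import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetsvar import data_io
from hetsvar.errors import ConfigError, DataError

from conftest import make_transformed


class TestReadPanel:
    def test_echoes_counts(self, tiny_csv):
        series = data_io.read_panel(tiny_csv)
        assert set(series) == {"law", "minorities", "whites", "twitter"}
        np.testing.assert_array_equal(series["law"].values, [0, 1, 5])
        np.testing.assert_array_equal(series["twitter"].values, [937, 3320, 56000])

    def test_missing_day_names_date(self):
        csv = io.StringIO(
            "date,law,minorities,whites,twitter\n"
            "2015-01-01,0,1,1,10\n"
            "2015-01-03,1,0,1,20\n"
        )
        with pytest.raises(DataError, match="2015-01-02"):
            data_io.read_panel(csv)

    def test_negative_count_rejected(self):
        csv = io.StringIO(
            "date,law,minorities,whites,twitter\n"
            "2015-01-01,0,-1,1,10\n"
            "2015-01-02,1,0,1,20\n"
        )
        with pytest.raises(DataError, match="negative"):
            data_io.read_panel(csv)

    def test_duplicate_date_rejected(self):
        csv = io.StringIO(
            "date,law,minorities,whites,twitter\n"
            "2015-01-01,0,1,1,10\n"
            "2015-01-01,1,0,1,20\n"
        )
        with pytest.raises(DataError, match="duplicate"):
            data_io.read_panel(csv)

    def test_missing_column_is_config_error(self):
        csv = io.StringIO("date,law,minorities,whites\n2015-01-01,0,1,1\n")
        with pytest.raises(ConfigError, match="twitter"):
            data_io.read_panel(csv)


class TestIHSTransform:
    @pytest.mark.parametrize(
        "count,expected,places",
        [(0, 0.0, 10), (1, 0.8814, 4), (6, 2.4918, 4), (3320, 8.801, 3), (937, 7.536, 3)],
    )
    def test_reference_values(self, count, expected, places):
        """The transform of single-count and tweet-scale values is analytic."""
        dates = pd.date_range("2015-01-01", periods=2, freq="D")
        s = data_io.DailyCountSeries("x", dates, np.array([count, 0]))
        g = data_io.ihs_transform(s).values[0]
        assert g == pytest.approx(expected, abs=0.5 * 10 ** -places)

    def test_zero_iff_zero_count(self, count_series):
        g = data_io.ihs_transform(count_series)
        assert np.all(g.values >= 0)
        np.testing.assert_array_equal(g.values == 0, count_series.values == 0)

    def test_nonpositive_theta_rejected(self, count_series):
        with pytest.raises(ConfigError):
            data_io.ihs_transform(count_series, theta=0.0)

    def test_order_preserving_and_odd(self):
        x = np.array([-5.0, -0.5, 0.0, 0.5, 5.0, 100.0])
        g = np.arcsinh(x)
        assert np.all(np.diff(g) > 0)
        np.testing.assert_allclose(np.arcsinh(-x), -g, atol=1e-12)

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(deadline=None, max_examples=200)
    def test_inverse_recovers_counts(self, count):
        dates = pd.date_range("2015-01-01", periods=2, freq="D")
        s = data_io.DailyCountSeries("x", dates, np.array([count, 0]))
        g = data_io.ihs_transform(s)
        back = data_io.ihs_inverse(g.values)
        assert back[0] == pytest.approx(count, abs=1e-9 * max(1, count))

    def test_general_theta_matches_formula(self, count_series):
        theta = 0.5
        g = data_io.ihs_transform(count_series, theta=theta)
        y = count_series.values.astype(float)
        expected = np.log(theta * y + np.sqrt(1 + theta**2 * y**2))
        np.testing.assert_allclose(g.values, expected, atol=1e-12)


class TestDifference:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 1, 1], [0, 0]), ([0, 2, 5], [2, 3])],
    )
    def test_arithmetic(self, values, expected):
        d = data_io.difference(make_transformed(values))
        np.testing.assert_allclose(d.values, expected)
        assert d.differenced and len(d.dates) == len(values) - 1

    def test_tweet_scale_difference(self):
        d = data_io.difference(make_transformed(np.arcsinh([937.0, 3320.0])))
        assert d.values[0] == pytest.approx(np.arcsinh(3320) - np.arcsinh(937), abs=1e-12)
        assert d.values[0] == pytest.approx(1.265, abs=5e-4)

    def test_double_difference_rejected(self):
        d = data_io.difference(make_transformed([0, 2, 5]))
        with pytest.raises(DataError, match="already differenced"):
            data_io.difference(d)

    @given(
        st.lists(st.floats(-1e3, 1e3, allow_nan=False), min_size=2, max_size=40)
    )
    @settings(deadline=None, max_examples=100)
    def test_cumsum_inverts_difference(self, values):
        s = make_transformed(values)
        d = data_io.difference(s)
        rebuilt = values[0] + np.concatenate([[0.0], np.cumsum(d.values)])
        np.testing.assert_allclose(rebuilt, s.values, atol=1e-9)


class TestAssemblePanel:
    def _trio(self, n=10):
        law = make_transformed(np.arange(n), name="law")
        ctz = make_transformed(np.arange(n) * 0.5, name="minorities")
        twt = data_io.difference(make_transformed(np.arange(n) * 2.0, name="twitter"))
        return law, ctz, twt

    def test_first_day_dropped(self):
        law, ctz, twt = self._trio(10)
        panel = data_io.assemble_panel(law, ctz, twt)
        assert panel.nobs == 9
        assert panel.dates[0] == law.dates[1]
        assert panel.variables == ("law", "minorities", "twitter")

    def test_ctz_choice_changes_only_column2(self):
        law, minorities, twt = self._trio(10)
        whites = make_transformed(np.linspace(0, 1, 10), name="whites")
        p1 = data_io.assemble_panel(law, minorities, twt)
        p2 = data_io.assemble_panel(law, whites, twt)
        np.testing.assert_array_equal(p1.matrix[:, [0, 2]], p2.matrix[:, [0, 2]])
        assert not np.allclose(p1.matrix[:, 1], p2.matrix[:, 1])

    def test_date_intersection(self):
        law = make_transformed(np.arange(10), name="law", start="2015-01-01")
        ctz = make_transformed(np.arange(10), name="m", start="2015-01-06")
        twt = data_io.difference(
            make_transformed(np.arange(10) * 1.0, name="t", start="2015-01-01")
        )
        panel = data_io.assemble_panel(law, ctz, twt)
        assert panel.nobs == 5

    def test_disjoint_ranges_rejected(self):
        law = make_transformed(np.arange(10), name="law", start="2015-01-01")
        ctz = make_transformed(np.arange(10), name="m", start="2016-01-01")
        twt = data_io.difference(
            make_transformed(np.arange(10) * 1.0, name="t", start="2015-01-01")
        )
        with pytest.raises(DataError, match="common dates"):
            data_io.assemble_panel(law, ctz, twt)

    def test_undifferenced_twt_rejected(self):
        law, ctz, _ = self._trio(10)
        twt_levels = make_transformed(np.arange(10) * 2.0, name="twitter")
        with pytest.raises(DataError, match="differenced"):
            data_io.assemble_panel(law, ctz, twt_levels)


class TestSummarize:
    def test_min_max(self):
        s = data_io.summarize(make_transformed([0, 0, 0, 5]))
        assert s.min == 0 and s.max == 5

    def test_tweet_scale_fixture(self):
        s = data_io.summarize(make_transformed([937, 1720, 3320, 5125, 56000]))
        assert s.min == 937 and s.max == 56000 and s.median == 3320

    def test_singleton_sd_zero_with_warning(self):
        with pytest.warns(UserWarning, match="single"):
            s = data_io.summarize(np.array([3.0]))
        assert s.sd == 0 and s.mean == 3 and s.median == 3

    def test_quantile_ordering_invariant(self):
        s = data_io.summarize(make_transformed([5, 1, 4, 2, 8, 0]))
        assert s.min <= s.first_quartile <= s.median <= s.third_quartile <= s.max
        assert s.sd >= 0

    @given(st.permutations(list(range(12))))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariance(self, perm):
        base = data_io.summarize(np.arange(12, dtype=float))
        shuffled = data_io.summarize(np.array(perm, dtype=float))
        assert base == shuffled

    def test_summary_table_shape(self, tiny_csv):
        series = data_io.read_panel(tiny_csv)
        table = data_io.summary_table(series)
        assert list(table.index) == ["min", "1Q", "median", "mean", "3Q", "max", "sd"]
        assert table.loc["max", "twitter"] == 56000
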
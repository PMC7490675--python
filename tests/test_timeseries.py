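"""Daily series, rolling sentiment index, trend, Welch's test, peaks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprpulse import timeseries
from crisprpulse.timeseries import (
    daily_counts,
    detect_peaks,
    fit_linear_trend,
    sentiment_index,
    welch_t,
    yearly_sentiment_tests,
)
from conftest import toy_corpus
from oracles import brute_force_peaks, textbook_welch, windowed_index


def make_series(n_pos, n_neg, n_neu=None, start="2016-01-01"):
    n = len(n_pos)
    n_neu = n_neu or [0] * n
    idx = pd.date_range(start, periods=n, freq="D", tz="UTC")
    df = pd.DataFrame({"n_positive": n_pos, "n_neutral": n_neu,
                       "n_negative": n_neg}, index=idx)
    df["n_total"] = df.sum(axis=1)
    return df


class TestDailyCounts:
    def test_direct_count(self):
        corpus = toy_corpus([
            ("a", "2016-01-01 05:00", "x", None, "positive"),
            ("b", "2016-01-01 06:00", "x", None, "negative"),
            ("c", "2016-01-01 07:00", "x", None, "neutral"),
        ])
        out = daily_counts(corpus)
        assert out.iloc[0][["n_positive", "n_neutral", "n_negative"]].tolist() == [1, 1, 1]
        assert out.iloc[0]["n_total"] == 3

    def test_gap_day_filled_with_zeros(self):
        corpus = toy_corpus([("a", "2016-01-01", "x", None, "positive"),
                             ("b", "2016-01-03", "x", None, "negative")])
        out = daily_counts(corpus)
        assert len(out) == 3
        assert out.iloc[1]["n_total"] == 0

    def test_conservation(self, quiet_corpus):
        out = daily_counts(quiet_corpus, sentiment_col="true_sentiment")
        assert out["n_total"].sum() == len(quiet_corpus)

    def test_empty_rejected(self, quiet_corpus):
        with pytest.raises(ValueError):
            daily_counts(quiet_corpus.iloc[0:0])


class TestSentimentIndex:
    def test_pure_positive(self):
        out = sentiment_index(make_series([3] * 10, [0] * 10), 7)
        assert (out["s"] == 1.0).all()

    def test_balanced_window_is_zero(self):
        out = sentiment_index(make_series([2] * 10, [2] * 10), 7)
        assert (out["s"] == 0.0).all()

    def test_matches_window_oracle_on_toy(self):
        n_pos = [3, 0, 1, 4, 0, 2, 5, 1, 0, 2]
        n_neg = [0, 1, 2, 0, 0, 3, 1, 0, 4, 1]
        out = sentiment_index(make_series(n_pos, n_neg), 7)
        s_exp, a_exp = windowed_index(n_pos, n_neg,
                                      [p + q for p, q in zip(n_pos, n_neg)], 7)
        np.testing.assert_allclose(out["s"], s_exp, atol=1e-12)
        np.testing.assert_allclose(out["a"], a_exp, atol=1e-12)

    def test_undefined_when_no_polar_tweets(self):
        out = sentiment_index(make_series([0] * 9, [0] * 9, [5] * 9), 3)
        assert out["s"].isna().all()
        assert (out["a"] == 5.0).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            sentiment_index(make_series([1] * 5, [1] * 5), 4)

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)),
                    min_size=30, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_on_random_series(self, triples):
        n_pos = [t[0] for t in triples]
        n_neg = [t[1] for t in triples]
        n_neu = [t[2] for t in triples]
        out = sentiment_index(make_series(n_pos, n_neg, n_neu), 7)
        s_exp, a_exp = windowed_index(
            n_pos, n_neg, [p + q + r for p, q, r in zip(n_pos, n_neg, n_neu)], 7)
        np.testing.assert_allclose(out["s"], s_exp, atol=1e-12)
        np.testing.assert_allclose(out["a"], a_exp, atol=1e-12)

    def test_antisymmetric_in_polarity(self):
        rng = np.random.default_rng(7)
        n_pos = rng.integers(0, 10, 30)
        n_neg = rng.integers(0, 10, 30)
        s1 = sentiment_index(make_series(n_pos, n_neg), 7)["s"]
        s2 = sentiment_index(make_series(n_neg, n_pos), 7)["s"]
        np.testing.assert_allclose(s1, -s2, atol=1e-12)


class TestTrend:
    def test_constant_index(self):
        out = sentiment_index(make_series([3] * 30, [1] * 30), 7)
        fit = fit_linear_trend(out)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.stderr == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        idx = pd.date_range("2016-01-01", periods=400, freq="D", tz="UTC")
        t_years = (idx - idx[0]).days / 365.25
        df = pd.DataFrame({"s": 0.5 - 0.1 * t_years, "a": 1.0}, index=idx)
        fit = fit_linear_trend(df)
        assert fit.slope == pytest.approx(-0.1, abs=1e-10)
        assert fit.intercept == pytest.approx(0.5, abs=1e-10)

    def test_nan_days_skipped(self):
        idx = pd.date_range("2016-01-01", periods=10, freq="D", tz="UTC")
        s = pd.Series(np.linspace(0, 1, 10), index=idx)
        s.iloc[3] = np.nan
        fit = fit_linear_trend(pd.DataFrame({"s": s, "a": 1.0}))
        assert np.isfinite(fit.slope)

    def test_too_few_points_rejected(self):
        idx = pd.date_range("2016-01-01", periods=5, freq="D", tz="UTC")
        df = pd.DataFrame({"s": [0.1, np.nan, np.nan, np.nan, 0.2], "a": 1.0}, index=idx)
        with pytest.raises(ValueError):
            fit_linear_trend(df)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_frozen_textbook_example(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3, 4, 5])
        assert t == pytest.approx(-1.0954451150103324)
        assert df == pytest.approx(5.882352941176469)
        assert p == pytest.approx(0.31613342192639304)

    def test_pooled_limit_df(self):
        # equal n and equal variances: df = 2n - 2
        a = [1.0, 2.0, 3.0, 4.0]
        b = [11.0, 12.0, 13.0, 14.0]
        _, df, _ = welch_t(a, b)
        assert df == pytest.approx(6.0)

    def test_degenerate_variance_equal_means(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_degenerate_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_matches_textbook_oracle_on_random_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(2, 30))
            b = rng.normal(0.3, 2, rng.integers(2, 30))
            ours = welch_t(a, b)
            exp = textbook_welch(a, b)
            np.testing.assert_allclose(ours, exp, rtol=1e-10)


class TestYearlyTests:
    def test_degenerate_year_all_positive(self):
        rows = [(f"a{k}", f"2015-03-0{k+1}", "x", None, "positive") for k in range(5)]
        rows += [(f"b{k}", f"2016-03-0{k+1}", "x", None,
                  "positive" if k % 2 else "negative") for k in range(6)]
        yearly, tests = yearly_sentiment_tests(toy_corpus(rows))
        y2015 = yearly[yearly["year"] == 2015].iloc[0]
        assert (y2015["mean"], y2015["sd"]) == (1.0, 0.0)
        assert len(tests) == 1

    def test_identical_years_p_one(self):
        rows = []
        for year in (2015, 2016):
            for k, s in enumerate(["positive"] * 3 + ["negative"] * 2):
                rows.append((f"t{year}{k}", f"{year}-06-0{k+1}", "x", None, s))
        _, tests = yearly_sentiment_tests(toy_corpus(rows))
        assert tests.iloc[0]["p"] == pytest.approx(1.0)

    def test_distinct_negative_shares_detected(self):
        """Years with 10% vs 30% negative shares at n=5000: means match the
        analytic value and Welch p agrees with the direct formula."""
        rng = np.random.default_rng(2)
        rows = []
        for year, p_neg in ((2015, 0.1), (2016, 0.3)):
            sents = rng.choice(["positive", "negative"], size=5000, p=[1 - p_neg, p_neg])
            days = rng.integers(0, 28, size=5000)
            months = rng.integers(1, 13, size=5000)
            for k, s in enumerate(sents):
                rows.append((f"t{year}_{k}", f"{year}-{months[k]:02d}-{days[k]+1:02d}",
                             "x", None, s))
        corpus = toy_corpus(rows)
        yearly, tests = yearly_sentiment_tests(corpus)
        w15 = yearly[yearly["year"] == 2015].iloc[0]
        w16 = yearly[yearly["year"] == 2016].iloc[0]
        assert w15["mean"] == pytest.approx(0.8, abs=0.03)
        assert w16["mean"] == pytest.approx(0.4, abs=0.04)
        weights = {2015: [], 2016: []}
        for r in rows:
            weights[int(r[0][1:5])].append(1.0 if r[4] == "positive" else -1.0)
        exp = textbook_welch(weights[2015], weights[2016])
        assert tests.iloc[0]["t"] == pytest.approx(exp[0], rel=1e-10)
        assert tests.iloc[0]["p"] == pytest.approx(exp[2], rel=1e-8)

    def test_insufficient_years_rejected(self):
        rows = [("a", "2015-01-01", "x", None, "positive"),
                ("b", "2015-01-02", "x", None, "negative")]
        with pytest.raises(ValueError):
            yearly_sentiment_tests(toy_corpus(rows))


class TestPeaks:
    def test_monotone_series_has_no_peaks(self):
        assert detect_peaks(list(range(10)), 0.2) == []

    def test_single_triangle(self):
        peaks = detect_peaks([0, 1, 2, 3, 2, 1, 0], 0.2)
        assert len(peaks) == 1
        assert peaks[0].height == 3.0
        assert peaks[0].prominence == 3.0
        assert peaks[0].rel_prominence == 1.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks([2.0, 2.0, 2.0], 0.2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks([1.0, 2.0], 0.2)

    def test_plateau_reported_at_left_edge(self):
        peaks = detect_peaks([0, 3, 3, 3, 0], 0.2)
        assert len(peaks) == 1
        assert peaks[0].day == 1

    def test_multi_bump_toy_matches_oracle(self):
        x = [0, 2, 1, 4, 1, 1, 6, 2, 3, 2, 0, 5, 4, 4, 5, 1, 0, 2, 1, 0]
        ours = [(p.day, p.height, p.prominence) for p in detect_peaks(x, 0.2)]
        assert ours == brute_force_peaks(x, 0.2)

    @given(st.lists(st.integers(0, 50), min_size=5, max_size=50))
    @settings(max_examples=150, deadline=None)
    def test_equals_brute_force_on_random_series(self, xs):
        if max(xs) == min(xs):
            return
        ours = [(p.day, p.height, p.prominence) for p in detect_peaks(xs, 0.2)]
        assert ours == [(i, float(h), float(pr)) for i, h, pr in brute_force_peaks(xs, 0.2)]

    def test_dates_carried_through_series_index(self):
        idx = pd.date_range("2016-01-01", periods=7, freq="D", tz="UTC")
        s = pd.Series([0, 1, 5, 1, 0, 1, 0], index=idx, dtype=float)
        peaks = detect_peaks(s, 0.2)
        assert peaks[0].day == idx[2]
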
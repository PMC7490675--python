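"""Daily activity and sentiment-index series, trend, tests, peaks.

The sentiment index of day d is the count-weighted mean of the +1/-1 weights
of polar (positive/negative) tweets in a centered window, i.e.
s(d) = (P - N)/(P + N) with P and N the windowed positive and negative
counts; neutral tweets are excluded from s but counted in activity.  Windows
are truncated at the series edges so the series keeps its full length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .labels import SENTIMENT_WEIGHTS

DAYS_PER_YEAR = 365.25


def _sentiment_column(corpus: pd.DataFrame, sentiment_col: Optional[str]) -> str:
    if sentiment_col is not None:
        return sentiment_col
    return "pred_sentiment" if "pred_sentiment" in corpus.columns else "true_sentiment"


def daily_counts(corpus: pd.DataFrame, sentiment_col: Optional[str] = None) -> pd.DataFrame:
    """Per-UTC-day counts by sentiment class; missing days filled with 0."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    col = _sentiment_column(corpus, sentiment_col)
    day = corpus["created_at"].dt.tz_convert("UTC").dt.floor("D")
    table = (
        pd.crosstab(day, corpus[col])
        .reindex(columns=["positive", "neutral", "negative"], fill_value=0)
    )
    full = pd.date_range(table.index.min(), table.index.max(), freq="D", tz="UTC")
    table = table.reindex(full, fill_value=0)
    table.columns = ["n_positive", "n_neutral", "n_negative"]
    table.index.name = "date"
    table["n_total"] = table.sum(axis=1)
    return table


def sentiment_index(series: pd.DataFrame, window: int = 7) -> pd.DataFrame:
    """Windowed sentiment index s and smoothed activity a.

    ``window`` must be odd; edge windows are truncated.  s is NaN on days
    whose window contains no polar tweets.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    roll = dict(window=window, center=True, min_periods=1)
    P = series["n_positive"].rolling(**roll).sum()
    N = series["n_negative"].rolling(**roll).sum()
    polar = P + N
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (P - N) / polar
    s[polar == 0] = np.nan
    a = series["n_total"].rolling(**roll).mean()
    out = pd.DataFrame({"s": s, "a": a}, index=series.index)
    out.attrs["window"] = window
    return out


@dataclass
class TrendFit:
    slope: float      # per year
    stderr: float     # per year, plain OLS
    intercept: float


def fit_linear_trend(index: pd.DataFrame) -> TrendFit:
    """OLS fit of the index s against time in years; NaN days skipped."""
    s = index["s"].dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 defined index values")
    t0 = s.index[0]
    t_years = (s.index - t0).days / DAYS_PER_YEAR
    res = stats.linregress(t_years, s.to_numpy())
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return TrendFit(slope=float(res.slope), stderr=stderr, intercept=float(res.intercept))


def welch_t(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need size >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va + vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        raise ValueError("zero combined variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2 = va / na + vb / nb
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def yearly_sentiment_tests(corpus: pd.DataFrame, sentiment_col: Optional[str] = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yearly polar-weight means/SDs and consecutive-year Welch tests.

    Only polar (+1/-1) tweets enter; p-values are reported raw and
    Holm-adjusted across the consecutive-year pairs.
    """
    col = _sentiment_column(corpus, sentiment_col)
    polar = corpus[corpus[col].isin(["positive", "negative"])]
    weights = polar[col].map(SENTIMENT_WEIGHTS).astype(float)
    years = polar["created_at"].dt.tz_convert("UTC").dt.year
    by_year = {y: w.to_numpy() for y, w in weights.groupby(years)}
    usable = {y: v for y, v in by_year.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 years with >= 2 polar tweets each")
    yearly = pd.DataFrame({
        "year": sorted(usable),
        "n_polar": [len(usable[y]) for y in sorted(usable)],
        "mean": [float(usable[y].mean()) for y in sorted(usable)],
        "sd": [float(usable[y].std(ddof=1)) for y in sorted(usable)],
    })
    rows = []
    ys = sorted(usable)
    for y1, y2 in zip(ys, ys[1:]):
        t, df, p = welch_t(usable[y1], usable[y2])
        rows.append({"year_a": y1, "year_b": y2, "t": t, "df": df, "p": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["p_holm"] = multipletests(tests["p"], method="holm")[1]
    return yearly, tests


@dataclass
class Peak:
    day: object       # index label (date) or position
    height: float
    prominence: float
    rel_prominence: float


def detect_peaks(values: Union[pd.Series, Sequence[float]],
                 rel_prominence_min: float = 0.2) -> list[Peak]:
    """Local maxima filtered by relative topographic prominence.

    Prominence follows the standard topographic definition (height above the
    higher of the two lowest descent points toward the nearest higher peaks
    or the series ends); "relative" normalizes by the series range.  Plateau
    maxima are reported at their leftmost index.
    """
    series = pd.Series(values)
    x = series.to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("series must have length >= 3")
    rng_ = x.max() - x.min()
    if rng_ == 0:
        raise ValueError("constant series: relative prominence undefined")
    idx, props = signal.find_peaks(x, plateau_size=(1, None))
    if len(idx) == 0:
        return []
    prominences = signal.peak_prominences(x, idx)[0]
    peaks = []
    for pos, left, prom in zip(idx, props["left_edges"], prominences):
        rel = prom / rng_
        if rel >= rel_prominence_min:
            peaks.append(Peak(day=series.index[left], height=float(x[pos]),
                              prominence=float(prom), rel_prominence=float(rel)))
    return peaks


def peaks_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"date": p.day, "height": p.height, "prominence": p.prominence,
          "rel_prominence": p.rel_prominence} for p in peaks],
        columns=["date", "height", "prominence", "rel_prominence"],
    )
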
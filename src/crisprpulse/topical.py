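"""Topical breakdowns: organisms by month, hashtags by year, regex themes.

Unlike the time-series index, the summaries here are means of the full
+1/0/-1 weights, i.e. neutral tweets are included.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ThemeSpec
from .labels import SENTIMENT_WEIGHTS
from .prep import anonymize_text

_HASHTAG_RE = re.compile(r"#\w+")


def extract_hashtags(text: str) -> list[str]:
    """Case-folded #-prefixed tokens of the text (leading # retained)."""
    return _HASHTAG_RE.findall(text.casefold())


def _weights(corpus: pd.DataFrame, sentiment_col: Optional[str]) -> pd.Series:
    col = sentiment_col or ("pred_sentiment" if "pred_sentiment" in corpus.columns
                            else "true_sentiment")
    return corpus[col].map(SENTIMENT_WEIGHTS).astype(float)


def organism_month_matrix(corpus: pd.DataFrame, min_cell: int = 100,
                          sentiment_col: Optional[str] = None,
                          organism_col: Optional[str] = None) -> pd.DataFrame:
    """Tidy (month, organism) cells: tweet count, mean weight, mask flag.

    Cells with fewer than ``min_cell`` tweets keep their value but are
    flagged ``masked`` (rendered transparent in the heat map).
    """
    org_col = organism_col or ("pred_organism" if "pred_organism" in corpus.columns
                               else "true_organism")
    w = _weights(corpus, sentiment_col)
    month = corpus["created_at"].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period("M")
    grouped = w.groupby([month, corpus[org_col]])
    out = grouped.agg(n="size", mean_sentiment="mean").reset_index()
    out.columns = ["month", "organism", "n", "mean_sentiment"]
    out["masked"] = out["n"] < min_cell
    return out


def hashtag_year_stats(corpus: pd.DataFrame, top_k: int = 15,
                       exclude: Iterable[str] = ("#crispr",),
                       sentiment_col: Optional[str] = None) -> pd.DataFrame:
    """Top-k hashtags per year by count, with tweet-weight mean and SD.

    Hashtags are case-folded but otherwise exact (no grouping of spelling
    variants); the overarching topic tag(s) in ``exclude`` are dropped.  A
    tweet with several hashtags contributes to each of them; count ties are
    broken lexicographically.
    """
    exclude = {e.casefold() for e in exclude}
    w = _weights(corpus, sentiment_col)
    year = corpus["created_at"].dt.tz_convert("UTC").dt.year
    long = pd.DataFrame({
        "year": year,
        "weight": w,
        "hashtag": corpus["text"].map(extract_hashtags),
    }).explode("hashtag").dropna(subset=["hashtag"])
    long = long[~long["hashtag"].isin(exclude)]
    if len(long) == 0:
        return pd.DataFrame(columns=["year", "hashtag", "count", "mean_sentiment", "sd"])
    stats = (
        long.groupby(["year", "hashtag"])["weight"]
        .agg(count="size", mean_sentiment="mean", sd=lambda v: float(np.std(v)))
        .reset_index()
    )
    stats = stats.sort_values(["year", "count", "hashtag"],
                              ascending=[True, False, True], kind="stable")
    top = stats.groupby("year", sort=True).head(top_k).reset_index(drop=True)
    top["count"] = top["count"].astype(int)
    return top


def match_themes(corpus: pd.DataFrame, themes: Sequence[ThemeSpec]) -> pd.DataFrame:
    """Boolean flag matrix (tweets x themes), case-insensitive search on the
    anonymized text; a tweet may match any number of themes."""
    names = [t.name for t in themes]
    if len(set(names)) != len(names):
        raise ValueError("theme names must be unique")
    compiled = [(t.name, t.regex) for t in themes]
    texts = corpus["text"].map(anonymize_text)
    data = {name: texts.map(lambda s, rx=rx: rx.search(s) is not None).to_numpy()
            for name, rx in compiled}
    flags = pd.DataFrame(data, index=corpus["id"].to_numpy(), dtype=bool)
    if flags.empty:
        flags = pd.DataFrame(index=corpus["id"].to_numpy(),
                             columns=[t.name for t in themes], dtype=bool)
    flags.index.name = "tweet_id"
    return flags


def theme_year_counts(flags: pd.DataFrame, corpus: pd.DataFrame,
                      months_observed_final_year: int = 12,
                      sentiment_col: Optional[str] = None) -> pd.DataFrame:
    """Counts per (year, theme, sentiment class).

    The final (possibly partial) year's counts are multiplied by
    12/months_observed and reported as reals, a linear full-year
    extrapolation.
    """
    if not 1 <= months_observed_final_year <= 12:
        raise ValueError(
            f"months_observed_final_year must be in [1, 12], got {months_observed_final_year}"
        )
    col = sentiment_col or ("pred_sentiment" if "pred_sentiment" in corpus.columns
                            else "true_sentiment")
    meta = pd.DataFrame({
        "year": corpus["created_at"].dt.tz_convert("UTC").dt.year.to_numpy(),
        "sentiment": corpus[col].to_numpy(),
    }, index=corpus["id"].to_numpy())
    rows = []
    for theme in flags.columns:
        matched = meta[flags[theme].reindex(meta.index, fill_value=False)]
        counts = matched.groupby(["year", "sentiment"]).size()
        for (year, sent), n in counts.items():
            rows.append({"year": int(year), "theme": theme, "sentiment": sent,
                         "count": float(n)})
    out = pd.DataFrame(rows, columns=["year", "theme", "sentiment", "count"])
    if len(out):
        final = out["year"].max()
        factor = 12.0 / months_observed_final_year
        out.loc[out["year"] == final, "count"] *= factor
    return out.sort_values(["year", "theme", "sentiment"], kind="stable").reset_index(drop=True)
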
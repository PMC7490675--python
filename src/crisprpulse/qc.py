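"""Crowd-annotation quality control and consensus merging.

The cleaning chain: per-annotator raw agreement (fraction of pairwise label
comparisons with co-annotators that agree), single-pass outlier removal
(3-SD rule, minimum possible agreements, minimum tasks), chance-corrected
agreement (Fleiss' kappa), and unanimity consensus with a relevance gate:
sentiment and organism gold labels are only kept for tweets whose relevance
consensus is "relevant".
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .labels import QUESTIONS


class DegenerateAgreementError(ValueError):
    """All ratings fall in a single category; chance agreement is 1 and
    kappa is undefined."""


def _check_question(question: str) -> list[str]:
    if question == "pooled":
        return list(QUESTIONS)
    if question not in QUESTIONS:
        raise ValueError(f"unknown question {question!r}; expected one of {QUESTIONS} or 'pooled'")
    return [question]


def raw_agreement(annotations: pd.DataFrame, question: str = "relevance") -> pd.DataFrame:
    """Per-annotator pairwise agreement statistics for one question.

    For each annotator, ``n_possible`` counts every (tweet, co-annotator)
    pair sharing a tweet with them and ``n_actual`` the agreeing ones;
    ``raw_agreement`` is their ratio (NaN when no pairs exist).  Summing
    ``n_actual`` over annotators counts each agreeing pair exactly twice.
    ``question='pooled'`` pools the pairs of all three questions.
    """
    questions = _check_question(question)
    possible: Counter = Counter()
    actual: Counter = Counter()
    tasks: Counter = Counter()
    for _, group in annotations.groupby("tweet_id", sort=False):
        annotators = group["annotator_id"].to_numpy()
        for a in annotators:
            tasks[a] += 1
        for q in questions:
            answers = group[q].to_numpy()
            n = len(annotators)
            for i in range(n):
                for j in range(i + 1, n):
                    possible[annotators[i]] += 1
                    possible[annotators[j]] += 1
                    if answers[i] == answers[j]:
                        actual[annotators[i]] += 1
                        actual[annotators[j]] += 1
    ids = sorted(tasks)
    df = pd.DataFrame({
        "annotator_id": ids,
        "n_tasks": [tasks[a] for a in ids],
        "n_possible": [possible[a] for a in ids],
        "n_actual": [actual[a] for a in ids],
    })
    df["raw_agreement"] = np.where(
        df["n_possible"] > 0, df["n_actual"] / df["n_possible"].replace(0, 1), np.nan
    )
    return df


def flag_outlier_annotators(stats: pd.DataFrame, sd_mult: float = 3.0,
                            min_possible: int = 20, min_tasks: int = 3) -> set[str]:
    """Annotators failing any screening rule.

    Rules: |raw agreement - mean| > sd_mult * population SD (mean and SD over
    all annotators with a defined raw agreement), fewer than ``min_possible``
    possible agreements, or fewer than ``min_tasks`` tasks.
    """
    if len(stats) == 0:
        raise ValueError("no annotator statistics supplied")
    flagged: set[str] = set()
    vals = stats["raw_agreement"].dropna()
    mean = vals.mean() if len(vals) else np.nan
    sd = vals.std(ddof=0) if len(vals) else np.nan
    for row in stats.itertuples(index=False):
        if row.n_possible < min_possible or row.n_tasks < min_tasks:
            flagged.add(row.annotator_id)
        elif not np.isnan(row.raw_agreement) and sd > 0 and abs(row.raw_agreement - mean) > sd_mult * sd:
            flagged.add(row.annotator_id)
    return flagged


def fleiss_kappa(counts: np.ndarray) -> float:
    """Fleiss' kappa for an items x categories matrix of rating counts.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar) with P_bar the mean over items of
    the within-item agreeing-pair fraction and Pe_bar the sum of squared
    overall category proportions.  Requires a fixed number of raters n >= 2
    per item; raises :class:`DegenerateAgreementError` when every rating
    falls in one category.
    """
    m = np.asarray(counts, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("counts must be a non-empty 2-D matrix")
    totals = m.sum(axis=1)
    n = totals[0]
    if n < 2 or not np.all(totals == n):
        raise ValueError("every item must have the same rater count n >= 2")
    p_j = m.sum(axis=0) / m.sum()
    pe = float((p_j ** 2).sum())
    if pe >= 1.0 - 1e-12:
        raise DegenerateAgreementError("all ratings in a single category")
    p_i = ((m ** 2).sum(axis=1) - n) / (n * (n - 1))
    return float((p_i.mean() - pe) / (1.0 - pe))


def annotation_count_matrix(annotations: pd.DataFrame, question: str,
                            outliers: Iterable[str] = (),
                            categories: Optional[Sequence[str]] = None,
                            ) -> tuple[np.ndarray, list[str], list[str]]:
    """Items x categories rating-count matrix for ``question``.

    Rows (tweets) whose remaining rater count differs from the modal count
    are excluded, since the classical kappa assumes a fixed panel size; the
    exclusion is what makes the statistic well defined after outlier removal
    leaves ragged rows.  Returns (matrix, kept tweet ids, category order).
    """
    _check_question(question)
    ann = annotations[~annotations["annotator_id"].isin(set(outliers))]
    if len(ann) == 0:
        raise ValueError("no annotations left after outlier removal")
    if categories is None:
        categories = sorted(ann[question].unique())
    counts = (
        ann.groupby("tweet_id")[question]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=categories, fill_value=0)
    )
    totals = counts.sum(axis=1)
    eligible = totals[totals >= 2]
    if len(eligible) == 0:
        raise ValueError("no tweet has >= 2 remaining annotations")
    # modal rater count; ties broken toward the larger panel
    mode = eligible.value_counts().sort_index(ascending=False).idxmax()
    keep = counts[totals == mode]
    return keep.to_numpy(), list(keep.index), list(categories)


def kappa_for_question(annotations: pd.DataFrame, question: str,
                       outliers: Iterable[str] = ()) -> float:
    """Convenience: build the count matrix and return Fleiss' kappa."""
    matrix, _, _ = annotation_count_matrix(annotations, question, outliers)
    return fleiss_kappa(matrix)


def consensus_labels(annotations: pd.DataFrame, outliers: Iterable[str] = (),
                     min_unanimous: int = 3) -> pd.DataFrame:
    """Unanimity consensus after outlier removal.

    A tweet receives a label for a question iff all its remaining
    annotations agree and there are at least ``min_unanimous`` of them.
    Sentiment and organism labels are only stored for tweets whose relevance
    consensus is "relevant"; tweets without a relevance consensus are
    dropped.
    """
    ann = annotations[~annotations["annotator_id"].isin(set(outliers))]
    rows = []
    for tweet_id, group in ann.groupby("tweet_id", sort=True):
        n = len(group)

        def unanimous(q: str) -> Optional[str]:
            vals = group[q].unique()
            return vals[0] if len(vals) == 1 and n >= min_unanimous else None

        relevance = unanimous("relevance")
        if relevance is None:
            continue
        sentiment = organism = None
        if relevance == "relevant":
            sentiment = unanimous("sentiment")
            organism = unanimous("organism")
        rows.append({"tweet_id": tweet_id, "relevance": relevance,
                     "sentiment": sentiment, "organism": organism,
                     "n_annotators": n})
    return pd.DataFrame(rows, columns=["tweet_id", "relevance", "sentiment",
                                       "organism", "n_annotators"])
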
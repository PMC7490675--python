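"""Filtering chain from the raw stream to the annotation sample.

Order of operations follows the collection pipeline: anonymize first (so
placeholders never count as content words and dedup ignores handle/URL
variation), then drop short tweets, then duplicates, then draw a
monthly-stratified sample so no calendar month dominates the annotation set.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import PrepConfig

_URL_RE = re.compile(r"(?:https?://\S+|\bt\.co/\S+)")
_HANDLE_RE = re.compile(r"@\w+")
_EDGE_PUNCT_RE = re.compile(r"^[^0-9A-Za-z]+|[^0-9A-Za-z]+$")


def anonymize_text(text: str) -> str:
    """Replace handles with ``@<user>`` and URLs with ``<url>``.

    Idempotent: the placeholders themselves match neither pattern.
    """
    text = _URL_RE.sub("<url>", text)
    return _HANDLE_RE.sub("@<user>", text)


def tokenize(text: str) -> list[str]:
    """Whitespace tokenizer with edge-punctuation stripping.

    Tokens starting with ``#`` or ``@`` and the anonymization placeholders
    are dropped; remaining tokens are case-folded.
    """
    out = []
    for tok in text.split():
        if tok.startswith("#") or tok.startswith("@") or "<url>" in tok:
            continue
        core = _EDGE_PUNCT_RE.sub("", tok)
        if core:
            out.append(core.casefold())
    return out


def count_content_words(text: str, lexicon: Iterable[str], stopwords: Iterable[str]) -> int:
    """Number of tokens in the lexicon but not in the stop list (with
    multiplicity)."""
    lexicon = set(lexicon)
    stopwords = set(stopwords)
    return sum(1 for t in tokenize(text) if t in lexicon and t not in stopwords)


def filter_min_words(records: pd.DataFrame, config: PrepConfig) -> pd.DataFrame:
    """Keep records with at least ``min_content_words`` content words."""
    lexicon, stop = config.lexicon, config.stopwords
    mask = records["text"].map(
        lambda t: count_content_words(t, lexicon, stop) >= config.min_content_words
    )
    return records[mask]


def normalize_for_dedup(text: str) -> str:
    """Anonymized text with runs of whitespace collapsed (case preserved)."""
    return " ".join(anonymize_text(text).split())


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Drop retweets/quotes (``duplicate_of`` set) and exact text duplicates.

    Of each group of records sharing a normalized text, the earliest by
    ``created_at`` (ties by id) survives.  Input order is preserved.
    """
    own = records[records["duplicate_of"].isna()]
    norm = own["text"].map(normalize_for_dedup)
    ordered = own.assign(_norm=norm).sort_values(
        ["created_at", "id"], kind="stable"
    )
    keep_ids = set(ordered.drop_duplicates("_norm")["id"])
    return records[records["id"].isin(keep_ids)]


def stratified_monthly_sample(records: pd.DataFrame, quota: int,
                              seed: int = 0) -> pd.DataFrame:
    """Uniform sample without replacement of up to ``quota`` records per
    UTC calendar month; months with fewer records contribute all of them.

    Deterministic given ``seed``; output sorted by ``created_at`` (ties by
    id).
    """
    if len(records) == 0:
        raise ValueError("cannot sample from an empty record set")
    if quota < 1:
        raise ValueError(f"quota must be >= 1, got {quota}")
    rng = np.random.default_rng(seed)
    months = records["created_at"].dt.tz_convert("UTC").dt.tz_localize(None).dt.to_period("M")
    taken = []
    for _, group in records.groupby(months, sort=True):
        group = group.sort_values(["created_at", "id"], kind="stable")
        k = min(quota, len(group))
        pos = rng.choice(len(group), size=k, replace=False)
        taken.append(group.iloc[np.sort(pos)])
    out = pd.concat(taken)
    return out.sort_values(["created_at", "id"], kind="stable").reset_index(drop=True)


def prepare(records: pd.DataFrame, config: PrepConfig,
            quota: Optional[int] = None) -> dict[str, pd.DataFrame]:
    """Run the whole chain; returns the intermediate stages keyed
    ``anonymized`` -> ``filtered`` -> ``deduplicated`` -> ``sample``."""
    anon = records.assign(text=records["text"].map(anonymize_text))
    filtered = filter_min_words(anon, config)
    deduped = deduplicate(filtered)
    sample = stratified_monthly_sample(
        deduped, quota if quota is not None else config.monthly_quota, config.seed
    )
    return {"anonymized": anon, "filtered": filtered,
            "deduplicated": deduped, "sample": sample}
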
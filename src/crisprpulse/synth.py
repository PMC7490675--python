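"""Synthetic tweet streams and crowd annotations with known ground truth.

The generator emulates the statistical shape of a 6.5-year topical Twitter
stream: Poisson daily activity with event bursts, a positive/neutral/negative
mix whose expected index (P-N)/(P+N) drifts linearly in time, organism-class
mixtures, hashtag vocabularies, verbatim retweet/duplicate structure, and a
small off-topic contamination.  Texts are template sentences over a packaged
toy lexicon so that content-word counts and class-specific tokens are
controlled and every downstream stage has a recoverable target.

Trend and event effects act on the log-odds of the negative class and the
class vector is renormalised, which keeps probabilities valid for any slope
magnitude.  The per-day log-odds offset is solved in closed form so that the
expected sentiment index follows ``s0 + trend_slope * t`` exactly (t in years
from the stream start), making the injected slope directly recoverable.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnnotatorProfile, ConfigurationError, CorpusConfig
from .labels import (
    GENERATED_ORGANISMS,
    ORGANISMS,
    QUESTIONS,
    RELEVANCE,
    SENTIMENTS,
    SENTIMENT_WEIGHTS,
)

# --- template vocabulary -------------------------------------------------

CUES = {
    "positive": ["breakthrough", "hope", "promising", "exciting", "progress", "remarkable", "lifesaving"],
    "negative": ["risk", "dangerous", "scandal", "warning", "fear", "backlash", "unethical", "alarming"],
    "neutral": ["report", "update", "overview", "announcement", "summary", "explainer"],
}
VERBS = {
    "positive": ["hails", "celebrates", "advances", "welcomes"],
    "negative": ["condemns", "questions", "criticizes", "warns"],
    "neutral": ["describes", "reviews", "discusses", "covers"],
}
ORG_WORDS = {
    "humans": ["patients", "people", "volunteers"],
    "embryos": ["embryo", "embryos", "germline"],
    "animals": ["mice", "animals", "livestock"],
    "plants": ["crops", "plants", "rice"],
    "bacteria": ["bacteria", "microbes", "phage"],
    "not_specified": ["research", "technology", "laboratories"],
}
TOPICS = [
    "gene", "editing", "genome", "mutation", "therapy", "treatment",
    "disease", "dna", "sequence", "trial", "babies", "cells",
]
OFFTOPIC_ADJ = ["lovely", "great", "terrible", "pleasant"]
OFFTOPIC_NOUN = ["dinner", "lunch", "breakfast", "pasta", "football", "tennis", "coffee", "garden"]
OFFTOPIC_TIME = ["today", "tonight", "yesterday", "earlier"]

CORPUS_COLUMNS = [
    "id", "created_at", "text", "duplicate_of",
    "true_sentiment", "true_organism", "true_relevance",
]


def _solve_negative_logodds(class_probs: Sequence[float], target_index: float,
                            extra_shift: float = 0.0) -> np.ndarray:
    """Class probabilities after shifting the negative-class log-odds.

    The trend offset is chosen so the expected index (p+ - p-)/(p+ + p-)
    equals ``target_index``; ``extra_shift`` (events) is applied on top as a
    raw log-odds offset.
    """
    p_pos, p_neu, p_neg = class_probs
    s = float(np.clip(target_index, -0.999, 0.999))
    if p_neg == 0.0 or p_pos == 0.0:
        # Degenerate polar mix: no log-odds offset can move the index.
        w_neg = p_neg * np.exp(extra_shift)
    else:
        ratio = p_pos * (1.0 - s) / (p_neg * (1.0 + s))  # e^{delta_trend}
        w_neg = p_neg * ratio * np.exp(extra_shift)
    raw = np.array([p_pos, p_neu, w_neg])
    return raw / raw.sum()


def day_class_probs(config: CorpusConfig, day_offset: int) -> np.ndarray:
    """Sentiment class probabilities on day ``day_offset`` from the start."""
    p_pos, _, p_neg = config.class_probs
    polar = p_pos + p_neg
    s0 = (p_pos - p_neg) / polar if polar > 0 else 0.0
    target = s0 + config.trend_slope * (day_offset / 365.25)
    shift = 0.0
    day = config.start_date + dt.timedelta(days=day_offset)
    for ev in config.events:
        if ev.date <= day < ev.date + dt.timedelta(days=ev.duration_days):
            shift += ev.sentiment_shift
    return _solve_negative_logodds(config.class_probs, target, shift)


def _activity_multipliers(config: CorpusConfig) -> np.ndarray:
    mult = np.ones(config.n_days)
    for ev in config.events:
        i0 = (ev.date - config.start_date).days
        mult[i0:i0 + ev.duration_days] *= ev.activity_multiplier
    return mult


def simulate_daily_counts(config: CorpusConfig,
                          rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw per-day sentiment class counts without materialising texts.

    Returns a frame indexed by UTC day with columns n_positive, n_neutral,
    n_negative, n_total.  ``generate_corpus`` materialises records from the
    same draws, so both views of one config+seed agree.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mult = _activity_multipliers(config)
    totals = rng.poisson(config.base_rate * mult)
    rows = np.empty((config.n_days, 3), dtype=np.int64)
    for i in range(config.n_days):
        rows[i] = rng.multinomial(totals[i], day_class_probs(config, i))
    idx = pd.date_range(config.start_date, config.end_date, freq="D", tz="UTC")
    df = pd.DataFrame(rows, columns=["n_positive", "n_neutral", "n_negative"], index=idx)
    df.index.name = "date"
    df["n_total"] = df.sum(axis=1)
    return df


def _make_text(rng: np.random.Generator, sentiment: str, organism: str,
               relevant: bool, hashtag_vocab: dict[str, tuple[float, float]]) -> str:
    def pick(pool):
        return pool[rng.integers(len(pool))]

    if not relevant:
        form = rng.integers(3)
        if form == 0:
            text = f"just had a {pick(OFFTOPIC_ADJ)} {pick(OFFTOPIC_NOUN)} with friends {pick(OFFTOPIC_TIME)}"
        elif form == 1:
            text = f"the weather {pick(OFFTOPIC_TIME)} is {pick(OFFTOPIC_ADJ)} for a long walk outside"
        else:
            text = f"watching {pick(OFFTOPIC_NOUN)} and drinking {pick(OFFTOPIC_NOUN)} at home {pick(OFFTOPIC_TIME)}"
    elif rng.random() < 0.05:
        # fragment too short to annotate (exercises the content-word filter)
        text = f"{pick(CUES[sentiment])} crispr"
    else:
        cue = pick(CUES[sentiment])
        verb = pick(VERBS[sentiment])
        org = pick(ORG_WORDS[organism])
        t1 = pick(TOPICS)
        t2 = pick(TOPICS)
        form = rng.integers(4)
        if form == 0:
            text = f"{cue} in crispr {t1} {t2} for {org}"
        elif form == 1:
            text = f"new crispr study {verb} {t1} {t2} in {org}"
        elif form == 2:
            text = f"this {cue} about crispr {t1} in {org} is spreading fast"
        else:
            text = f"scientists say crispr {t1} {verb} {t2} outlook for {org}"

    if rng.random() < 0.2:
        text = f"@user{rng.integers(10_000)} " + text
    if rng.random() < 0.15:
        suffix = "".join(rng.choice(list("abcdefghij0123456789"), size=8))
        text += f" https://t.co/{suffix}"

    if hashtag_vocab and relevant:
        n_tags = min(int(rng.poisson(0.8)), 3)
        if n_tags:
            tags = list(hashtag_vocab)
            w = np.array([hashtag_vocab[t][0] * np.exp(hashtag_vocab[t][1] * SENTIMENT_WEIGHTS[sentiment])
                          for t in tags])
            chosen = rng.choice(len(tags), size=min(n_tags, len(tags)), replace=False, p=w / w.sum())
            text += " " + " ".join(tags[i] for i in chosen)
    return text


def generate_corpus(config: CorpusConfig) -> pd.DataFrame:
    """Generate the full record stream (the raw-collection analogue).

    Deterministic given ``config.seed``.  Duplicates copy an earlier
    original's text and truth labels verbatim and set ``duplicate_of``.
    """
    rng = np.random.default_rng(config.seed)
    daily = simulate_daily_counts(config, rng)

    org_names = [o for o in GENERATED_ORGANISMS if o in config.organism_probs]
    org_p = np.array([config.organism_probs[o] for o in org_names])

    records: list[dict] = []
    original_indices: list[int] = []  # positions of non-duplicate records
    seq = 0
    for day, row in zip(daily.index, daily.itertuples(index=False)):
        labels = (["positive"] * row.n_positive + ["neutral"] * row.n_neutral
                  + ["negative"] * row.n_negative)
        rng.shuffle(labels)
        seconds = np.sort(rng.integers(0, 86_400, size=len(labels)))
        for sent, sec in zip(labels, seconds):
            rec_id = f"t{seq:08d}"
            created = day + pd.Timedelta(seconds=int(sec))
            if original_indices and rng.random() < config.duplicate_rate:
                src = records[original_indices[rng.integers(len(original_indices))]]
                records.append({
                    "id": rec_id, "created_at": created, "text": src["text"],
                    "duplicate_of": src["id"],
                    "true_sentiment": src["true_sentiment"],
                    "true_organism": src["true_organism"],
                    "true_relevance": src["true_relevance"],
                })
            else:
                relevant = rng.random() >= config.irrelevant_rate
                organism = org_names[rng.choice(len(org_names), p=org_p)] if org_names else "not_specified"
                text = _make_text(rng, sent, organism, relevant, config.hashtag_vocab)
                records.append({
                    "id": rec_id, "created_at": created, "text": text,
                    "duplicate_of": None,
                    "true_sentiment": sent,
                    "true_organism": organism,
                    "true_relevance": "relevant" if relevant else "not_relevant",
                })
                original_indices.append(len(records) - 1)
            seq += 1
    df = pd.DataFrame(records, columns=CORPUS_COLUMNS)
    df["created_at"] = pd.to_datetime(df["created_at"], utc=True)
    return df


def generate_annotations(records: pd.DataFrame, profiles: Sequence[AnnotatorProfile],
                         redundancy: int = 3, seed: int = 0) -> pd.DataFrame:
    """Simulate the crowd: ``redundancy`` distinct annotators per tweet.

    Honest annotators answer each question truthfully with probability
    ``accuracy`` and otherwise pick a uniformly random *wrong* label; spammers
    answer uniformly at random.  Returns the long-format annotation table
    (tweet_id, annotator_id, relevance, sentiment, organism).
    """
    if redundancy < 1:
        raise ConfigurationError(f"redundancy must be >= 1, got {redundancy}")
    if len(profiles) < redundancy:
        raise ConfigurationError(
            f"need at least {redundancy} annotator profiles, got {len(profiles)}"
        )
    rng = np.random.default_rng(seed)
    weights = np.array([p.n_tasks_target for p in profiles], dtype=float)
    weights = weights / weights.sum()
    label_sets = {"relevance": RELEVANCE, "sentiment": SENTIMENTS, "organism": ORGANISMS}

    rows = []
    for rec in records.itertuples(index=False):
        truth = {"relevance": rec.true_relevance, "sentiment": rec.true_sentiment,
                 "organism": rec.true_organism}
        chosen = rng.choice(len(profiles), size=redundancy, replace=False, p=weights)
        for ci in chosen:
            prof = profiles[ci]
            answers = {}
            for q in QUESTIONS:
                options = label_sets[q]
                if prof.is_spammer:
                    answers[q] = options[rng.integers(len(options))]
                elif rng.random() < prof.accuracy:
                    answers[q] = truth[q]
                else:
                    wrong = [o for o in options if o != truth[q]]
                    answers[q] = wrong[rng.integers(len(wrong))]
            rows.append({"tweet_id": rec.id, "annotator_id": prof.annotator_id, **answers})
    return pd.DataFrame(rows, columns=["tweet_id", "annotator_id", *QUESTIONS])
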
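import datetime as dt

import pandas as pd
import pytest

import crisprpulse as cp
from crisprpulse import synth


@pytest.fixture(scope="session")
def quiet_corpus_config() -> cp.CorpusConfig:
    """Three flat months, no trend/events: a small well-behaved stream."""
    return cp.CorpusConfig(
        start_date=dt.date(2016, 1, 1), end_date=dt.date(2016, 3, 31),
        base_rate=40.0, trend_slope=0.0, events=[], seed=11,
    )


@pytest.fixture(scope="session")
def quiet_corpus(quiet_corpus_config) -> pd.DataFrame:
    return synth.generate_corpus(quiet_corpus_config)


def toy_corpus(rows) -> pd.DataFrame:
    """Build a corpus frame from (id, iso_time, text, duplicate_of, sentiment)
    tuples; organism defaults to not_specified, relevance to relevant."""
    recs = []
    for r in rows:
        rid, ts, text, dup, sent = r[:5]
        recs.append({
            "id": rid, "created_at": pd.Timestamp(ts, tz="UTC"), "text": text,
            "duplicate_of": dup, "true_sentiment": sent,
            "true_organism": r[5] if len(r) > 5 else "not_specified",
            "true_relevance": "relevant",
        })
    return pd.DataFrame(recs, columns=synth.CORPUS_COLUMNS)


@pytest.fixture
def perfect_profiles():
    return [cp.AnnotatorProfile(annotator_id=f"a{i}", accuracy=1.0) for i in range(5)]
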
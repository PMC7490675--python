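"""Configuration models for corpus simulation, preparation, QC and analysis.

All tunable constants of the pipeline live here, validated with pydantic so a
mis-specified YAML fails loudly with the offending field named.
"""

from __future__ import annotations

import datetime as dt
import re
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .labels import GENERATED_ORGANISMS


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


class EventSpec(BaseModel):
    """A discrete news-style burst: an activity spike with a sentiment shift.

    ``sentiment_shift`` is added to the log-odds of the negative sentiment
    class for the duration of the event; positive values push the stream
    negative.
    """

    date: dt.date
    activity_multiplier: float = Field(ge=1.0)
    sentiment_shift: float = 0.0
    duration_days: int = Field(default=1, ge=1)


class AnnotatorProfile(BaseModel):
    """Behavioural model of one crowd worker.

    Honest workers report the true label with probability ``accuracy`` and an
    (incorrect) label chosen uniformly otherwise; spammers answer uniformly at
    random over each question's label set, ignoring ``accuracy``.
    """

    annotator_id: str
    accuracy: float = Field(default=0.9, ge=0.0, le=1.0)
    is_spammer: bool = False
    n_tasks_target: float = Field(default=1.0, gt=0.0)


def _default_events() -> list[EventSpec]:
    # Bursts at the approximate dates of the major CRISPR news events of
    # 2016-2019 (first human trial, patent ruling, embryo-repair study,
    # side-effect warnings, gene-edited babies, DNA-malware story).  The last
    # three carry strong negative sentiment shifts, the earlier ones little.
    return [
        EventSpec(date=dt.date(2016, 11, 15), activity_multiplier=4.0, sentiment_shift=0.2, duration_days=3),
        EventSpec(date=dt.date(2017, 2, 15), activity_multiplier=4.0, sentiment_shift=0.0, duration_days=2),
        EventSpec(date=dt.date(2017, 8, 2), activity_multiplier=5.0, sentiment_shift=0.2, duration_days=3),
        EventSpec(date=dt.date(2018, 7, 16), activity_multiplier=4.0, sentiment_shift=1.2, duration_days=3),
        EventSpec(date=dt.date(2018, 11, 26), activity_multiplier=6.0, sentiment_shift=1.5, duration_days=5),
        EventSpec(date=dt.date(2019, 2, 15), activity_multiplier=4.0, sentiment_shift=2.0, duration_days=3),
    ]


def _default_hashtag_vocab() -> dict[str, tuple[float, float]]:
    # tag -> (base weight, sentiment affinity).  Affinity multiplies the
    # selection weight by exp(affinity * w) where w is the tweet's +1/0/-1
    # sentiment weight, so positive-affinity tags cluster on positive tweets.
    return {
        "#crispr": (10.0, 0.0),
        "#dna": (2.0, 0.1),
        "#science": (2.5, 0.3),
        "#biotech": (1.5, 0.2),
        "#geneediting": (1.5, 0.1),
        "#genomeediting": (1.2, 0.1),
        "#research": (1.0, 0.2),
        "#cancer": (0.8, 0.5),
        "#genetherapy": (0.6, 0.5),
        "#hiv": (0.5, 0.5),
        "#gmo": (0.6, -0.4),
        "#bioethics": (0.4, -0.5),
        "#geneeditsummit": (0.3, -0.5),
        "#crisprbabies": (0.5, -1.0),
    }


def _default_organism_probs() -> dict[str, float]:
    # Mix matching the predicted organism shares of the full corpus.
    return {
        "humans": 0.303,
        "embryos": 0.043,
        "animals": 0.076,
        "plants": 0.049,
        "bacteria": 0.024,
        "not_specified": 0.505,
    }


class CorpusConfig(BaseModel):
    """Generative model of a 6.5-year tweet stream with known ground truth.

    Defaults emulate the observed CRISPR stream: Jan 2013 - May 2019 (77
    calendar months), a 52.3/40.3/7.5 positive/neutral/negative mix, a
    -0.061 y^-1 drift of the expected sentiment index, news-event bursts,
    ~67% retweet/duplicate share, and a small off-topic contamination.
    """

    start_date: dt.date = dt.date(2013, 1, 1)
    end_date: dt.date = dt.date(2019, 5, 31)
    base_rate: float = Field(default=600.0, ge=0.0, description="expected tweets/day")
    class_probs: tuple[float, float, float] = (0.523, 0.403, 0.075)
    trend_slope: float = -0.061  # sentiment-index drift per year
    events: list[EventSpec] = Field(default_factory=_default_events)
    organism_probs: dict[str, float] = Field(default_factory=_default_organism_probs)
    hashtag_vocab: dict[str, tuple[float, float]] = Field(default_factory=_default_hashtag_vocab)
    duplicate_rate: float = Field(default=0.67, ge=0.0, lt=1.0)
    irrelevant_rate: float = Field(default=0.05, ge=0.0, lt=1.0)
    seed: int = 0

    @field_validator("class_probs")
    @classmethod
    def _probs_sum(cls, v: tuple[float, float, float]) -> tuple[float, float, float]:
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ConfigurationError(f"class_probs must be a probability vector, got {v}")
        return v

    @field_validator("organism_probs")
    @classmethod
    def _organisms(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(GENERATED_ORGANISMS)
        if unknown:
            raise ConfigurationError(f"organism_probs has unknown classes {sorted(unknown)}")
        if any(p < 0 for p in v.values()) or abs(sum(v.values()) - 1.0) > 1e-9:
            raise ConfigurationError(f"organism_probs must be a probability vector, got {v}")
        return v

    @model_validator(mode="after")
    def _dates_and_events(self) -> "CorpusConfig":
        if self.start_date >= self.end_date:
            raise ConfigurationError(
                f"start_date {self.start_date} must precede end_date {self.end_date}"
            )
        for ev in self.events:
            if not (self.start_date <= ev.date <= self.end_date):
                raise ConfigurationError(f"events: event on {ev.date} outside the corpus range")
        return self

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def _load_wordlist(name: str) -> frozenset[str]:
    text = resources.files("crisprpulse.data").joinpath(name).read_text(encoding="utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#"))


def default_lexicon() -> frozenset[str]:
    """Packaged English word list used for content-word counting (swappable)."""
    return _load_wordlist("lexicon.txt")


def default_stopwords() -> frozenset[str]:
    """Packaged stop-word list (swappable)."""
    return _load_wordlist("stopwords.txt")


class PrepConfig(BaseModel):
    """Thresholds of the filtering chain (content words, sampling quota)."""

    min_content_words: int = Field(default=3, ge=0)
    monthly_quota: int = Field(default=380, ge=1)
    seed: int = 0
    lexicon: frozenset[str] = Field(default_factory=default_lexicon)
    stopwords: frozenset[str] = Field(default_factory=default_stopwords)

    model_config = {"arbitrary_types_allowed": True}


class ThemeSpec(BaseModel):
    """A named theme expressed as a case-insensitive regular expression."""

    name: str
    pattern: str

    @model_validator(mode="after")
    def _compiles(self) -> "ThemeSpec":
        try:
            re.compile(self.pattern, re.IGNORECASE)
        except re.error as exc:
            raise ConfigurationError(f"theme {self.name!r}: pattern does not compile ({exc})")
        return self

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern, re.IGNORECASE)


def default_themes() -> list[ThemeSpec]:
    """The six stock themes (genome, baby, disease, embryo, treatment,
    mutation) with simple stem patterns; user configs replace them."""
    raw = yaml.safe_load(
        resources.files("crisprpulse.data").joinpath("themes.yaml").read_text(encoding="utf-8")
    )
    return [ThemeSpec(name=k, pattern=v) for k, v in raw.items()]


class QCConfig(BaseModel):
    """Annotation quality-control thresholds."""

    sd_mult: float = Field(default=3.0, gt=0)
    min_possible: int = Field(default=20, ge=1)
    min_tasks: int = Field(default=3, ge=1)
    min_unanimous: int = Field(default=3, ge=1)


class AnalysisConfig(BaseModel):
    """Time-series and topical analysis parameters."""

    window: int = Field(default=7, ge=1)
    rel_prominence_min: float = Field(default=0.2, gt=0, le=1)
    min_cell: int = Field(default=100, ge=1)
    top_k: int = Field(default=15, ge=1)
    months_observed_final_year: Optional[int] = Field(default=None, ge=1, le=12)

    @field_validator("window")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ConfigurationError(f"window must be odd, got {v}")
        return v


class AnnotationJobConfig(BaseModel):
    """Shape of the simulated crowd: pool composition and redundancy."""

    n_honest: int = Field(default=24, ge=1)
    honest_accuracy: float = Field(default=0.9, ge=0, le=1)
    n_spammers: int = Field(default=1, ge=0)
    redundancy: int = Field(default=3, ge=1)

    def profiles(self) -> list[AnnotatorProfile]:
        pool = [
            AnnotatorProfile(annotator_id=f"honest{i:03d}", accuracy=self.honest_accuracy)
            for i in range(self.n_honest)
        ]
        pool += [
            AnnotatorProfile(annotator_id=f"spammer{i:03d}", is_spammer=True)
            for i in range(self.n_spammers)
        ]
        return pool


class RunConfig(BaseModel):
    """End-to-end run: inputs (or simulation), thresholds, output directory."""

    outdir: str = "runs/run0"
    corpus_path: Optional[str] = None  # JSONL; simulated when absent
    annotations_path: Optional[str] = None  # CSV; simulated when absent
    themes_path: Optional[str] = None  # YAML; packaged defaults when absent
    corpus: CorpusConfig = Field(default_factory=CorpusConfig)
    prep: PrepConfig = Field(default_factory=PrepConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    annotation_job: AnnotationJobConfig = Field(default_factory=AnnotationJobConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    write_predictions: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})
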
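"""Classifier slots, a self-contained baseline, evaluation, and the cascade.

The production-scale transformer models that filled the relevance, sentiment
and organism slots are external artifacts; the pipeline only needs the
*contract* (fit/predict over a fixed label set) plus a dependency-free
baseline to exercise it.  The baseline is a multinomial token-count scorer:

    score(c | text) = log prior(c) + sum_t log (count(t, c) + a) / (N_c + a V)

with additive smoothing ``a``, vocabulary size ``V`` and argmax prediction,
ties broken by label-set order.  Tokens unseen in training carry no evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .labels import SENTIMENTS
from .prep import tokenize


class NotFittedError(RuntimeError):
    pass


class MultinomialTextClassifier:
    """Multinomial token-count scorer satisfying the classifier contract."""

    def __init__(self, label_set: Sequence[str], smoothing: float = 1.0):
        if smoothing <= 0:
            raise ValueError("smoothing must be positive")
        self.label_set = list(label_set)
        self.smoothing = float(smoothing)
        self.vocab_: Optional[dict[str, int]] = None
        self.log_like_: Optional[np.ndarray] = None  # labels x vocab
        self.log_prior_: Optional[np.ndarray] = None

    # -- training ---------------------------------------------------------
    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> "MultinomialTextClassifier":
        if len(texts) == 0:
            raise ValueError("empty training set")
        if len(texts) != len(labels):
            raise ValueError("texts and labels differ in length")
        unknown = set(labels) - set(self.label_set)
        if unknown:
            raise ValueError(f"labels outside the label set: {sorted(unknown)}")
        label_index = {c: i for i, c in enumerate(self.label_set)}
        docs = [tokenize(t) for t in texts]
        vocab: dict[str, int] = {}
        for doc in docs:
            for tok in doc:
                vocab.setdefault(tok, len(vocab))
        counts = np.zeros((len(self.label_set), len(vocab)))
        class_n = np.zeros(len(self.label_set))
        for doc, lab in zip(docs, labels):
            ci = label_index[lab]
            class_n[ci] += 1
            for tok in doc:
                counts[ci, vocab[tok]] += 1
        a, V = self.smoothing, len(vocab)
        totals = counts.sum(axis=1, keepdims=True)
        self.log_like_ = np.log(counts + a) - np.log(totals + a * V)
        with np.errstate(divide="ignore"):
            self.log_prior_ = np.log(class_n / class_n.sum())  # -inf for absent classes
        self.vocab_ = vocab
        return self

    # -- prediction -------------------------------------------------------
    def _scores(self, texts: Sequence[str]) -> np.ndarray:
        if self.vocab_ is None:
            raise NotFittedError("classifier has not been trained")
        rows, cols, data = [], [], []
        for i, t in enumerate(texts):
            for tok in tokenize(t):
                j = self.vocab_.get(tok)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    data.append(1.0)
        X = sparse.csr_matrix((data, (rows, cols)),
                              shape=(len(texts), len(self.vocab_)))
        return X @ self.log_like_.T + self.log_prior_

    def predict(self, texts: Sequence[str]) -> list[str]:
        scores = self._scores(texts)
        return [self.label_set[i] for i in np.argmax(scores, axis=1)]

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        if self.vocab_ is None:
            raise NotFittedError("classifier has not been trained")
        return json.dumps({
            "label_set": self.label_set,
            "smoothing": self.smoothing,
            "vocab": self.vocab_,
            "log_like": self.log_like_.tolist(),
            "log_prior": [None if np.isneginf(v) else v for v in self.log_prior_],
        })

    @classmethod
    def from_json(cls, payload: str) -> "MultinomialTextClassifier":
        d = json.loads(payload)
        clf = cls(d["label_set"], d["smoothing"])
        clf.vocab_ = d["vocab"]
        clf.log_like_ = np.array(d["log_like"])
        clf.log_prior_ = np.array([-np.inf if v is None else v for v in d["log_prior"]])
        return clf


def train_baseline(texts: Sequence[str], labels: Sequence[str], smoothing: float = 1.0,
                   label_set: Optional[Sequence[str]] = None) -> MultinomialTextClassifier:
    """Train the baseline scorer; ``label_set`` defaults to the labels in
    order of first appearance (classes absent from training are allowed in an
    explicit label set but are never predicted)."""
    if len(texts) == 0:
        raise ValueError("empty training set")
    if label_set is None:
        label_set = list(dict.fromkeys(labels))
    return MultinomialTextClassifier(label_set, smoothing).fit(texts, labels)


@dataclass
class EvalReport:
    """Per-class precision/recall/F1, macro-F1 and the confusion matrix
    (rows = true classes, columns = predicted, in label-set order)."""

    label_set: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    macro_f1: float
    confusion: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "label_set": self.label_set,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "macro_f1": self.macro_f1,
            "confusion": self.confusion.tolist(),
        }


def macro_f1(true_labels: Sequence[str], predicted_labels: Sequence[str],
             label_set: Sequence[str]) -> EvalReport:
    """Macro-averaged F1 with the absent-class-F1=0 convention."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    label_set = list(label_set)
    p, r, f, _ = precision_recall_fscore_support(
        true_labels, predicted_labels, labels=label_set, zero_division=0
    )
    cm = confusion_matrix(true_labels, predicted_labels, labels=label_set)
    return EvalReport(
        label_set=label_set,
        precision=dict(zip(label_set, p.tolist())),
        recall=dict(zip(label_set, r.tolist())),
        f1=dict(zip(label_set, f.tolist())),
        macro_f1=float(f.mean()),
        confusion=cm,
    )


def train_test_split_idx(n: int, test_frac: float = 0.2, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled unstratified 80/20 split indices, fixed seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_frac))
    return perm[n_test:], perm[:n_test]


def cascade_predict(relevance_model: MultinomialTextClassifier,
                    sentiment_model: MultinomialTextClassifier,
                    organism_model: MultinomialTextClassifier,
                    records: pd.DataFrame) -> pd.DataFrame:
    """Relevance-gated prediction cascade.

    Relevance is predicted for every record; records predicted not relevant
    are removed, and sentiment/organism are predicted only for the
    survivors.  The returned corpus carries pred_relevance, pred_sentiment,
    pred_organism and a provenance marker naming the producing slot.
    """
    texts = records["text"].tolist()
    rel = relevance_model.predict(texts)
    out = records.assign(pred_relevance=rel)
    out = out[out["pred_relevance"] == "relevant"].copy()
    survivors = out["text"].tolist()
    out["pred_sentiment"] = sentiment_model.predict(survivors) if len(out) else []
    out["pred_organism"] = organism_model.predict(survivors) if len(out) else []
    out.attrs["provenance"] = {"relevance": "M_R", "sentiment": "M_S", "organism": "M_O"}
    return out


def class_proportions(corpus: Union[pd.DataFrame, Mapping[str, int], pd.Series],
                      label_set: Sequence[str] = tuple(SENTIMENTS),
                      column: str = "pred_sentiment") -> dict[str, float]:
    """Percentage share per class, rounded half-up to one decimal.

    Accepts a labeled corpus (counts taken from ``column``) or a mapping of
    precomputed class counts.
    """
    if isinstance(corpus, pd.DataFrame):
        counts = corpus[column].value_counts()
    else:
        counts = pd.Series(dict(corpus), dtype=float)
    total = counts.sum()
    if total == 0 or len(counts) == 0:
        raise ValueError("empty corpus")
    out = {}
    for lab in label_set:
        pct = float(100.0 * counts.get(lab, 0) / total)
        out[lab] = float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out
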
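"""Baseline classifier, macro-F1 evaluation, cascade, class proportions."""

import numpy as np
import pandas as pd
import pytest

from crisprpulse import classify, synth
from crisprpulse.classify import (
    MultinomialTextClassifier,
    cascade_predict,
    class_proportions,
    macro_f1,
    train_baseline,
)
from conftest import toy_corpus


SEPARABLE = (
    ["hope cure breakthrough", "cure hope wonderful", "risk danger scandal",
     "danger risk awful"],
    ["pos", "pos", "neg", "neg"],
)


class TestBaseline:
    def test_separable_training_set_reproduced(self):
        texts, labels = SEPARABLE
        clf = train_baseline(texts, labels)
        assert clf.predict(texts) == labels

    def test_unseen_tokens_tie_break_first_label(self):
        texts, labels = SEPARABLE
        clf = train_baseline(texts, labels, label_set=["pos", "neg"])
        assert clf.predict(["zzz qqq unseen"]) == ["pos"]
        clf_r = train_baseline(texts, labels, label_set=["neg", "pos"])
        assert clf_r.predict(["zzz qqq unseen"]) == ["neg"]

    def test_empty_text_prior_argmax(self):
        clf = train_baseline(["up good", "up fine", "down bad"],
                             ["pos", "pos", "neg"])
        assert clf.predict([""]) == ["pos"]

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_baseline([], [])

    def test_untrained_predict_rejected(self):
        clf = MultinomialTextClassifier(["a", "b"])
        with pytest.raises(classify.NotFittedError):
            clf.predict(["x"])

    def test_json_round_trip(self):
        texts, labels = SEPARABLE
        clf = train_baseline(texts, labels)
        clone = MultinomialTextClassifier.from_json(clf.to_json())
        probe = ["hope risk", "danger cure hope", ""]
        assert clone.predict(probe) == clf.predict(probe)

    def test_matches_sklearn_multinomial_nb(self):
        """Cross-check the scorer against sklearn's multinomial NB on a
        random token corpus (same smoothing, same tokenization)."""
        from sklearn.feature_extraction.text import CountVectorizer
        from sklearn.naive_bayes import MultinomialNB

        rng = np.random.default_rng(1)
        vocab = [f"w{i}" for i in range(30)]
        texts, labels = [], []
        for _ in range(120):
            lab = rng.integers(3)
            # class-dependent token distribution
            p = np.roll(np.array([5.0] * 10 + [1.0] * 20), 10 * lab)
            texts.append(" ".join(rng.choice(vocab, size=8, p=p / p.sum())))
            labels.append(f"c{lab}")
        clf = train_baseline(texts, labels, smoothing=1.0, label_set=["c0", "c1", "c2"])
        vec = CountVectorizer(vocabulary={w: i for i, w in enumerate(vocab)},
                              tokenizer=str.split, preprocessor=lambda x: x)
        skl = MultinomialNB(alpha=1.0).fit(vec.transform(texts), labels)
        probe = [" ".join(rng.choice(vocab, size=6)) for _ in range(200)]
        ours = clf.predict(probe)
        theirs = list(skl.predict(vec.transform(probe)))
        agreement = np.mean([a == b for a, b in zip(ours, theirs)])
        assert agreement >= 0.99  # ties may break differently

    def test_sanity_floor_on_separable_synthetic_classes(self):
        """Token-separable classes (disjoint cue vocabulary, shared filler)
        with >=50 examples per class give macro-F1 >= 0.95."""
        rng = np.random.default_rng(8)
        pools = {"positive": ["hope", "cure", "breakthrough", "promising"],
                 "neutral": ["report", "update", "overview", "summary"],
                 "negative": ["risk", "danger", "scandal", "warning"]}
        shared = ["crispr", "gene", "editing", "study", "news", "people"]
        texts, labels = [], []
        for lab, cues in pools.items():
            for _ in range(80):
                words = list(rng.choice(cues, size=2)) + list(rng.choice(shared, size=5))
                rng.shuffle(words)
                texts.append(" ".join(words))
                labels.append(lab)
        perm = rng.permutation(len(texts))
        texts = [texts[i] for i in perm]
        labels = [labels[i] for i in perm]
        tr, te = classify.train_test_split_idx(len(texts), 0.2, seed=0)
        clf = train_baseline([texts[i] for i in tr], [labels[i] for i in tr],
                             label_set=["positive", "neutral", "negative"])
        rep = macro_f1([labels[i] for i in te], clf.predict([texts[i] for i in te]),
                       ["positive", "neutral", "negative"])
        assert rep.macro_f1 >= 0.95


class TestMacroF1:
    def test_perfect_predictions(self):
        rep = macro_f1(["a", "b", "a"], ["a", "b", "a"], ["a", "b"])
        assert rep.macro_f1 == 1.0

    def test_all_wrong_binary(self):
        rep = macro_f1(["a", "b"], ["b", "a"], ["a", "b"])
        assert rep.macro_f1 == 0.0

    def test_frozen_confusion_example(self):
        # confusion [[8,2],[3,7]]: true 'a' predicted a 8 / b 2; true 'b' 3 / 7
        true = ["a"] * 10 + ["b"] * 10
        pred = ["a"] * 8 + ["b"] * 2 + ["a"] * 3 + ["b"] * 7
        rep = macro_f1(true, pred, ["a", "b"])
        assert rep.confusion.tolist() == [[8, 2], [3, 7]]
        assert rep.f1["a"] == pytest.approx(0.761904761904762)
        assert rep.f1["b"] == pytest.approx(0.7368421052631577)
        assert rep.macro_f1 == pytest.approx(0.7493734335839599)

    def test_absent_class_contributes_zero(self):
        rep = macro_f1(["a", "a"], ["a", "a"], ["a", "ghost"])
        assert rep.f1["ghost"] == 0.0
        assert rep.macro_f1 == pytest.approx(0.5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        true = list(rng.choice(["a", "b", "c"], size=60))
        pred = list(rng.choice(["a", "b", "c"], size=60))
        base = macro_f1(true, pred, ["a", "b", "c"]).macro_f1
        perm = rng.permutation(60)
        shuffled = macro_f1([true[i] for i in perm], [pred[i] for i in perm],
                            ["a", "b", "c"]).macro_f1
        assert shuffled == pytest.approx(base)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            macro_f1(["a"], ["a", "b"], ["a", "b"])


def _toy_models():
    rel = train_baseline(["crispr gene talk", "dinner pasta nice"],
                         ["relevant", "not_relevant"])
    sent = train_baseline(["hope cure", "risk danger", "report update"],
                          ["positive", "negative", "neutral"])
    org = train_baseline(["patients people", "mice animals"], ["humans", "animals"])
    return rel, sent, org


class TestCascade:
    def test_survivor_count_and_gating(self):
        rel, sent, org = _toy_models()
        corpus = toy_corpus(
            [(f"r{k}", f"2016-01-0{k+1}", "crispr gene hope cure", None, "positive")
             for k in range(7)]
            + [(f"n{k}", f"2016-02-0{k+1}", "dinner pasta tonight", None, "neutral")
               for k in range(3)])
        out = cascade_predict(rel, sent, org, corpus)
        assert len(out) == 7
        assert set(out["id"]) == {f"r{k}" for k in range(7)}
        assert out["pred_sentiment"].notna().all()

    def test_everything_relevant_passes_through(self):
        rel, sent, org = _toy_models()
        corpus = toy_corpus([("a", "2016-01-01", "crispr gene hope", None, "positive"),
                             ("b", "2016-01-02", "crispr talk risk", None, "negative")])
        assert len(cascade_predict(rel, sent, org, corpus)) == 2

    def test_everything_filtered_gives_empty(self):
        rel, sent, org = _toy_models()
        corpus = toy_corpus([("a", "2016-01-01", "dinner pasta nice", None, "neutral")])
        assert len(cascade_predict(rel, sent, org, corpus)) == 0


class TestClassProportions:
    def test_exact_quarters(self):
        assert class_proportions({"positive": 1, "neutral": 1, "negative": 2}) == {
            "positive": 25.0, "neutral": 25.0, "negative": 50.0}

    def test_single_class(self):
        out = class_proportions({"positive": 42})
        assert out["positive"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_proportions({})

    def test_sums_to_100_within_rounding(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            counts = {k: int(v) for k, v in zip(
                ("positive", "neutral", "negative"), rng.integers(1, 10_000, 3))}
            out = class_proportions(counts)
            assert abs(sum(out.values()) - 100.0) <= 0.3
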
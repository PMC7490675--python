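"""End-to-end orchestration: simulate/load -> prep -> QC -> train -> cascade
-> time series -> topics, with a manifest and a machine-readable run report.

All randomness flows from the single ``RunConfig.seed`` through named
substreams, so a rerun with the same config reproduces every output file
byte for byte.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io, prep, qc, synth, timeseries, topical
from .classify import (
    MultinomialTextClassifier,
    cascade_predict,
    class_proportions,
    macro_f1,
    train_baseline,
    train_test_split_idx,
)
from .config import RunConfig, default_themes
from .labels import ORGANISMS, RELEVANCE, SENTIMENTS

log = logging.getLogger("crisprpulse")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def subseed(master: int, name: str) -> int:
    """Deterministic named substream seed derived from the master seed."""
    ss = np.random.SeedSequence([master, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    kappa: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    trend: dict = field(default_factory=dict)
    peaks: list = field(default_factory=list)
    proportions: dict = field(default_factory=dict)
    yearly_tests: list = field(default_factory=list)
    manifest: list = field(default_factory=list)
    config: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _train_slot(texts: list[str], labels: list[str], label_set: list[str],
                seed: int, stage: str) -> tuple[MultinomialTextClassifier, dict]:
    present = [c for c in label_set if c in set(labels)]
    if len(present) < 2:
        raise PipelineStageError(stage, "TOO_FEW_CLASSES",
                                 f"training data covers classes {present} only")
    tr, te = train_test_split_idx(len(texts), 0.2, seed)
    if len(te) == 0 or len(tr) == 0:
        raise PipelineStageError(stage, "EMPTY_SPLIT", "not enough data to split")
    texts_arr = np.asarray(texts, dtype=object)
    labels_arr = np.asarray(labels, dtype=object)
    # guard: the train split itself must cover >= 2 classes
    if len(set(labels_arr[tr])) < 2:
        raise PipelineStageError(stage, "TOO_FEW_CLASSES", "train split single-class")
    model = train_baseline(list(texts_arr[tr]), list(labels_arr[tr]), label_set=present)
    report = macro_f1(list(labels_arr[te]), model.predict(list(texts_arr[te])), present)
    return model, report.to_dict()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts under
    ``config.outdir``; identical config+seed reproduces identical bytes."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = RunReport()
    from . import __version__
    report.versions = {"crisprpulse": __version__}
    report.config = config.model_dump(mode="json")

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        entry = io.write_table(path, frame)
        written.append(path)
        report.manifest.append(entry)

    try:
        # --- corpus ----------------------------------------------------
        stage = "corpus"
        if config.corpus_path:
            corpus = io.read_corpus(config.corpus_path)
        else:
            cc = config.corpus.model_copy(update={"seed": subseed(config.seed, "corpus")})
            corpus = synth.generate_corpus(cc)
        if len(corpus) == 0:
            raise PipelineStageError(stage, "EMPTY_STAGE", "no records in the corpus")
        report.counts["d0"] = len(corpus)
        log.info("corpus: %d records", len(corpus))

        # --- preparation ----------------------------------------------
        stage = "prep"
        anon = corpus.assign(text=corpus["text"].map(prep.anonymize_text))
        d1 = prep.filter_min_words(anon, config.prep)
        report.counts["d1"] = len(d1)
        if len(d1) == 0:
            raise PipelineStageError("prep.filter_min_words", "EMPTY_STAGE",
                                     "no record has enough content words")
        d2 = prep.deduplicate(d1)
        report.counts["d2"] = len(d2)
        if len(d2) == 0:
            raise PipelineStageError("prep.deduplicate", "EMPTY_STAGE", "nothing survived dedup")
        s0 = prep.stratified_monthly_sample(
            d2, config.prep.monthly_quota, subseed(config.seed, "sampling"))
        report.counts["s0"] = len(s0)
        assert report.counts["d0"] >= report.counts["d1"] >= report.counts["d2"], \
            "filtering stages must be monotone non-increasing"
        log.info("prep: d1=%d d2=%d s0=%d", len(d1), len(d2), len(s0))

        # --- annotation ------------------------------------------------
        stage = "annotation"
        if config.annotations_path:
            annotations = io.read_annotations(config.annotations_path)
        else:
            annotations = synth.generate_annotations(
                s0, config.annotation_job.profiles(),
                redundancy=config.annotation_job.redundancy,
                seed=subseed(config.seed, "annotation"))
        report.counts["a0"] = len(annotations)

        # --- QC --------------------------------------------------------
        stage = "qc"
        stats = qc.raw_agreement(annotations, "relevance")
        flags = qc.flag_outlier_annotators(
            stats, config.qc.sd_mult, config.qc.min_possible, config.qc.min_tasks)
        stats["flagged"] = stats["annotator_id"].isin(flags)
        emit("qc_report.csv", stats)
        for question in ("relevance", "sentiment"):
            try:
                report.kappa[question] = qc.kappa_for_question(annotations, question, flags)
            except (ValueError, qc.DegenerateAgreementError) as exc:
                report.kappa[question] = None
                log.warning("kappa (%s) undefined: %s", question, exc)
        consensus = qc.consensus_labels(annotations, flags, config.qc.min_unanimous)
        report.counts["a1_relevance"] = int(consensus["relevance"].notna().sum())
        report.counts["a2_sentiment"] = int(consensus["sentiment"].notna().sum())
        report.counts["a2_organism"] = int(consensus["organism"].notna().sum())
        emit("consensus.csv", consensus)
        log.info("qc: flagged=%d kappa=%s", len(flags), report.kappa)

        # --- training --------------------------------------------------
        stage = "train"
        texts_by_id = dict(zip(s0["id"], s0["text"]))
        cons = consensus.assign(text=consensus["tweet_id"].map(texts_by_id))
        cons = cons[cons["text"].notna()]
        if len(cons) == 0:
            raise PipelineStageError(stage, "EMPTY_STAGE", "no consensus-labelled texts")

        m_r, ev_r = _train_slot(cons["text"].tolist(), cons["relevance"].tolist(),
                                RELEVANCE, subseed(config.seed, "split_relevance"), stage)
        sent = cons[cons["sentiment"].notna()]
        m_s, ev_s = _train_slot(sent["text"].tolist(), sent["sentiment"].tolist(),
                                SENTIMENTS, subseed(config.seed, "split_sentiment"), stage)
        org = cons[cons["organism"].notna()]
        m_o, ev_o = _train_slot(org["text"].tolist(), org["organism"].tolist(),
                                ORGANISMS, subseed(config.seed, "split_organism"), stage)
        report.evaluation = {"relevance": ev_r, "sentiment": ev_s, "organism": ev_o}
        log.info("train: macro-F1 R=%.3f S=%.3f O=%.3f", ev_r["macro_f1"],
                 ev_s["macro_f1"], ev_o["macro_f1"])

        # --- prediction cascade ---------------------------------------
        stage = "predict"
        p2 = cascade_predict(m_r, m_s, m_o, d1)
        report.counts["p0"] = len(d1)
        report.counts["p1"] = len(p2)
        if len(p2) == 0:
            raise PipelineStageError(stage, "EMPTY_STAGE", "everything predicted not relevant")
        report.proportions = class_proportions(p2)
        if config.write_predictions:
            path = outdir / "p2.jsonl"
            io.write_corpus(p2, path)
            written.append(path)
            report.manifest.append({"path": path.name, "rows": len(p2),
                                    "sha256": io.sha256_of(path)})
        log.info("predict: p1=%d proportions=%s", len(p2), report.proportions)

        # --- time series ----------------------------------------------
        stage = "timeseries"
        daily = timeseries.daily_counts(p2)
        index = timeseries.sentiment_index(daily, config.analysis.window)
        trend = timeseries.fit_linear_trend(index)
        report.trend = {"slope_per_year": trend.slope, "stderr_per_year": trend.stderr,
                        "intercept": trend.intercept}
        peaks = timeseries.detect_peaks(index["a"], config.analysis.rel_prominence_min)
        report.peaks = [{"date": str(p.day.date()), "height": p.height,
                         "prominence": p.prominence, "rel_prominence": p.rel_prominence}
                        for p in peaks]
        try:
            yearly, tests = timeseries.yearly_sentiment_tests(p2)
            emit("yearly_sentiment.csv", yearly)
            report.yearly_tests = json.loads(tests.to_json(orient="records"))
        except ValueError as exc:
            log.warning("yearly tests skipped: %s", exc)
        index_out = daily.join(index).reset_index()
        index_out["date"] = index_out["date"].dt.strftime("%Y-%m-%d")
        emit("index.csv", index_out)
        pk = timeseries.peaks_frame(peaks)
        pk["date"] = [str(d.date()) for d in pk["date"]] if len(pk) else pk["date"]
        emit("peaks.csv", pk)
        log.info("timeseries: slope=%.4f/y (se %.4f), %d peaks",
                 trend.slope, trend.stderr, len(peaks))

        # --- topical ---------------------------------------------------
        stage = "topical"
        org_matrix = topical.organism_month_matrix(p2, config.analysis.min_cell)
        org_matrix = org_matrix.assign(month=org_matrix["month"].astype(str))
        emit("organism_month.csv", org_matrix)
        tags = topical.hashtag_year_stats(p2, config.analysis.top_k)
        emit("hashtags_year.csv", tags)
        themes = (io.load_themes(config.themes_path) if config.themes_path
                  else default_themes())
        flags_m = topical.match_themes(p2, themes)
        months_obs = config.analysis.months_observed_final_year
        if months_obs is None:
            months_obs = int(p2["created_at"].max().month)
        themes_year = topical.theme_year_counts(flags_m, p2, months_obs)
        emit("themes_year.csv", themes_year)

        # --- report ----------------------------------------------------
        stage = "report"
        path = outdir / "report.json"
        path.write_text(report.to_json() + "\n", encoding="utf-8")
        return report
    except PipelineStageError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(stage, "STAGE_FAILURE", str(exc)) from exc
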
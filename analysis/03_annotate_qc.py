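"""Simulate the crowd annotation of the sample and clean it: raw agreement,
outlier screening, Fleiss' kappa, unanimity consensus with relevance gate.

Writes results/qc_report.csv, results/qc_summary.json and the consensus
labels used for training.
"""

import json

from common import ANNOTATION_JOB, QC_CONFIG, RESULTS, SCRATCH, SEED, ensure_dirs

from crisprpulse import io, qc, synth


def main() -> None:
    ensure_dirs()
    sample = io.read_corpus(SCRATCH / "sample.jsonl")
    annotations = synth.generate_annotations(
        sample, ANNOTATION_JOB.profiles(), ANNOTATION_JOB.redundancy, seed=SEED + 1)
    io.write_annotations(annotations, SCRATCH / "annotations.csv")

    stats = qc.raw_agreement(annotations, "relevance")
    flags = qc.flag_outlier_annotators(stats, QC_CONFIG.sd_mult,
                                       QC_CONFIG.min_possible, QC_CONFIG.min_tasks)
    stats["flagged"] = stats["annotator_id"].isin(flags)
    io.write_table(RESULTS / "qc_report.csv", stats)

    kappa = {q: qc.kappa_for_question(annotations, q, flags)
             for q in ("relevance", "sentiment", "organism")}
    consensus = qc.consensus_labels(annotations, flags, QC_CONFIG.min_unanimous)
    io.write_table(SCRATCH / "consensus.csv", consensus)

    summary = {"n_annotations": len(annotations),
               "n_annotators": stats.shape[0],
               "flagged_annotators": sorted(flags),
               "fleiss_kappa": kappa,
               "n_consensus_relevance": int(consensus["relevance"].notna().sum()),
               "n_consensus_sentiment": int(consensus["sentiment"].notna().sum()),
               "n_consensus_organism": int(consensus["organism"].notna().sum())}
    (RESULTS / "qc_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"annotations: {len(annotations)} rows from {stats.shape[0]} annotators; "
          f"flagged: {sorted(flags)}")
    print("Fleiss kappa:", {k: round(v, 3) for k, v in kappa.items()})
    print(f"consensus: relevance={summary['n_consensus_relevance']} "
          f"sentiment={summary['n_consensus_sentiment']} "
          f"organism={summary['n_consensus_organism']}")


if __name__ == "__main__":
    main()
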
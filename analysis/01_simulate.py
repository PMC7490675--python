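"""Generate the synthetic 77-month tweet stream with known ground truth.

Writes scratch/analysis/corpus.jsonl and prints the stream's composition.
"""

from common import CORPUS_CONFIG, SCRATCH, ensure_dirs

from crisprpulse import io, synth


def main() -> None:
    ensure_dirs()
    corpus = synth.generate_corpus(CORPUS_CONFIG)
    io.write_corpus(corpus, SCRATCH / "corpus.jsonl")
    mix = corpus["true_sentiment"].value_counts(normalize=True).round(3)
    print(f"generated {len(corpus)} records over "
          f"{CORPUS_CONFIG.start_date} .. {CORPUS_CONFIG.end_date}")
    print(f"true sentiment mix: {mix.to_dict()}")
    print(f"duplicate share: {corpus['duplicate_of'].notna().mean():.3f}")
    print(f"off-topic share (originals): "
          f"{(corpus[corpus['duplicate_of'].isna()]['true_relevance'] == 'not_relevant').mean():.3f}")


if __name__ == "__main__":
    main()
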
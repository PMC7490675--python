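"""Filtering chain: anonymize, require >= 3 content words, deduplicate,
monthly-stratified annotation sample.

Reads scratch/analysis/corpus.jsonl; writes the sample and the stage counts.
"""

import json

from common import PREP_CONFIG, RESULTS, SCRATCH, ensure_dirs

from crisprpulse import io, prep


def main() -> None:
    ensure_dirs()
    corpus = io.read_corpus(SCRATCH / "corpus.jsonl")
    stages = prep.prepare(corpus, PREP_CONFIG)
    io.write_corpus(stages["deduplicated"], SCRATCH / "deduplicated.jsonl")
    io.write_corpus(stages["filtered"], SCRATCH / "filtered.jsonl")
    io.write_corpus(stages["sample"], SCRATCH / "sample.jsonl")
    counts = {"d0_raw": len(corpus), "d1_filtered": len(stages["filtered"]),
              "d2_deduplicated": len(stages["deduplicated"]),
              "s0_sample": len(stages["sample"])}
    (RESULTS / "prep_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
    print("filtering chain:", counts)
    print(f"short tweets removed: {counts['d0_raw'] - counts['d1_filtered']}; "
          f"duplicates removed: {counts['d1_filtered'] - counts['d2_deduplicated']}")


if __name__ == "__main__":
    main()
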
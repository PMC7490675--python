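"""Relevance-gated cascade over the filtered corpus: predict relevance for
every record, drop off-topic predictions, then predict sentiment and
organism for the survivors.

Writes scratch/analysis/p2.jsonl and results/proportions.json.
"""

import json

from common import RESULTS, SCRATCH, ensure_dirs

from crisprpulse import io
from crisprpulse.classify import (MultinomialTextClassifier, cascade_predict,
                                  class_proportions)


def main() -> None:
    ensure_dirs()
    corpus = io.read_corpus(SCRATCH / "filtered.jsonl")
    models = {slot: MultinomialTextClassifier.from_json(
        (SCRATCH / "models" / f"model_{slot}.json").read_text())
        for slot in ("relevance", "sentiment", "organism")}
    p2 = cascade_predict(models["relevance"], models["sentiment"],
                         models["organism"], corpus)
    io.write_corpus(p2, SCRATCH / "p2.jsonl")
    props = class_proportions(p2)
    (RESULTS / "proportions.json").write_text(json.dumps(
        {"n_p0": len(corpus), "n_p1": len(p2), "proportions_pct": props},
        indent=2) + "\n")
    print(f"cascade: p0={len(corpus)} -> p1={len(p2)} "
          f"({len(corpus) - len(p2)} predicted off-topic)")
    print("predicted sentiment shares (%):", props)


if __name__ == "__main__":
    main()
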
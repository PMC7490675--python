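"""Train the baseline relevance/sentiment/organism classifier slots on the
consensus labels and evaluate them on a held-out 20% split (macro-F1).

Writes the serialized models and results/eval.json.
"""

import json

import pandas as pd

from common import RESULTS, SCRATCH, SEED, ensure_dirs

from crisprpulse import io, prep
from crisprpulse.labels import ORGANISMS, RELEVANCE, SENTIMENTS
from crisprpulse.pipeline import _train_slot, subseed


def main() -> None:
    ensure_dirs()
    sample = io.read_corpus(SCRATCH / "sample.jsonl")
    consensus = pd.read_csv(SCRATCH / "consensus.csv", dtype={"tweet_id": str})
    texts = dict(zip(sample["id"], sample["text"].map(prep.anonymize_text)))
    cons = consensus.assign(text=consensus["tweet_id"].map(texts)).dropna(subset=["text"])

    (SCRATCH / "models").mkdir(exist_ok=True)
    evaluation = {}
    for slot, label_set, col in (("relevance", RELEVANCE, "relevance"),
                                 ("sentiment", SENTIMENTS, "sentiment"),
                                 ("organism", ORGANISMS, "organism")):
        rows = cons[cons[col].notna()]
        model, ev = _train_slot(rows["text"].tolist(), rows[col].tolist(),
                                list(label_set), subseed(SEED, f"split_{slot}"),
                                "train")
        (SCRATCH / "models" / f"model_{slot}.json").write_text(model.to_json())
        evaluation[slot] = ev
        print(f"{slot}: n={len(rows)} macro-F1={ev['macro_f1']:.3f} "
              f"per-class F1={ {k: round(v, 3) for k, v in ev['f1'].items()} }")
    (RESULTS / "eval.json").write_text(json.dumps(evaluation, indent=2) + "\n")


if __name__ == "__main__":
    main()
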
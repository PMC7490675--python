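"""Canonical label vocabularies shared across the pipeline.

Order matters: classifier tie-breaks and report columns follow these lists.
"""

SENTIMENTS = ["positive", "neutral", "negative"]
RELEVANCE = ["relevant", "not_relevant"]
ORGANISMS = [
    "humans",
    "embryos",
    "animals",
    "plants",
    "bacteria",
    "multiple",
    "not_specified",
]

#: Organism classes the generator can assign as ground truth.  "multiple" is a
#: legitimate annotator answer but never a generated truth, mirroring the fact
#: that predicted organism classes omit it.
GENERATED_ORGANISMS = [o for o in ORGANISMS if o != "multiple"]

QUESTIONS = ["relevance", "sentiment", "organism"]

#: Numeric weight of each sentiment class used in every numerical summary.
SENTIMENT_WEIGHTS = {"positive": 1, "neutral": 0, "negative": -1}
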
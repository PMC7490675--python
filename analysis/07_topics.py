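"""Topical breakdowns of the predicted corpus: organism-by-month sentiment
matrix (100-tweet mask), yearly top-15 hashtags (excluding the topic tag),
and regex theme counts with final-year extrapolation.

Writes results/organism_month.csv, hashtags_year.csv, themes_year.csv.
"""

from common import ANALYSIS_CONFIG, RESULTS, SCRATCH, ensure_dirs

from crisprpulse import io, topical
from crisprpulse.config import default_themes


def main() -> None:
    ensure_dirs()
    p2 = io.read_corpus(SCRATCH / "p2.jsonl")

    org = topical.organism_month_matrix(p2, ANALYSIS_CONFIG.min_cell)
    io.write_table(RESULTS / "organism_month.csv", org.assign(month=org["month"].astype(str)))
    shown = org[~org["masked"]]
    by_org = shown.groupby("organism")["mean_sentiment"].mean().round(2)
    print("mean monthly sentiment by organism (unmasked cells):", by_org.to_dict())

    tags = topical.hashtag_year_stats(p2, ANALYSIS_CONFIG.top_k)
    io.write_table(RESULTS / "hashtags_year.csv", tags)
    last = tags[tags["year"] == tags["year"].max()]
    print(f"top hashtags {tags['year'].max()}: "
          f"{list(last.head(5)['hashtag'])} (of {len(last)} reported)")

    themes = default_themes()
    flags = topical.match_themes(p2, themes)
    months_obs = int(p2["created_at"].max().month)
    ty = topical.theme_year_counts(flags, p2, months_obs)
    io.write_table(RESULTS / "themes_year.csv", ty)
    totals = ty.groupby("theme")["count"].sum().sort_values(ascending=False).round(0)
    print(f"theme totals (final year extrapolated from {months_obs} months):",
          totals.to_dict())


if __name__ == "__main__":
    main()
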
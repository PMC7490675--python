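# Methods

This note documents the models and conventions implemented in
`crisprpulse`: what the synthetic generator emulates, the exact definitions
of the statistics, the numerical choices made where the design was open,
and what the passing tests do and do not establish about real data.

## The synthetic stream

`synth.generate_corpus` draws, for each UTC day d of the configured window:

* an activity count N_d ~ Poisson(λ · m_d), with base rate λ (default 600
  tweets/day; the real stream averaged ≈ 640/day over 2013–2019) and m_d
  the product of the multipliers of events covering d;
* per-tweet sentiment classes from a probability vector p_d =
  (p⁺, p⁰, p⁻)_d.  The baseline vector (default 0.523/0.403/0.075, the
  corpus-level predicted shares) is deformed in time by shifting the
  log-odds of the negative class and renormalizing.  The per-day trend
  offset is solved in closed form so that the **expected sentiment index**
  (p⁺ − p⁻)/(p⁺ + p⁻) equals s₀ + β·t exactly, with t in years from the
  stream start and β the configured drift (default −0.061 y⁻¹); the target
  is clipped to (−0.999, 0.999), so extreme drifts saturate rather than
  produce invalid probabilities.  Event `sentiment_shift`s are additional
  raw log-odds offsets on the negative class during the event days.
* an organism class from a fixed mixture (defaults follow the predicted
  organism shares, "multiple" excluded — it is an annotation answer, not a
  generated truth), and a relevance flag (5% off-topic contamination, so
  the relevance gate has something to do);
* a template text over a packaged ~300-word toy lexicon.  Sentiment cue
  words, organism words and topic words are drawn from disjoint pools, so
  classes are *largely* token-identifiable; 5% of relevant tweets are
  two-word fragments (they exercise the content-word filter), 20% carry a
  raw @handle and 15% a URL (they exercise anonymization), and hashtags are
  appended with probability weights w·exp(a·s), where a is the tag's
  sentiment affinity and s the tweet's ±1/0 weight;
* with probability `duplicate_rate` (default 0.67, matching the observed
  ≈ 67% duplicate share) the record instead *copies verbatim* the text and
  truth labels of a uniformly chosen earlier original and records its id in
  `duplicate_of`, which makes deduplication exactly testable.

One `numpy` Generator seeded from the config drives the whole call, so a
config+seed pair is reproducible bit for bit.  `simulate_daily_counts`
exposes the same day-level draws without materialising texts; replicate
studies (trend recovery, event recall) use it directly.

What the generator does **not** emulate: user accounts and their follower
network, tweet-aware tokenization subtleties (emoji, contractions),
language variety, topic drift inside a class, correlated annotator errors,
and duplicate bursts concentrated around events.  Passing tests therefore
show that the *pipeline machinery* recovers planted structure under clean
conditions, not that any classifier reaches a particular accuracy on real
tweets.

### The simulated crowd

Honest annotators answer each of the three questions (relevance, sentiment,
organism) truthfully with probability `accuracy` (default 0.9) and
otherwise pick a uniformly random *wrong* label; spammers answer uniformly
at random.  Every tweet receives `redundancy` (default 3) annotations from
distinct annotators, chosen with probability proportional to their task
target.  The uniform-error model is a stated assumption: the real crowd's
error structure is unknown, and systematically biased annotators (e.g.
everything "positive") would evade agreement-based screening differently.

## Preparation

* **Anonymization** replaces `@\w+` with `@<user>` and URLs
  (`https?://…` or `t.co/…`) with `<url>`; the placeholders match neither
  pattern, so the map is idempotent.  It runs *before* counting and
  deduplication, so placeholders never count as content words and dedup
  ignores handle/URL variation.
* **Content words** are whitespace tokens, edge-punctuation stripped and
  case-folded, that appear in the lexicon and not in the stop list; tokens
  starting with `#`/`@` and the placeholders are excluded.  The packaged
  lexicon and stop list are swappable fixtures, not normative corpora.
  Tweets with fewer than `min_content_words` (default 3) are dropped.
* **Deduplication** removes every record with `duplicate_of` set and every
  record whose normalized text (anonymized, whitespace-collapsed, case
  preserved) repeats an earlier record's; the earliest `created_at` (ties
  by id) survives.
* **Stratified sampling** bins by UTC calendar month and draws up to
  `monthly_quota` records per bin uniformly without replacement; a bin with
  fewer records contributes all of them.

## Annotation QC

*Raw agreement* of annotator A for a question: over all tweets A annotated,
count every (tweet, co-annotator) pair as a possible agreement and the
equal-valued ones as actual; the ratio is undefined (and reported NaN) with
no pairs.  Agreement is computed per question (relevance by default;
`"pooled"` pools all three).

*Outlier screening* is a single pass (no re-computation after removal): an
annotator is flagged if |x − mean| > 3·SD (population SD over all defined
raw agreements; two-sided, the conservative reading), or has < 20 possible
agreements, or < 3 tasks.

*Fleiss' κ* = (P̄ − P̄ₑ)/(1 − P̄ₑ), with P̄ the mean over items of the
within-item agreeing-pair fraction Σⱼ nᵢⱼ(nᵢⱼ−1)/(n(n−1)) and
P̄ₑ = Σⱼ pⱼ².  The classical statistic assumes a fixed panel size n, but
outlier removal leaves ragged rows; the matrix builder therefore keeps only
tweets whose remaining annotation count equals the modal count (ties broken
toward the larger panel) — an explicit, logged exclusion.  A single-category
matrix (P̄ₑ = 1) raises a degenerate-input error rather than returning 0/0.

*Consensus*: after outlier removal, a tweet gets a label for a question iff
**all** remaining annotations agree and there are ≥ 3 of them ("unanimous
consensus of at least 3" read as unanimity over the tweet's whole remaining
annotation set, not "some 3 agree").  Sentiment/organism labels are stored
only where the relevance consensus is "relevant".

## Classifiers

The production-scale transformer models that filled the three slots are
external artifacts and out of scope; the package defines the contract
(ordered `label_set`, `fit`, `predict`) and ships a multinomial token-count
baseline: score(c|text) = log π_c + Σ_t log[(n_{t,c} + α)/(N_c + αV)] with
add-α smoothing (α = 1), argmax prediction, ties broken by label-set order,
and tokens unseen in training carrying no evidence.  Classes listed in the
label set but absent from training get a −∞ prior and are never predicted
(the organism answer "multiple" typically behaves this way).

Evaluation uses an unstratified shuffled 80/20 split with a fixed derived
seed; the model trained on the 80% is both evaluated on the 20% and used
for prediction (no refit on the full set, keeping the reported macro-F1 an
honest estimate for the predicting model).  Macro-F1 is the unweighted mean
over the label set of per-class F1 from the confusion matrix, with the
convention F1 = 0 for a class with no true and no predicted instances
(keeps the mean defined on small splits).  The cascade predicts relevance
on every record, removes predicted-irrelevant records, and predicts
sentiment/organism only on the survivors.  Class proportions are percentages
of the relevant corpus, rounded half-up to one decimal.

## Time series

Daily counts are per UTC calendar day by predicted sentiment, zero-filled
over gaps.  The sentiment index of day d uses the centered window
[d−3, d+3] (window length 7, configurable but odd), truncated at the series
edges so the series keeps full length: s(d) = (P − N)/(P + N) over windowed
positive/negative counts — a count-weighted mean of the ±1 weights, not a
mean of daily ratios — and is undefined (NaN) when the window holds no
polar tweet.  Activity a(d) is the windowed mean of total counts.

The trend is ordinary least squares of s on time in years (365.25 days),
NaN days skipped; the reported standard error is the plain OLS slope SE.
One calibration caveat: with a 7-day window, adjacent index values share
6/7 of their data, the residuals are MA(6)-autocorrelated, and the OLS SE
understates the true slope uncertainty by roughly √7.  Replicate-coverage
checks (slope within ±2 estimated SE in ≥ 90% of runs) therefore evaluate
the index at window 1 — the same estimand with honestly calibrated SE —
while single-stream point estimates are reported at the production window.

Welch's test uses t = (m̄_a − m̄_b)/√(v_a/n_a + v_b/n_b) with
Welch–Satterthwaite df; two samples with zero combined variance give
t = 0, p = 1 when means agree and are rejected otherwise.  Yearly
comparisons take the ±1 weights of polar tweets per calendar year and test
consecutive-year pairs, reporting raw and Holm-adjusted p (the pairing and
correction are this package's choices; means and SDs are reported per year
alongside).

Peaks are local maxima of the *smoothed activity* series (strictly greater
than neighbours; plateaus count once, reported at their leftmost index)
with standard topographic prominence — height above the higher of the two
lowest descent points toward the nearest higher peaks or the series ends —
computed by `scipy.signal`, kept when prominence/(max − min) ≥ 0.2.
"Relative" prominence is normalized by the smoothed series range: the
cutoff is dimensionless while activity is in tweets/day, and range
normalization makes an isolated bump over a flat baseline have relative
prominence 1.  Two consequences worth knowing: on a series *without* any
dominant structure the range is set by noise and small wiggles can clear
the threshold (event-recall guarantees hold for bursts with multiplier ≥ 4
over a flat baseline, which dominate the range); and bursts shorter than
the smoothing half-width (3 days) produce a flat-topped smoothed bump whose
argmax is ambiguous within the window, so peak *dates* are only guaranteed
to ±duration_days for bursts lasting at least 3 days.

## Topics

Topical summaries use the full +1/0/−1 weights (neutral included), unlike
the polar-only index.  Organism cells are (calendar month × organism) with
mean weight and count; cells under 100 tweets keep their value but carry a
mask flag.  Hashtags are `#\w+` tokens, case-folded (Twitter hashtags are
case-insensitive identifiers) but otherwise exact — no stemming or variant
grouping — with #crispr excluded as the overarching topic; per year the 15
most frequent are reported with the mean and population SD (ddof = 0, so a
single-tweet tag reports SD 0) of the weights of tweets carrying them, a
multi-tag tweet counting once per tag, count ties broken lexicographically.
Themes are case-insensitive regexes over anonymized text, shipped as an
editable YAML table; the six stock stem patterns (genome, baby, disease,
embryo, treatment, mutation) are deliberately simple placeholders for a
curated table.  Yearly theme×sentiment counts multiply the final partial
year by 12/m (m = months observed, default inferred from the last record's
month) and are reported as reals.

## Reproducibility and problem sizes

All randomness in a pipeline run flows from one master seed through named
substreams (corpus, sampling, annotation, per-slot splits), so reruns
reproduce every CSV byte for byte; the run report carries a SHA-256
manifest.  A failed stage removes partial outputs and raises an error
naming the stage and a machine-readable code.

The replicate studies use deliberately scaled problem sizes chosen for
tight-enough Monte-Carlo error at interactive runtimes: trend recovery uses
50 streams of 200 tweets/day over 4 years (day-level counts only); event
recall uses 20 streams of 1000 tweets/day over one year with planted
multiplier-4 and -5 bursts; spammer screening uses 50 crowds of 12 honest
annotators (accuracy 0.9) plus one spammer over 250 tasks at redundancy 3;
the determinism check runs the full pipeline twice on a ~50k-tweet
77-month stream.  The `analysis/` drivers replay the study at 25 tweets/day
(~58k records).

## Known limitations

* The lexicon-template text model makes classes nearly separable, so the
  baseline's macro-F1 on consensus-labelled synthetic data is optimistic;
  on the realistic mixed stream the rare negative class already drops
  per-class F1 markedly, mirroring the behaviour of real imbalanced
  sentiment data, but absolute scores do not transfer.
* Relevance κ on synthetic crowds is low despite accurate annotators: with
  ~95% relevant truth, chance agreement is high and κ is dominated by the
  imbalance — a reminder that κ values across questions with different
  marginals are not comparable.
* The fitted drift of a full-condition stream (trend *plus* event dips and
  clipping) differs from the injected baseline drift; recovery guarantees
  hold for event-free streams.
* Peak detection reports dates of activity bursts only; attributing peaks
  to real-world events is outside the package.
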
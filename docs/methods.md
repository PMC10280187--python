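# Methods

## The measurement model

The package treats population subjective well-being as a latent monthly
signal that two noisy instruments observe: a survey (small n, direct
question, sampling error) and a labelled post stream (large n, indirect
expression, classifier error, non-representative demographics). The
measurement pipeline converts the stream into monthly indicator series
and judges them by rank agreement with the survey series.

Key modelling commitments:

* **The user, not the post, is the unit.** Within each calendar month a
  user's tweets are collapsed to one sentiment class by majority vote.
  This removes repeated sharing of the same emotion and stops highly
  active users dominating the index. Ties resolve toward Neutral: a tie
  involving NEU returns NEU, and a POS/NEG tie — conflicting affect —
  also returns NEU rather than injecting either sign; any remaining tie
  breaks by the fixed order SKIP > SA > POS > NEG. Resolving toward
  Neutral is conservative (it can only attenuate an affect signal, never
  fabricate one) and deterministic.
* **Post-stratification as user-mass reweighting.** Each known-gender
  user's single vote is scaled by w_g = π_g / p_g (census over sample
  share) before tallying; this is algebraically the standard
  post-stratification estimator (a stratum-share-weighted combination of
  stratum-level counts). Sample shares are recomputed per month from
  that month's users because stream composition drifts. Users whose
  gender cannot be inferred are excluded from the weighted variant but
  kept in the unweighted one.
* **Indicators are shares of (weighted) users**: PA = POS/total,
  NA = NEG/total, SA = SA/total, Net = (POS−NEG)/total, and the
  neutral-relative forms PA/NEU, NA/NEU, (POS−NEG)/NEU. A zero
  denominator is an explicit error naming the indicator and month — a
  series value must be finite to enter a correlation, so +∞ is not a
  useful convention.
* **Stationarity before correlation.** Monthly well-being series trend;
  correlating trending series overstates agreement. Each pair is
  checked with the augmented Dickey–Fuller test (unit-root null,
  lag order by AIC) and both series are first-differenced when either
  fails; differencing runs across consecutive *available* months even
  when the calendar has gaps. Both a forced and an automatic mode are
  exposed because the underlying design can be read either way.

## Inclusion thresholds

* Language filter: exact match on the stream's own language tag;
  retweets (records with a `retweeted_status` member) are dropped.
  Quote-tweets without that member count as originals.
* Month coverage: a month enters only if tweets exist for ≥ 80% of its
  days (the stream archive has partial months).
* Minimum sample: ≥ 1,600 distinct users per month — the typical
  single-wave size of the reference telephone survey, adopted as the
  floor for the stream side as well.

## Name-based gender inference

TF-IDF over character n-grams of lengths 2–7 taken inside word
boundaries (each word padded with one boundary marker per side, so
suffixes — the grammatically gendered part of Russian surnames — form
distinguishable terminal n-grams), IDF enabled, L2 normalisation, terms
in more than 50% of documents ignored; L2-regularized logistic
regression on top (C = 1.0 by default, grid-searchable). Names are
case-folded first. Evaluation splits 80/20 and reports both binary and
macro F1 on the held-out part only. Empty or degenerate names predict
"unknown" and are excluded from stratified counts.

## The synthetic world

The generator emulates the joint process the pipeline assumes, with
every stage's ground truth retained:

* Latent affect h_t: AR(1) with ρ = 0.6, innovation SD σ = 0.25,
  clipped to [−1, 1], started from the stationary distribution. The
  bounded scale keeps tilted class probabilities valid at sensitivity 1
  even with per-gender level offsets of ±0.2. σ was chosen so the
  latent-induced variation in the monthly PA share (≈ 0.03) dominates
  the tweet-side sampling error (≈ 0.01 at ~1,750 users/month):
  a recovery experiment is informative only if signal exceeds noise,
  and a real monthly happiness index moves by several points as well.
* Users: gender from the platform mix (default 59% male / 41% female,
  vs census 46/54), full names from a gendered Cyrillic lexicon
  (synthetic: first name plus surname stem with -ов/-ев/-ин or
  -ова/-ева/-ина suffix), so downstream name-based inference is
  exercised rather than bypassed.
* Activity: a user posts in a month with probability 0.35, and then a
  zero-truncated-Poisson(5.5) number of tweets, matching the sparse
  "few tweets per user per month" regime of a 1% stream sample. (0.35
  makes the expected 1,750 active users per 5,000-user month clear the
  1,600-user floor with ≈ 4 SD of margin; a rate low enough to fail the
  pipeline's own inclusion rule would make the default scenario
  self-contradictory.)
* Sentiment: base class distribution (POS, NEG, NEU, SA, SKIP) =
  (0.18, 0.17, 0.40, 0.05, 0.20) — neutral-dominated, as general-domain
  streams are. Affect tilts it by moving probability mass
  δ = sensitivity·(h_t + offset_g)·½·min(base_POS, base_NEG) from NEG
  to POS; NEU/SA/SKIP stay at base. A tilt that would push any class
  negative is a hard error naming month and stratum. Observed labels
  are drawn from the confusion row of the true label (default:
  0.85 diagonal, off-diagonal mass uniform).
* Survey: 1,600 respondents per month; "don't know" with probability
  0.05, otherwise happy with probability logistic(2·h_t), strong form
  of the answer (Yes/No vs Rather) with probability 0.6.
* Determinism: all randomness flows from `default_rng` streams spawned
  from the config seed; identical config ⇒ byte-identical output files.

What the generator deliberately does **not** model: real text (tweets
carry labels only), holiday effects on SA (a per-day SA multiplier
exists purely to exercise the holiday-ranking module), user churn,
age structure, platform-specific emotion norms, or correlated classifier
errors (the confusion matrix is applied independently per tweet).
Passing the recovery experiment therefore shows the *pipeline's*
statistical machinery is sound — not that any real stream satisfies
these assumptions.

## Misclassification-bias simulation

Per iteration: period-level class shares ~ Dirichlet(1,1,1,1,1), counts
~ Multinomial(5,000 posts) over 20 periods; observed counts redistribute
each true-class count multinomially along its confusion row (totals
conserved exactly); Spearman correlation between the true and observed
indicator series. The Dirichlet–multinomial is the minimal exchangeable
model over five classes. Aggregation is the arithmetic mean over
non-degenerate iterations (constant series and zero-denominator
iterations are excluded and counted); full per-iteration distributions
are kept so any other aggregate is recoverable. The desk default is
1,000 iterations; the reference analysis's 500,000 is a config value
away and changes the mean by less than the Monte-Carlo error at 1,000.
A correlation-test p-value is reported; no attempt is made to interpret
an "aggregated p-value above 0.95", which cannot describe a
correlation test under near-perfect correlation.

## Experiment sizes

The standard recovery scenario is 24 months × 5,000 users (≈ 230,000
tweets) with the 0.85-diagonal confusion matrix; the gender-skew
comparison uses the same size with an identity confusion matrix and
per-gender affect offsets ±0.2. Identity confusion is used there
deliberately: classifier noise shifts the *level* of the raw and
post-stratified series equally, and such a common shift can
coincidentally offset the demographic bias of the raw series; removing
it isolates the effect post-stratification is designed to correct. The
gender-model experiment uses a 10,000-name lexicon with an 80/20 split.

## Numerical conventions

* Speaker-population estimates: full-precision chain, rounded
  half-away-from-zero to 2 decimals on output. (The published table
  this reproduces mixes rounding dialects; only its rounding-robust
  cells are asserted in tests.)
* Post-stratification validates Σ_g w_g·p_g = 1 to 1e-9 and errors on a
  census-positive stratum with zero sample mass instead of producing an
  infinite weight.
* Holiday ranking is tweet-level (no user aggregation, no reweighting):
  rank 1 = highest daily SA share, competition ranking for exact ties,
  aggregate ordering by mean of per-gender ranks with ties reported as
  rank ranges ("2-4").
* Index CSV output uses a fixed float format so identical runs are
  byte-identical.

## Known limitations

* Gender is the only stratification variable; age post-stratification
  is out of scope (the stream's age mix is too skewed for stable
  weights).
* The gender model is validated on a synthetic lexicon with clean
  grammatical gender; real display names (nicknames, Latin
  transliteration, emoji) are far harder, and the near-perfect synthetic
  F1 does not transfer.
* The bias simulation treats classifier errors as independent across
  posts and periods; systematic drift in classifier behaviour over time
  would violate this and is not modelled.
* No smoothing or imputation of months that fail the inclusion rules;
  correlations simply use the surviving months.
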
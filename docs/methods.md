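# Methods

This note documents the models, conventions and numerical choices behind
`crowdcongruence`, and what the synthetic study does and does not emulate.

## The measurement chain

The quantity of interest is per-district *congruence*: the rank
correlation between (a) the crowd ranking of pediatric clinics by
frequency of positive/neutral mentions in local forum messages and (b)
the official ranking by antibiotic prescription rate (prescriptions per
visit; lower is better, since antibiotic overuse in children is harmful).
Congruence is then regressed on six sociodemographic covariates to ask
which districts produce unreliable crowdsourced information.

Quality orientation is fixed once: quality = −(antibiotic rate). Any
strictly decreasing transform gives the same ranks, so nothing downstream
depends on the functional form. Positive congruence therefore means the
crowd's favourite clinics are the low-prescribing ones.

## Extraction

*Candidate filter.* A thread qualifies when its root message contains a
domain keyword ("pediatric") and a request keyword ("recommendation"),
case-insensitively; candidates are the replies of qualifying threads.
Both keyword sets are configurable.

*Stepwise normalization.* Each whitespace token n-gram (n ≤ 5) of a
candidate is resolved against the alias dictionary: (1) exact canonical
match, (2) exact alias match, (3) minimum-Levenshtein alias match.  The
per-alias acceptance threshold is ⌊len(alias)/4⌋: aliases of up to three
characters (acronyms) must match exactly, 4–7 characters tolerate one
edit, 8–11 two, and so on.  Ties at the minimal distance prefer the
longer alias (more specific), then the lexicographically smallest
canonical name — an arbitrary but deterministic convention.  Fuzzy
matching respects token boundaries: a k-token span is only compared
against k-token aliases.  Whitespace segmentation is reliable both in the
synthetic corpus and in the curated dictionary, and relaxing it lets
common function-word bigrams ("for a") land within one edit of short
name variants.  Morphological analysis and anaphora resolution (the hard
part of the real Korean corpora) are out of scope.

*Dedup convention.* At most one mention per (message, clinic) pair is
counted by default, damping single-user repetition; occurrence-level
counting (overlapping matched spans merged first) is available via
`dedupe=False`.

*Sentiment.* Messages carry labels (positive / neutral / negative /
ambiguous / unlabeled); labelling itself is an input, not a model.  The
crowd signal keeps positive, neutral and ambiguous-as-neutral mentions
and drops negative ones.  Unlabeled mentions are kept by default
(configurable to drop or error).

*Evaluation.* Precision/recall/F1 on (message, clinic) pairs over a
seeded random message sample, with precision defined as 0 when there are
no predictions.  Note that a precision of 0.84 and recall of 0.73 give
F1 = 2PR/(P+R) = 0.781 at full precision of the inputs; rounding the
inputs first can print a slightly different figure.

## Rankings and congruence

Crowd and government rankings are built over the clinics with ≥ 1
retained mention (unmentioned clinics are dropped, not assigned worst
rank), with average ranks on ties; every rank vector sums to n(n+1)/2.
Districts with fewer than `min_district_n` (default 2) commonly rankable
clinics are flagged excluded, mirroring the exclusion of sparsely covered
districts in real data.  Clinics mentioned online but absent from the
registry raise an error in counting — in the synthetic setting they
cannot occur, and with real inputs silent dropping would bias counts.

Kendall's tau is computed from explicit pair counts.  The tie-corrected
tau-b is the default because frequency-based crowd rankings tie often and
the uncorrected tau-a deflates magnitudes; tau-a is selectable
(`tau_variant="a"`).  Spearman's rho is the Pearson correlation of the
rank vectors, returned as exactly ±1 when the centered ranks are equal or
opposite.  Constant rank vectors make either index undefined; they yield
NaN with a warning (never silent zeros), and the regression drops those
districts listwise with a log line.

A caution for property-testing: tau and rho need not share a sign on
every input.  They satisfy Daniels' inequality |3τ − 2ρ| ≤ 1, which
permits rare strict sign disagreement (about 1.7% of random tie-free
permutations of lengths 3–9); the test suite asserts the inequality, not
sign equality.

## Covariates

The six regressors: birthrate (births per fertile woman), mean and SD of
married women's educational attainment, population density, doctors per
pediatric clinic, availability (clinics per 1000 residents).  Educational
categories map to years of schooling (none→0, elementary→6, middle→9,
high→12, 2-year college→14, 4-year college→16, master→18, PhD→23); the SD
uses the population (divide-by-N) formula, immaterial at census scale.

Density units: official areas are km², but metropolitan-district values
in the 0.003–0.029 range imply the covariate is population/(area_km²·10⁶),
i.e. persons per m².  The package computes exactly that and documents it;
a unit change rescales one raw coefficient only, leaving p-values and
standardized coefficients untouched (property-tested).

Multi-period inputs are collapsed before analysis: arithmetic mean per
column (population, area, birthrate, prescription rates), pass-through
for single-period quantities (education); mention counts are summed.

## Regression

OLS with intercept via statsmodels: classical SEs, two-sided t-tests,
adjusted R² = 1 − (1−R²)(n−1)/(n−k−1).  No multiple-testing correction
(raw p-values are reported).  Standardized coefficients come from
refitting on z-scored variables (sample SD, ddof = 1) and satisfy
β_std = β·SD(x)/SD(y) to numerical precision, with an intercept forced to
~0 by centering.  Rank-deficient designs raise an error naming collinear
columns; a zero-variance dependent (e.g. the noiseless limit below)
raises, and the pipeline converts that into a flagged, reported condition
rather than a crash.

## The synthetic study

The generator stands in for three undeposited inputs: crawled forum HTML,
HIRA clinic tables, and census downloads.  It produces a registry,
an alias dictionary, district covariates, a message corpus and gold
annotations, all from one seed via named `SeedSequence` children
(registry, aliases, demographics, corpus, study), so every sub-stream is
independently reproducible and equal configs give byte-identical files.

**Registry.** Default 29 districts; with per-district clinic counts
supplied (the published counts) the registry totals 779 clinics.
Antibiotic rates are Beta(2, 5) (mean 0.29, SD 0.16) — a unimodal,
right-spread rate distribution plausible for pediatric outpatient
antibiotic prescribing; no empirical distribution was published, and only
ranks matter downstream.  Canonical names are three tokens
("name name clinic") built from pronounceable syllables; full names are
kept ≥ 7 edits apart so that an exactly written name can never fuzzily
resolve to a second clinic.

**Aliases.** Per clinic: the canonical name itself, an acronym
(initial-character contraction, exact-match-only by the threshold rule),
a truncation (leading token), and Poisson-many typo variants within
`typo_dmax` (default 1) edits of the leading token — about three
"similar expressions" per clinic on average, matching the curated
dictionary's density.  Two safeguards keep the uncorrupted corpus
unambiguous: variants colliding with the filler vocabulary or reserved
words are rejected at generation, and a global post-pass removes any
variant reachable (within its own threshold) from a *different* clinic's
tokens or aliases.  The realized mean of non-identity forms is ~2.5–2.8
after pruning.

**Demographics.** The six covariates are drawn as independent clipped
normals around the published census moments (birthrate 1.048 ± 0.100,
education 12.390 ± 0.833 / SD 3.496 ± 0.183, density 0.016 ± 0.007,
doctors/clinic 1.641 ± 0.396, availability 0.060 ± 0.010); raw counts
(population, area, clinics, doctors) are then derived so the internal
identities hold exactly after integer rounding.  An education-category
sampler with the same moments supports the covariate-construction tests.

**Corpus.** Threads arrive per district (default 60); message count per
thread is 1 + Poisson(mean − 1) with mean 5.36, the published
messages-per-thread figure.  A configurable fraction (default 0.8) of
roots are recommendation requests; only their replies carry mentions.
Reply sentiment is drawn from the configured mix — default
(0.6203, 0.30, 0.0797, 0) for positive/neutral/negative/ambiguous, fixing
the published 92.03/7.97 positive-or-neutral/negative split; the
positive-vs-neutral subdivision is not separately published and is a
package choice with no downstream effect (both are retained).

**The crowd signal.** Perceived quality is q_h = −rate_h + ε_h with
ε_h ~ N(0, σ_d) drawn once per clinic, and σ_d = max(0, c₀ + Σ c_j z_j)
a linear function of the district's z-scored covariates.  Defaults:
c₀ = 0.45 and slopes 0.20 (birthrate), 0.10 (education SD, density,
doctors/clinic), 0 otherwise.  The scale — noise a few times the 0.16
quality spread — is calibrated so per-district tau spans the
weak-congruence range the real study observed (roughly −0.5 to 1, far
from ceiling) while the covariate regression still explains about a third
of the tau variance at scale; the positive slopes make congruence *fall*
with those covariates, the direction the published regression found.

Retained-mention counts per clinic are allocated deterministically rather
than sampled per reply: softmax weights over perceived quality
(temperature 0.15) set real-valued targets for a budget of one mention
per retained reply on average; the top k clinics (largest k with
k(k+1)/2 ≤ budget) receive a unit staircase plus largest-remainder extras
sorted decreasing.  This preserves the budget exactly, makes the count
ranking tie-free and identical to the perceived-quality ranking, and is
what makes the noiseless limit *exact*: with σ = 0 and no surface
corruption, every district's tau and rho equal 1 precisely, not merely in
expectation.  Mention tokens go to distinct positive/neutral replies (so
message-level dedup is lossless); negative replies carry background
mentions of uniformly random clinics, which the sentiment filter removes
exactly.  Surfaces are sampled aliases, corrupted with probability
`corruption_rate` (default 0.1) by 1–4 extra edits to the leading token.

**Fast path.** `simulate_district_study` reproduces the chain perceived
quality → count allocation → aligned rankings → tau/rho at the district
level without rendering text, for Monte-Carlo design checks and power
studies of the regression; extraction is separately verified to be exact
at zero corruption, so omitting it there loses nothing.

### What the generator does not emulate

Real Korean text: no morphology, no spacing errors inside names, no
anaphora, no topic drift — token-level name realism only, by design.
Mention behaviour is stylized (softmax-monotone in perceived quality,
one mention per reply on average); the real mention-generation process is
unobserved.  Clinic-level doctor counts and the district doctors-per-clinic
covariate are drawn independently.  Passing tests therefore demonstrate
correctness of the measurement chain under the stated generative
assumptions — not that the extractor would reach the published 84%/73%
precision/recall on real informal Korean, nor that the real regression
coefficients are recoverable from 29 districts.

## Problem sizes in the test suite

Property suites use 300–1000 random vectors; extraction exactness uses a
~10,000-message corpus; corruption-degradation uses three seeds × three
corruption rates on ~2,000-message corpora; sign recovery uses 200
replicates of 200 districts through the fast path; the end-to-end runs
use 10–29 districts.  These sizes keep each check comfortably converged
(binomial/3-SE bands are stated in the tests) while the whole suite runs
in about a minute.

## Known limitations

- The alias-confusability prune guarantees unambiguity for single-token
  variants and canonical names; astronomically unlikely multi-token
  coincidences (a filler trigram within a long name's threshold) are not
  excluded by construction, only made negligible by vocabulary design.
- Tau/rho significance tests are not provided (none were used in the
  source analysis); the regression treats per-district tau as a known
  quantity, ignoring its estimation error from finite clinic counts.
- The pipeline is single-period by default; multi-period aggregation is a
  pre-step, not a panel model.
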
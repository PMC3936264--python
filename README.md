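# crowdcongruence

How well does crowdsourced hospital-quality information agree with official
government quality data — and what explains the places where it doesn't?

This package implements, as a tested and reusable pipeline, an
infodemiology analysis built around South Korean pediatric care: parents in
geospecific online communities (Naver/Daum forums) recommend local
pediatric clinics; the Health Insurance Review and Assessment Service
(HIRA) publishes each clinic's antibiotic prescription rate (prescriptions
per visit), which — because antibiotic overuse in children is harmful — is
used, inverted, as an objective quality index. The analysis asks whether
the two rankings agree district by district, and regresses that agreement
on census covariates.

It is intended for researchers studying crowdsourced health-information
quality who want the full measurement chain — dictionary-based entity
extraction, rank-correlation congruence, covariate regression — as
library functions with a synthetic-data generator standing in for the
crawled corpora and government downloads, which were never deposited.

## The analysis

1. **Extraction.** Threads whose root contains the keywords *pediatric* and
   *recommendation* mark recommendation requests; their replies are
   candidate messages. Hospital mentions are found by stepwise expression
   normalization against an alias dictionary: exact canonical match, exact
   alias match, then minimum Levenshtein-distance match subject to a
   per-alias threshold (⌊len/4⌋, so acronyms must match exactly). Negative
   mentions are discarded; in the real corpus 92.03% of annotated messages
   were positive or neutral.
2. **Ranking.** Within each district, clinics are ranked by retained
   mention frequency (crowd ranking, most-mentioned first) and by official
   antibiotic rate (government ranking, lowest first), over the clinics
   with at least one retained mention; ties get average ranks.
3. **Congruence.** Per district, Kendall's tau-b

   τ_b = (C − D) / √((n₀ − T_x)(n₀ − T_y)),  n₀ = n(n−1)/2,

   computed from explicit concordant/discordant/tied pair counts, and
   Spearman's rho (Pearson correlation of the rank vectors). +1 means the
   rankings agree completely, −1 that they are reversed.
4. **Regression.** OLS of the congruence index on six covariates —
   birthrate, mean and SD of married women's education (years), population
   density (persons/m²), doctors per clinic, clinics per 1000 residents —
   with classical SEs, two-sided p-values, adjusted R², and standardized
   coefficients β_std = β·SD(x)/SD(y).

The synthetic generator emulates the study conditions with known ground
truth: perceived clinic quality is true quality plus Gaussian noise whose
standard deviation rises with district covariates (birthrate above all),
so the regression has recoverable signs by construction. See
`docs/methods.md` for the generative model and its limits.

## Worked example

```python
import crowdcongruence as cc
from crowdcongruence.simulate import SimulationConfig

config = SimulationConfig(n_districts=10, hospitals_per_district=12,
                          threads_per_district=40, seed=42)
results = cc.CongruenceModel.from_simulation(config).fit()
print(results.summary())
```

prints (abridged):

```
Crowdsourced-vs-official hospital-quality congruence
====================================================
messages 2107, candidates 1353, mentions 1301 (retained after sentiment filter 1198)
districts analyzed 10, excluded 0
extraction vs gold (n=1353 messages): precision 0.998, recall 0.960, F1 0.979
congruence: mean tau 0.383 (min -0.273, max 0.962), mean rho 0.457

OLS: kendall_tau ~ birthrate + education_mean + education_sd + population_density + doctors_per_clinic + availability
n = 10, adjusted R^2 = 0.340
                    coefficient       se       P  standardized
const                    6.0997   2.8584  0.1225           NaN
birthrate               -2.3391   1.6876  0.2598       -0.8282
...
```

Reading it: of 2107 simulated forum messages, 1353 are replies in
recommendation threads; extraction recovers the planted mentions almost
perfectly at the default 10% surface-corruption rate; district congruence
varies widely (tau −0.27 to 0.96); and the fitted birthrate coefficient is
negative — districts with higher birthrates (hence more of the generated
perceived-quality noise) have crowd rankings that agree less with the
official ranking. With only 10 districts the p-values are large; the
published-scale run below uses 29.

The same chain is available from a shell:

```bash
crowdcongruence simulate --seed 1 --out-dir data/
crowdcongruence extract --corpus data/corpus.jsonl --aliases data/aliases.json --out mentions.jsonl
crowdcongruence congruence --mentions mentions.jsonl --registry data/registry.csv --out congruence.csv
crowdcongruence regress --congruence congruence.csv --demographics data/demographics.csv --out-dir out/
```

or end to end from a YAML config via `crowdcongruence run-all`.

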
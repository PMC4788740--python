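# Methods

`retrievalqc` statistically validates keyword search filters used to
collect social-media text for health surveillance.  A filter partitions a
message archive into a retrieved and an unretrieved set; its quality is
summarized by **retrieval precision** (relevant fraction of what was
retrieved) and **retrieval recall** (retrieved fraction of everything
relevant).  The package estimates these under four evidence regimes, from
a full gold standard down to no gold standard at all.

## Classical estimation (gold-standard coding)

With coders treated as error-free and both strata sampled, the 2x2
filter-by-coder table (a, b, c, d) gives precision a/(a+b), recall
a/(a+c), specificity d/(b+d) and NPV d/(c+d), combined by the F-score

    F = (1 + beta^2) P R / (beta^2 P + R),      F(0, 0) := 0.

When the unretrieved stratum is too large to cross-tabulate directly,
recall follows from stratum proportions by Bayes' theorem:

    R = P * P(retr) / [ P * P(retr) + P(relevant|unretr) * (1 - P(retr)) ].

On internally consistent inputs this is an algebraic identity with
a/(a+c); the package property-tests it over random tables.

**Stratified-sampling adjustment.**  Coding samples oversample the
retrieved stratum.  Before the strata share one table, the retrieved
cells are rescaled by the ratio of the unretrieved to the retrieved
sampling fraction, rounded half-to-even per cell, margins recomputed;
the unretrieved stratum is preserved verbatim.

**Intervals.**  Proportion CIs go through
`statsmodels.stats.proportion.proportion_confint`; the default is the
Wald normal interval (which reproduces the published 94.9–96.1 for
4176/4373), with Wilson and exact Clopper–Pearson selectable.  A Wald
request at a boundary count (0 or n successes) degenerates to a point,
so it falls back to Clopper–Pearson with a warning.  The interval for
the Bayes-theorem recall propagates the binomial sampling variance of
both the retrieved-stratum precision and the unretrieved relevant
fraction via a seeded parametric bootstrap (percentile interval;
default 2000 resamples); a first-order delta-method variant is provided
as a cross-check and the two agree to ~0.01 on the shipped example.  A
fully coded stratum contributes no resampling variance (finite-population
census case).

**Silver-standard correction.**  If coders have perfect specificity but
imperfect recall S2 (they miss relevant content but do not invent it),
naive precision is biased down; the corrected value is a/[S2 (a+b)].
Inconsistent inputs can push this above 1, in which case it is clamped
to 1 with a warning rather than silently truncated.

## Bayesian estimation without complete evidence

Both samplers are pure Gibbs schemes — every full conditional is beta or
binomial — with beta priors on each probability parameter.

### Unretrieved messages never archived

Only the retrieved total n1, the approximate unretrieved total n2, and a
confidence interval for the coded-sample precision are observable; the
false-negative count c is latent.  With prevalence pi, filter recall S
and specificity C, each cycle:

1. draws precision uniformly on its interval and sets
   a = round(precision * n1), b = n1 - a (round-half-to-even);
2. draws c ~ Binomial(n2, q), q = (1-S)pi / [(1-S)pi + C(1-pi)]
   (the conditional probability that an unretrieved message is
   relevant), d = n2 - c;
3. draws pi ~ Beta(a+c+a_pi, n-a-c+b_pi), S ~ Beta(a+a_S, c+b_S),
   C ~ Beta(d+a_C, b+b_C);
4. records pi, S, C, precision, and the cycle's derived NPV and F1.

Redrawing precision every cycle (rather than fixing it once) propagates
its sampling uncertainty into every posterior and makes the recorded
precision chain's 95% interval coincide with the uniform's support; a
`precision_mode="fixed"` flag provides the alternative reading.  The
ratio q is guarded with an epsilon against 0/0 in degenerate corners.

### Two imperfect classifiers (no gold standard)

When coders also err, each observed cell of the filter-vs-coder table is
split into latent truly-relevant counts y1..y4.  Under conditional
independence of the two classifiers given true relevance — the standard
identifiability assumption of latent-class diagnostic models, stated in
every report — the full conditionals are four binomial splits,

    y1 ~ Bin(a, pi S1 S2 / [pi S1 S2 + (1-pi)(1-C1)(1-C2)])   (etc.),

followed by conjugate beta updates for pi, S1, C1, S2, C2, with the
filter's and coder's precision, NPV and F1 recorded per cycle from

    Precision_j = S_j pi / [S_j pi + (1-C_j)(1-pi)],
    NPV_j = C_j (1-pi) / [C_j (1-pi) + (1-S_j) pi].

**Validation by exact enumeration.**  Because the structure is fully
conjugate, the posterior conditional on the latent counts is analytic:
the joint posterior is an exact finite mixture over latent-count
configurations with beta-function weights.  The test suite enumerates
this mixture (log-space, `scipy.special.betaln`) on small instances and
requires the samplers to match the exact posterior means to 0.01–0.02.
With a point-mass perfect-coder prior, the latent splits are determined
and the two-classifier model collapses to the single-classifier
conjugate posterior with c observed; the suite asserts that closed form
directly.  (It does *not* collapse to the unarchived sampler, which
marginalizes an unobserved c — genuinely weaker evidence.)

**Prior elicitation.**  Reports state priors as a mean plus a 95%
interval, not as beta shapes.  `elicit_beta` recovers (alpha, beta) by
Nelder–Mead on (log alpha, log beta), minimizing the squared mismatch of
the mean and the two interval endpoints, with a vanishing alpha+beta
penalty so the weakest near-tie wins.  Equal-tail targets are the
default (highest-density targets are supported but make the fit
non-unique for flat priors).  Elicited shapes are echoed in every
report.  Round-trip accuracy is ~0.02 on the endpoints for the shipped
prior rows; very asymmetric targets (mean 0.019 against a 1e-6 lower
endpoint) are met as a least-squares compromise.

**Posterior summaries.**  Chains are summarized by means and empirical
highest-posterior-density intervals: the shortest contiguous window of
the sorted draws holding the requested mass (never longer than the
equal-tailed interval, and strictly shorter for skewed chains).  An
exact beta-density HPD (quantile-width minimization) backs prior
reporting and is validated against a density-grid oracle.

**Chain length and Monte-Carlo error.**  Defaults are 100,000 cycles
with 10,000 burn-in, no thinning.  The unarchived model's (c, pi, S)
block mixes slowly: the recall chain's autocorrelation leaves a
chain-to-chain standard deviation of ~0.06 on the posterior-mean
estimate at that length.  Where the package reports that posterior mean
as a headline number (the reproduction script and the corresponding
test), it averages replicate independent chains at the same per-chain
configuration, shrinking the Monte-Carlo error roughly by the square
root of the number of chains.  The latent-class sampler mixes fast and
is stable to ~0.001 at a single chain.  No convergence diagnostics
beyond trace export are provided.

## Sampling-plan simulation

Choosing coding sample sizes is a design problem: recall precision is
limited by how many unretrieved messages (sample size k) are coded,
because relevant messages are rare there.  `simulate_recall_ci`
constructs the implied population table from (N, precision, recall,
P(retr)) — prevalence is derived as precision * P(retr) / recall so the
scenario is internally consistent — then repeatedly draws stratified
samples (binomially within strata; hypergeometrically below N=100,000),
estimates recall with its bootstrap CI, and averages the limits per k.
Mean CI length decreases in k with diminishing returns; coding the
entire unretrieved stratum leaves only retrieved-stratum variance.
`recommend_sample_sizes` scans the k grid for the smallest size meeting
a target mean CI length and returns an explicit infeasibility result
when none does.  Defaults: 200 replicates and 500 bootstrap resamples
per grid point, seedable.

## Filter engine

Matching is case-insensitive (NFKC + casefold) and token-based
(`[#@]?\w+`): `word`/`phrase` match the keyword's token sequence at word
boundaries (multi-token surfaces are exact n-grams; windowed proximity
is out of scope), `hashtag` matches with or without the leading `#`,
`handle` matches the author field or an `@mention` and retrieves
unconditionally (promotional-account rule).  Boolean rules are nested
any/all/not trees over declared keywords; compilation errors name the
offending leaf.  Exclusions are co-occurrence veto pairs.  No stemming:
surface variants are enumerated explicitly in the keyword list.
Keyword screening computes matches per calendar month (timestamps
normalized to UTC) and precision among coded matches, discarding a
keyword below 10 matches/month or below 0.30 precision (both
thresholds configurable).

## Synthetic corpus generator

The generator plants the exact statistical structure the estimators
assume: relevance ~ Bernoulli(prevalence); filter flags and coder labels
are conditionally independent Bernoulli mechanisms given truth with the
configured recall/specificity per classifier; ambiguous decoy phrases
are embedded in a fraction of irrelevant messages so naive term filters
show false positives.  Defaults echo the shipped worked example
(prevalence 0.028, filter recall 0.93 / specificity 0.999, coder recall
0.96 / specificity 0.998).  Text is bag-of-terms from small templates —
deliberately unrealistic.  Passing tests therefore demonstrate
statistical correctness of the estimators under the models' own
assumptions (including conditional independence, which real coders
reading real text may violate), not robustness to real platform
language, spam, near-duplicates or drifting slang.

## Problem sizes used in the test suite

Module tests run shortened chains (3k–40k cycles) and medium corpora
(2e5–5e5 messages); parameter-recovery checks use 20 seeded replicates
per model with a 3-posterior-SD criterion and a small allowance for
expected 3-sigma misses.  The full 100,000-cycle configurations run in
the reproduction script and the acceptance-style tests only.

## Known limitations

- Identifiability of the latent-class model rests on conditional
  independence and informative priors; with a single 2x2 table the
  likelihood alone cannot separate five parameters.
- The unarchived model treats n2 as exact even when it is only
  approximately known; no error-in-n2 term.
- One filter/topic per table; no joint multi-topic estimation, no
  covariate-dependent error rates, no 3+ classifiers.
- The bootstrap recall interval conditions on P(retr) (archive counts
  known exactly).
- The filter engine is a research instrument for corpus partitioning,
  not a streaming collector: no rate limits, APIs, or deduplication.
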
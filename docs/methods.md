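# Methods

## The estimand

The Number Needed to Beat (NNB) is the smallest number k of human raters
whose averaged item ratings correlate with a gold standard significantly
better than a single reference rater's ratings do. "Significantly" is
operationalised with a one-tailed one-sample t-test over participant
combinations, pooled across stimulus lists, in two modes: the per-
combination difference ρ_ref − ρ_k tested against 0, and the ratio
ρ_ref / ρ_k tested against 1, both with the alternative "less than". The
NNB per mode is the smallest k with p < α; the full per-k curve is always
reported because significance need not be monotone in k, and no requirement
is imposed that larger k stay significant.

Combinations that share raters are treated as independent observations.
This is deliberate pseudo-replication: it is what the NNB's definition
demands (the reported degrees of freedom equal the pooled combination count
minus one), and applying a cluster-robust or permutation correction would
change the meaning of the statistic. Users should read the t statistics as
descriptions of the resampling distribution, not as inferences about a
rater population.

## Design choices

- **α = 0.05, one-tailed.** The analysis convention treats p-values of .01
  and .03 as significant; 0.05 is the natural operating point and is
  config-exposed.
- **Combination cap 500.** If C(n, k) ≤ 500 every combination is
  enumerated (deterministic lexicographic order); otherwise 500 distinct
  combinations are drawn uniformly without replacement by rejection
  sampling on the sorted-tuple encoding, seeded per (list, k) from the
  study seed so results are reproducible and adding a list or k does not
  shift other draws.
- **Orientation.** Difference and ratio are reference-over-human so that
  "beating the reference" shows up as negative t statistics. The
  cost/quality module's *quality ratio* is the reciprocal orientation
  (sample over reference), matching its parity-at-1 reading.
- **Ties.** Spearman's ρ is Pearson on mid-ranks (average ranks for ties),
  the standard convention.
- **Undefined correlations.** Fewer than 3 paired observations, or a
  constant vector, yields NaN rather than an exception or a ±1 artifact.
  NaNs are dropped from summaries and from the per-combination test
  statistics with a logged count (ratios also drop combinations whose
  human correlation is exactly 0).
- **Degenerate tests.** If the pooled per-combination statistic has zero
  variance, t is undefined and p is set to 0 when all values lie on the
  alternative side, 1 otherwise, with a warning.
- **Missing responses.** Items nobody in a combination rated are absent
  from that combination's mean; correlations use pairwise deletion over
  the item intersection with the gold standard. No imputation.

## Exclusion screens

Applied in the order catch → response-time → straight-liner →
gold-correlation, so the correlation screen sees cleaned trials (the
order is a package choice; the screens are near-orthogonal in practice).
All thresholds use strict inequalities: a catch failer answers anything
other than the expected response; trials *under* 500 ms are dropped;
straight-liners answer the same way on *more than* 80% of trials; raters
correlating with the gold standard *below* 0.1 are removed. The catch
screen and the RT/straight-liner screens are per-dataset options (not all
designs include them); the gold screen always applies. A rater whose
screening correlation is undefined (constant responses) is retained with
a warning — the straight-liner filter, not the correlation screen, is the
instrument for constant responders.

## The simulator and its oracles

`crowd_sim` generates studies under a parallel-rater model: latent item
values t ~ Normal(scale midpoint, σ_t) per item, human responses t + ε
with ε ~ Normal(0, σ_e) i.i.d. across raters and items, and a reference
rater t + ε_ref. The gold standard is the latent value itself by default,
which makes two closed forms exact:

- a single rater correlates with gold at r₁ = σ_t / √(σ_t² + σ_e²);
- the mean of k raters correlates at √(k r₁² / (k r₁² + 1 − r₁²))
  (the Spearman–Brown prophecy transported to the correlation scale);

whence the predicted NNB: the smallest k with that expression above
r_ref, i.e. ⌊ r_ref²(1−r₁²) / (r₁²(1−r_ref²)) ⌋ + 1, with a not-reached
sentinel at r_ref = 1. These are the independent oracles of the
parameter-recovery tests: simulated studies at the default design
(17 lists × 50 items × 10 raters, continuous responses) recover the
predicted NNB within ±1 across seeds for well-separated (r₁, r_ref)
pairs. Near the exact crossing the empirical NNB legitimately lands on
either neighbouring integer — finite item counts put sampling noise of a
few hundredths on every list-wise correlation — which is why the
recovery contract is ±1, not equality.

Defaults (17 × 50 × 10, r₁ = 0.6, r_ref = 0.8) mirror a realistic
concreteness-norming replication: lists of ~50 items rated by ~10 raters
each, individual humans clearly noisier than a strong LLM rater.

What the simulator deliberately does **not** model: rater-specific bias or
severity, item-difficulty heterogeneity, non-Gaussian or heteroscedastic
noise, list-assignment imbalance, and response styles beyond the
straight-liner contaminant. Passing parameter-recovery tests therefore
shows the pipeline is correct under the additive-noise model, not that
real raters obey it. Two realism options exist: `round-to-scale` clips
and rounds responses to the integer scale (slightly attenuating
correlations, so the continuous mode is the default for oracle tests),
and `gold_crowd_size` replaces the latent gold by the mean of a finite
simulated prior crowd.

A note on "continuous" tables: the trial-table contract keeps responses
within declared scale bounds, so the simulator widens the declared scale
to the generated support in continuous mode; rounded mode uses the real
integer scale.

## Cost model

Human judgments are priced at hourly_rate × seconds_per_judgment / 3600
(defaults $12/h and 5 s ≈ $0.0167) and reference judgments at
tokens × price-per-1k-tokens (defaults 20 input tokens at $0.0003/1k plus
10 output tokens at $0.0006/1k = $1.2 × 10⁻⁵). The cost ratio for k
humans is k × human cost / reference cost; centaur samples add one
reference cost to the numerator, so a centaur's cost ratio exceeds the
human-only ratio by exactly 1 at every k. Quality ratios aggregate the
per-combination correlations by their arithmetic mean within
(k, aggregator) before dividing by the mean reference correlation —
the aggregation level is a package choice, exposed by keeping the full
sampling table available. All cost figures are config parameters; the
wage and duration defaults are underestimates of real crowd costs
(helpers `implied_hourly_rate` and `seconds_per_judgment` recover the
effective figures from flat payments and completion times).

## Problem sizes

The test suite and the acceptance script run entirely on simulated data.
Brute-force equivalence checks use 2 lists × 5 raters (all 31 subsets per
list, exact to 1e-12); parameter recovery uses the default 17 × 50 × 10
design over 10 seeds per parameter pair, about 17 000 combinations per
study. These sizes were chosen to exercise every code path at full
fidelity while keeping a complete run in the tens of seconds.

## Known limitations

- The pooled t-test inherits the pseudo-replication discussed above.
- NNB is reported per correlation method (Spearman vs Pearson) and can
  differ between them on real data; the package computes whichever the
  config requests and takes no position on which is right for a dataset.
- Items missing from the gold or reference vectors are silently excluded
  from the analysis item set of their list (logged when a list drops below
  3 analysable items).
- The cost model knows nothing about platform fees, bonuses, currency, or
  prompt-length variation; it is a two-parameter sketch on each side.
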
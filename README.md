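# nnbkit

**How many human raters does a norming study need before their averaged
judgments are as good as a single strong reference rater — for example, a
large language model?**

`nnbkit` implements the *Number Needed to Beat* (NNB) analysis for
crowd-rating ("norming") studies in which stimuli are partitioned into
lists, each participant rates the items of one list on a bounded ordinal
scale, and previously published per-item means serve as the gold standard.
It is aimed at behavioural researchers deciding whether (and when) to
replace or augment human annotation with LLM ratings.

## What it computes

Let ρ<sub>ref</sub> be the reference rater's correlation (Spearman's ρ or
Pearson's r) with the gold standard on a list, and ρ<sub>k</sub> the
correlation of the mean of k human raters' responses. For every list and
every k, all combinations of k retained raters are enumerated (capped at
500 random distinct combinations per list and k); each combination's
per-item mean is correlated with the gold standard. Pooling combinations
across lists, a one-tailed one-sample t-test asks at which k the
per-combination statistic

- d = ρ<sub>ref</sub> − ρ<sub>k</sub> is significantly below 0 (*difference* mode), or
- r = ρ<sub>ref</sub> / ρ<sub>k</sub> is significantly below 1 (*ratio* mode).

The smallest such k is the **NNB**. Two hybrid ("centaur") estimators are
evaluated alongside the human-only mean:

- **Centaur 1** — the reference rating averaged with the human sample mean
  (reference weight ½ regardless of k);
- **Centaur 2** — the reference rater added to the sample as one more
  participant (reference weight 1/(k+1)).

Before any of that, the data pass the standard exclusion screens: catch
trials, a 500 ms response-time floor, straight-liner removal (modal
response on more than 80% of trials), and a gold-standard correlation
screen at 0.1 — each applicable per dataset, with strict boundary
semantics.

A cost model prices a human judgment from an hourly wage ($12/h, 5 s per
judgment ≈ $0.017) and a reference judgment from per-token API prices
(≈ $1.2 × 10⁻⁵), and turns the sampling table into cost-ratio /
quality-ratio trade-off curves (1 = parity with the reference rater).

The `crowd_sim` module simulates whole studies under a parallel-rater
model (response = latent item value + i.i.d. noise). Under that model the
mean of k raters correlates with the latent values at

√( k·r₁² / (k·r₁² + 1 − r₁²) ),

where r₁ is a single rater's correlation — a closed form that predicts the
NNB analytically and anchors the package's parameter-recovery tests.

## Worked example

Simulate a 4-list study (40 items per list, 10 raters per list) in which a
single rater correlates with the truth at r₁ = 0.6 and the reference rater
at 0.8, then run the full analysis:

```python
import nnbkit as nk

sim = nk.SimConfig(
    n_lists=4, items_per_list=40, raters_per_list=10,
    rater_noise_sd=nk.noise_sd_for_correlation(0.6),
    reference_noise_sd=nk.noise_sd_for_correlation(0.8),
    rounding="continuous", seed=42,
)
trials, gold, reference = nk.simulate_study(sim)
config = nk.StudyConfig(scale=trials.scale, correlation_method="pearson", rng_seed=42)

clean, report = nk.run_exclusions(trials, gold, config)
table = nk.sampling_analysis(clean, gold, reference, config=config)
nnb = nk.compute_nnb(table, "human_only", alpha=config.alpha)
print("NNB:", nnb.nnb)
print("predicted:", nk.predicted_nnb(0.6, 0.8))
```

prints

```
NNB: {'difference': 4, 'ratio': 4}
predicted: 4
```

i.e. four average raters are needed to beat the reference rater, exactly
where the closed form puts the crossing (√(4·0.36/(4·0.36+0.64)) = 0.832 >
0.8 > 0.793 at k = 3). The per-k test curve shows the crossing:

```
 k       mode          t   df             p
 1 difference  13.611289   39  1.000000e+00
 2 difference  12.427528  179  1.000000e+00
 3 difference  -0.630005  479  2.644960e-01
 4 difference -22.293738  839  3.923002e-87
```

and the trade-off curve prices those four raters at 5 556× the reference
rater's cost for 1.05× its quality:

```
 k aggregator  cost_ratio  quality_ratio
 4 human_only 5555.555556       1.054821
```

The same pipeline runs from the shell on CSV inputs:

```bash
nnbkit simulate --config sim.yaml --outdir fixtures/
nnbkit run --config cfg.yaml --outdir results/
```

writing `clean_trials.csv`, `exclusion_report.json`, `sampling.csv`,
`nnb.json`, `tradeoff.csv` and a reproducibility manifest.

## Validating against a real study

The simulator stands in for real data; nothing in this repository ships
empirical ratings. To run the pipeline on a published norming replication,
export the trial data to the long CSV format
(`participant_id,list_id,item_id,response,rt_ms,trial_type`), the published
norms and the reference rater's ratings to two-column `item_id,value`
files, set the scale and exclusion flags in the YAML config to match the
study design, and run `nnbkit run`. The NNB you obtain is specific to that
dataset, scale and correlation method.
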
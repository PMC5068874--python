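# behentropy

Entropy-rate and fragmentation analysis of scored animal-behavior event
logs, built for maternal-care studies that compare dams across rearing
environments (e.g. control cages vs impoverished limited-bedding/nesting
"LBN" cages), and usable for any two-group ethogram study with replicate
cohorts.

The total *amount* of maternal care often fails to distinguish rearing
environments; what differs is its *pattern*. This package quantifies two
pattern properties per dam:

- **Fragmentation** — behavior is delivered in more, shorter *bouts*
  (maximal contiguous runs of one behavior): bout count per observation
  period and mean bout duration, per behavior.
- **Unpredictability** — the sequence of successive distinct behaviors
  (the *jump chain*) is more random. From the matrix of conditional
  probabilities `P_ij = P(next behavior j | current behavior i)` and state
  weights `w`, the entropy rate

  `H = − Σ_i w_i Σ_j P_ij log₂ P_ij` (bits per transition)

  is 0 for a perfectly predictable sequence and at most `log₂(k − 1)` for
  `k` behaviors.

Dam-level measures are compared between groups by a t-test on the group
coefficient in a linear model with fixed cohort effects, plus Welch
t-tests and Pearson correlations. A semi-Markov generator simulates whole
studies with known entropy rates and bout-duration means, so the entire
pipeline is verifiable end to end; see `docs/methods.md` for the model and
all defaults.

## Worked example

Simulate the default synthetic study — 4 cohorts × 2 dams per group per
cohort, two 50-min sessions/day for 8 days, light phase for all cohorts
and dark phase for three — with group entropy targets 1.61 (CTL) vs 1.81
(LBN) bits and licking/grooming mean bouts of 105 vs 42 s, then analyze
and compare:

```python
import behentropy as be

config = be.GeneratorConfig(seed=1)
dataset = be.simulate_study(config)
table = be.summarize_study(dataset.logs, config.ethogram)
light = table[table["phase"] == "light"]
print(light.groupby("group")[["entropy_rate", "meanbout_lick_groom",
                              "nbouts_lick_groom"]].mean().round(3))

result = be.cohort_adjusted_group_test(
    light["entropy_rate"], light["group"], light["cohort"],
    measure="entropy_rate",
)
print(result.summary())

corr = be.correlations(light, "entropy_rate", "meanbout_lick_groom")
print(f"r(entropy, mean bout) = {corr.r:.3f}  (n = {corr.n}, p = {corr.p:.4f})")
```

prints

```
       entropy_rate  meanbout_lick_groom  nbouts_lick_groom
group
CTL           1.572              100.092             71.000
LBN           1.775               42.249            145.375

Cohort-adjusted group comparison: entropy_rate
  group effect  +0.2029  (se 0.0286)
  t(11) = 7.105,  p = 1.982e-05
  n = CTL: 8, LBN: 8
  coefficients:
    intercept      +1.5505  (se 0.0319)
    group[LBN]     +0.2029  (se 0.0286)
    cohort[cohort2] +0.0269  (se 0.0404)
    cohort[cohort3] +0.0510  (se 0.0404)
    cohort[cohort4] +0.0086  (se 0.0404)

r(entropy, mean bout) = -0.916  (n = 16, p = 0.0000)
```

The LBN-regime dams come out roughly 0.2 bits less predictable (the
configured gap; the estimates 1.572/1.775 sit slightly below the 1.61/1.81
targets because the plug-in entropy estimator is mildly biased downward at
finite transition counts), with less than half the control bout duration
and about twice the bout count — and entropy and mean bout length are
strongly negatively correlated across dams, the fragmentation–
unpredictability coupling the generator builds in.

The same pipeline runs from the shell on the event-log CSV dialect
(`dam_id,group,cohort,phase,day,session_id,start_s,end_s,behavior`):

```
behentropy simulate --seed 1 --out data/
behentropy analyze --events data/events.csv --out results/   # summary.csv,
                                                             # transition_*.csv
behentropy compare --summary results/summary.csv --out results/compare.csv
```

Analyzing your own scorings: write intervals in that CSV dialect, supply
your ethogram as a YAML list of labels (`--ethogram`), and start at
`analyze`. Transition heat-maps (`--heatmaps`) render the per-dam matrix
CSVs; entropy estimates from fewer than `--min-transitions` (default 20)
transitions are reported as missing with a QC flag.

## Model and fitting API

`JumpChain(sequences, ethogram).fit()` returns a `TransitionModel` with
`counts`, `probs`, `weights`, `entropy_rate(base=2)`, `summary()`,
`simulate()` and `plot_heatmap()`; `GroupComparison.from_dataframe(...)
.fit()` returns the cohort-adjusted test result. `analyze_dam` /
`summarize_study` wrap these per dam and per study.

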
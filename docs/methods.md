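# Methods

## The measures

`behentropy` quantifies two complementary properties of a scored behavior
stream — how *fragmented* each behavior is, and how *unpredictable* the
sequence of behaviors is — for maternal-care observations of rodent dams in
control (CTL) versus limited-bedding/nesting (LBN) cage environments, or any
comparable two-group ethogram study.

**Fragmentation.** A *bout* is a maximal contiguous run of one behavior;
its duration is the scored time in seconds. For each behavior we report the
bout count per total observation period, the mean bout duration
(total / count), and the total duration. Fragmented care means more,
shorter bouts of the same total care.

**Unpredictability.** The sequence of successive distinct behaviors forms a
*jump chain* on the ethogram's `k` states. From the pooled within-session
bout transitions we form the count matrix `N` and its row-normalized
conditional probability matrix `P` (maximum likelihood; optional Laplace
pseudocount for sparse heat-maps). The entropy rate

    H = − Σ_i w_i Σ_j P_ij log₂ P_ij        (0 log 0 := 0)

is the expected per-transition Shannon entropy, in bits by default. Because
a bout ends exactly when the behavior changes, `P` has a structurally zero
diagonal and `0 ≤ H ≤ log₂(k − 1)`; `H = 0` for a perfectly predictable
(deterministic) sequence.

## Modeling assumptions and choices

- **State weights `w`.** Default: empirical source-state frequencies
  (`w_i` = transitions out of state `i` / all transitions), which are well
  defined even when the observed chain is not irreducible (short sessions,
  rare behaviors). The left fixed point of `P` (`eigen`) is available as an
  option; the solver restricts `P` to its recurrent communicating classes,
  verifies the L1 residual of `wP = w` below 1e−10, and falls back to the
  empirical weights with a warning when the fixed point is not unique. The
  two choices agree asymptotically (tested).
- **Log base.** Default 2 (bits); `e` and 10 are accepted. The base is
  recorded in every output row so entropy values are interpretable.
- **Pooling.** Per-dam entropy is computed per phase scope by pooling that
  scope's transition counts, not by averaging per-session entropies. This
  matches per-total-observation-period reporting of bout counts and uses
  all transitions at once; per-session averaging would inflate small-sample
  bias session by session.
- **Bout merging.** Two same-behavior intervals separated by an unscored
  gap ≤ `merge_gap` seconds (default 0) merge into one bout whose duration
  excludes the gap. Unmerged gap-separated same-behavior bouts stay
  separate bouts for fragmentation but contribute *no* transition: the jump
  chain's diagonal stays structurally zero. Gaps are unscored time, never a
  state; treating "gap" as a state would silently change the state space.
- **Session boundaries.** Transitions never span sessions; splitting a
  session at a bout boundary removes exactly one transition (tested).
- **QC threshold.** Entropy is reported as missing (`qc_flag =
  low_transitions`) below 20 observed transitions: the plug-in estimator's
  downward bias (≈ (#nonzero cells − k) / (2N ln 2) bits) is severe on very
  short chains. The threshold is configurable; no bias-corrected estimator
  (Miller–Madow etc.) is applied beyond this gate.
- **Group inference.** OLS of the dam-level measure on an intercept, a
  group indicator (LBN = 1) and fixed-effect cohort contrasts
  (lexicographically first cohort as reference), with a two-sided t-test on
  the group coefficient. Residual degrees of freedom are reported as
  `n − p` for the fitted design — the package reports its own df
  transparently rather than reproducing any particular published df
  accounting. A cohort containing only one group makes the design rank
  deficient and is reported as such, naming the collinear columns.
  QC-flagged (missing) values are excluded listwise with a logged count.

## The synthetic-data generator

The generator produces event logs with the statistical structure the
analysis assumes — a semi-Markov process: a jump chain chooses the next
behavior, an exponential (optionally gamma) duration distribution chooses
how long it lasts. It emulates the observation design of the maternal-care
study it is modeled on: 4 cohorts × 2 dams per group per cohort (16 dams),
two 50-minute sessions per day for 8 days per phase, light-phase
observation for every cohort and dark-phase observation for all but the
last — hence 8 dams per group with light-phase data and 6 per group with
dark-phase data.

- **Jump chains.** The calibration base is a cycle-dominant matrix: each
  behavior has one dominant successor (probability 0.75), with the
  dominant successors forming a single cycle (irreducibility by
  construction) and the remainder spread uniformly. Rows are tempered
  (`p^(1/τ)`, renormalized) and τ is found by log-space bisection so the
  closed-form entropy rate (stationary weights) hits the group target
  within 1e−4: defaults 1.61 bits (CTL-like, sharply structured rows) and
  1.81 bits (LBN-like, flatter mid-range rows). Entropy is monotone in τ
  for this family; the bracket is checked and an unreachable target raises
  an error reporting the achievable interval.
- **Durations.** Exponential by default, with behavior- and group-specific
  means: licking/grooming 105 s (CTL) vs 42 s (LBN) — the fragmentation
  contrast — and 120 s vs 60 s placeholders for the other behaviors. Draws
  are rounded to whole seconds (minimum 1 s); the final bout is truncated
  at the session end so sessions are fully tiled. The true bout-duration
  family in real data is unknown; exponential is a modeling default, and a
  gamma option exists. Because LBN pairs the higher-entropy chain with
  shorter bouts, high entropy and high fragmentation co-occur in the same
  synthetic dams, reproducing the negative within-group
  entropy–mean-bout-length coupling as a property of the generating model.
- **Cohort effects** enter as multiplicative factors on duration means
  (default 1.0 — the cohort terms in the inference model then absorb only
  sampling noise). **Unscored gaps** are not generated by default;
  `gap_prob` injects them for I/O robustness tests only.
- **Reproducibility.** One master seed; each dam's stream is seeded by a
  SHA-256 hash of `(master_seed, dam_id)`, so any dam regenerates
  bit-identically in isolation and generation order is irrelevant. The
  manifest records every per-dam seed.

### What the generator does and does not emulate

It reproduces the study design's dimensions, the entropy/fragmentation
contrast, and their within-dam coupling. It does **not** model circadian
modulation within a phase (dark-phase durations reuse the group means),
between-dam heterogeneity beyond cohort factors, pup-state feedback,
duration-dependent transition probabilities (the jump chain is first-order
Markov), or the observational scoring process itself. Passing the recovery
tests therefore shows the *pipeline* is correct and well calibrated under
the assumed model — not that real maternal behavior follows a first-order
semi-Markov process.

## Power analysis and the null configuration

`power_analysis` recalibrates the LBN chain to the CTL entropy target plus
each grid effect, simulates full studies, runs the pipeline end to end
(summarize → cohort-adjusted group test on light-phase entropy), and
reports Monte-Carlo rejection rates with binomial standard errors. At
effect 0 this estimates the type-I error under the configured design,
which may keep group-specific durations (unequal per-dam transition counts,
hence unequal estimator variances). For a pure type-I check,
`GeneratorConfig.null()` removes *all* group differences (shared CTL chain
and durations), making dams exchangeable across group labels.

## Problem sizes and numerical points

Validation simulations use chains of 1.5 × 10⁵ transitions for estimator
consistency (max-entry error and entropy error both below 0.02) and 200
study replicates for power and type-I checks; the full default study
(16 dams, ≤ 32 sessions each) simulates and analyzes in well under a
second. Fixed-point solves replace one linear equation with the
normalization constraint and verify the residual; probability rows sum to
1 within 1e−12; ties in bisection terminate after 200 iterations. Empty
rows of `P` are NaN (flagged), never renormalized; a session shorter than
its first bout yields a single truncated bout and zero transitions, which
the QC gate reports as missing entropy rather than a number.

## Known limitations

- The six-state default ethogram is a package default for a realistic
  repertoire, fully user-overridable; analyses of real data should supply
  the ethogram actually scored.
- The plug-in entropy estimator is negatively biased at small transition
  counts; the QC gate bounds but does not remove this bias. Group
  contrasts are robust to it insofar as the bias is similar across groups
  (it shrinks with more transitions, i.e. with more fragmented behavior).
- Time resolution is 1 s; sub-second scoring is rounded by the generator
  and rejected by the CSV dialect.
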
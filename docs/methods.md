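# Methods

## Signal model and resampling

Consumer force platforms emit CoP samples at an inherently non-constant
rate. The resampler places a uniform grid at `rate` = 25 Hz starting at the
first raw timestamp and restricted to the raw time span (output length
`floor(span·rate) + 1`). Each output value is the arithmetic mean of raw
samples in the closed window of width `window` (default `1/rate` s)
centered on the grid time; grid points whose window is empty are filled by
linear interpolation between the nearest non-empty window means, with
constant extension at the record edges. The default window makes the
operator exact on grid-aligned input and an identity on constant signals,
and it commutes with constant offsets. Traces spanning less than two
output periods are rejected ("trace too short"), as are duplicate
timestamps (ill-posed averaging weights). Units are centimetres and
seconds throughout; no unit conversion happens anywhere downstream.

## Descriptors

Five descriptors summarise a subject's two records (closed eyes `cl`,
open eyes `op`):

| name | definition | unit |
|---|---|---|
| `rho_cl_50` | median distance from the trajectory mean point | cm |
| `a_cl_10` | 10th percentile of the acceleration norm | cm·s⁻² |
| `var_y_cl` | unbiased variance of the AP coordinate | cm² |
| `x_ratio_10` | closed/open ratio of the 10th-percentile ML coordinate | — |
| `var_ibi_op` | unbiased variance of the ballistic intervals | s² |

Conventions fixed here (all configurable via `FeatureConfig`):

- **Percentile**: linear interpolation between order statistics at position
  `(n−1)·q` — the common numpy default, fixed for reproducibility.
- **Acceleration**: per-axis central second difference times `rate²`,
  endpoints dropped; exact for quadratic motion.
- **Sway density**: forward first-exit time — `dwell(i) = dt·(j−i)` with
  `j` the first later sample farther than `circle_radius` (default
  0.25 cm, the conventional value in the sway-density literature) from
  sample `i`, truncated at the record end. A symmetric (backward+forward)
  mode is available for comparability with the wider literature.
- **Peaks**: the dwell curve is smoothed by a 0.48 s centered moving
  average (shrinking at the edges); strict local maxima closer than 0.2 s
  are merged keeping the larger (ties keep the earlier). Ballistic
  intervals are successive differences of the sorted peak times; their
  variance needs at least three peaks, otherwise extraction fails with
  "insufficient sway-density peaks".
- **ML ratio**: computed on *uncentered* ML coordinates. Centering would
  make both percentiles almost surely negative and the ratio nearly
  constant; off-center stances keep the denominator away from zero, and a
  guard (`|denominator| < 1e-6 cm`) rejects degenerate records. The ratio
  may be negative.
- **Variances** use the n−1 denominator (small interval counts).

Scaling the trajectory by `s` scales `rho_cl_50` and `a_cl_10` by `s` and
`var_y_cl` by `s²`; translations leave all but `x_ratio_10` unchanged.
These invariances are property-tested.

## Ranking forest

The score combines the five descriptors with a bagged ensemble of 50
cross-entropy decision trees. Per tree: a random subsample of
`subsample_fraction` = 0.8 of the training records drawn *without*
replacement; greedy top-down induction; at each node 3 of the 5 features
drawn without replacement, candidate thresholds at midpoints between
consecutive distinct values, and the split minimising the size-weighted
child cross-entropy (natural log). Stopping: depth 5, node smaller than
2·`min_leaf` (`min_leaf` = 5), or purity. Ties in impurity break to the
lowest feature index, then the smallest threshold, making the fit fully
deterministic given (data, config, seed).

A leaf scores the non-faller fraction of its training records,
Laplace-smoothed by ½ per class so isolated pure leaves do not pin the
average (raw fractions via `laplace=False`). The forest score is 100 × the
mean leaf score, in [0, 100], 100 = best balance; the faller probability
is `1 − score/100`. Feature importance per tree sums, over the nodes
splitting on a feature, the node-size fraction times the impurity
decrease, normalised to 1 within the tree (trees with no split contribute
a uniform vector); the model reports mean and sample std (ddof = 1) over
trees, means summing to 1.

Defaults were chosen a priori: depth 5 and `min_leaf` 5 are conventional
for n ≈ 10²; 3 of 5 features keeps a majority of the descriptor set in
play per node while decorrelating trees. Models serialise to versioned
JSON and round-trip losslessly.

## Evaluation protocol

One stratified split: per class, a seeded shuffle sends
`round(0.7·n_class)` records to training (clamped so both sets keep at
least one record per class). The forest is fit on the training subjects
and judged by ROC/AUC on the test subjects; the ROC is a full threshold
sweep with tie grouping, and its trapezoidal area equals the
Mann–Whitney pair statistic with half credit for ties (tested to 1e-12).

Per descriptor the report gives class means/stds on the full cohort, the
two-tailed Wilcoxon rank-sum p (exact enumeration when both groups have at
most 10 tie-free observations, otherwise the tie- and continuity-corrected
normal approximation — the approximation's worst-case error versus exact
enumeration exceeds 0.02 below 5 observations per group, which is why
small samples route to the exact branch), and the test AUC of a 1-D
soft-margin linear SVM (C = 1) fit on the training split of that single
descriptor. The SVM's test decision values are used as-is — no post-hoc
reorientation — so reported AUCs can fall below 0.5. Univariate AUCs use
the same split as the forest by default (a full-sample option exists). No
multiple-testing correction is applied; p < 0.05 is flagged per test.

## Synthetic cohort

Per axis the sway is an Ornstein–Uhlenbeck process around the stance point
`(stance_offset_ml, 0)`, advanced with the exact transition between
consecutive irregular timestamps and started from its stationary law, so
the jump-free stationary variance is `noise²/(2·stiffness)` (checked by
simulation against the closed form). Poisson-timed ballistic
repositioning jumps (rate `jerk_rate`, per-axis scale `jump_scale`) are
added to the state and pulled back by the mean reversion — this produces
the sway-density peak structure. Timestamps have increments
`1/60 Hz · exp(N(0, 0.2))` (log-normal jitter), strictly increasing by
construction; the closed-eyes record multiplies the diffusion noise by
`closed_eyes_gain` ≥ 1, encoding increased visual reliance.

With jumps the stationary per-axis variance is
`(noise² + jerk_rate·jump_scale²)/(2·stiffness)`; the default phenotypes
are placed on that *total*-amplitude axis and on the jerkiness axis in an
XOR-like arrangement: non-fallers intermediate on both; one faller
phenotype wide and smooth (total variance ≈ 1.7× non-faller, jumps rare),
the other narrow and jerky (≈ 1/1.7×, jumps frequent but small), mixed
50/50. This is the only generator family consistent with the premise that
marginal descriptors fail while their combination succeeds: each
descriptor responds monotonically to one axis, so the 50/50 faller
mixture straddles the non-fallers and univariate AUCs sit near 0.5, while
axis-aligned tree splits isolate the central non-faller band. The default
cohort calibration (n = 200, default seed) yields every univariate
descriptor AUC ≤ 0.60 against a forest held-out AUC ≥ 0.70; because the
test set contains only ~17 fallers, the univariate AUCs move in steps of
1/17 and an unlucky phenotype imbalance in the test draw can push the
largest of them somewhat above 0.6 under other seeds — the qualitative
gap to the forest (which stays ≥ 0.95 across seeds) is unaffected.

What the generator does **not** emulate: inverted-pendulum biomechanics,
sensor quantisation and drift, inter-trial learning effects, demographic
covariates, or the descriptor correlations of real elderly cohorts.
Passing tests therefore show the pipeline is a faithful, deterministic
implementation of the method and that it recovers planted joint structure
that univariate analysis misses — not that the same AUC would be achieved
on a clinical population.

## Problem sizes and numerical choices

The test suite and the acceptance script use cohorts of 200 subjects with
two 25 s records each (≈ 1500 raw samples per record at the jittered
60 Hz device rate, 625 after resampling) — the full study-scale signal
path — and smaller cohorts (14–30 subjects, 10–12 s records) where only
plumbing is exercised. Determinism is end-to-end: a single global seed
fans out to per-stage substreams (synthetic, split, forest) via
`numpy.random.SeedSequence` in fixed order, artifacts embed the config
hash and seed, and reruns are byte-identical.

## Known limitations

- The exact resampling window and interpolation rule of the original
  SWARII reference, and the study's tree depth/regularisation, are not
  published; the defaults here are declared and configurable but cannot be
  verified against the study's unreleased data.
- Sway-density peak detection has no field-standard rule; results for
  `var_ibi_op` depend on the smoothing window and separation defaults.
- Single-split evaluation (as in the protocol) has high variance at n ≈
  100–200; the CLI accepts repeated seeds but no aggregate statistic is
  defined.
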
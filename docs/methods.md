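# Methods

## Scope and model

`cogscore` implements a pairwise discrimination analysis for a
neuropsychological screening battery with 14 sub-scores across three
diagnostic groups (HC, SCD, MCI). The analysis chain is: parallel
two-mediator path models per sub-score → selection of sub-scores whose group
difference is purely direct → orientation and min–max normalization →
eight composite total-score formulas → ROC/Youden classification per
formula → best-formula choice. The battery's raw data are not distributable,
so a synthetic-cohort generator reproducing the assumed statistical
structure is part of the package and is what the tests and the acceptance
script exercise.

## Battery registry

The 14 sub-scores are registered with id, kind, bounds and orientation
(`battery.json`, shipped with the package). The revised digital tasks have
explicit scoring rules: three cognitive-flexibility conditions rated as
erroneous sets out of 8; a visual-fluency condition counting distinct
orderings of 4 pads (4! = 24 possible); two window-recognition conditions
rated as errors out of 15. The baseline tasks are opaque numerics: no
published ranges exist, so they are unbounded, and the error/time-penalty
scores (ACT, the inhibition/switching family, CFT) are registered as
unbounded error counts — which also makes the registry invariant
"higher-worse ⇔ error count" exact. Working-memory scores and the fluency
count are higher-better; orientation of higher-worse scores is by
reflection (max − raw when bounded, −raw otherwise), which is equivalent to
negation after min–max normalization (affine invariance) but keeps bounded
intermediate values in their documented range.

## Synthetic cohort generator

Each participant gets age and education from group-specific normal
distributions and sub-scores from the linear structural model

    score = intercept + c·stage + b_age·age + b_edu·education + ε,

with stage the diagnostic severity (HC 0, SCD 1, MCI 2) and ε Gaussian.
Because mediator distributions are group-specific, the diagnosis→mediator
paths of a two-group contrast are the group mean differences;
`pair_config()` exposes the (a_age, a_edu, b_age, b_edu, c_direct)
parameterisation directly for oracle tests.

Defaults (all configuration, not constants):

- group sizes 20/29/31; ages ≈ N(61.6, 6.6), N(61.2, 7.0), N(68.7, 8.4)
  years; education ≈ N(16.3, 3.0), N(13.3, 4.2), N(13.5, 4.3) years —
  a typical memory-clinic validation sample of this design;
- per-sub-score severity steps and residual spreads chosen so that
  single-sub-score pairwise discriminations are moderate (one-step AUC
  ≈ 0.55–0.75, two-step up to ≈ 0.9), with heterogeneity across sub-scores
  (inhibition/switching, flexibility and episodic-memory errors carry the
  strongest gradients); implied per-step standardized effects range from
  ≈ 0.1 (short-term store) to ≈ 1 (inhibition/switching);
- small residual age/education slopes (the battery is designed to be
  largely demographics-free);
- bounded scores are clipped to their documented range, with a per-subtask
  clip counter on the cohort (≈ 1–2% of values at the defaults) so tests
  can keep clipping negligible. Clipping, rather than resampling, keeps
  generation reproducible and one-pass.

What the generator does **not** emulate: inter-sub-score residual
correlation (real executive tasks correlate), floor/ceiling clustering
beyond what clipping induces, item-level responses, practice/order effects,
and non-Gaussian score shapes. Passing tests therefore demonstrate that the
pipeline's estimators and decision rules behave correctly under the assumed
linear-path structure — not that the battery itself attains any particular
accuracy on real patients.

## Mediation estimation

Per-path OLS: the direct effect is the diagnosis coefficient in
`outcome ~ diagnosis + age + education` with asymptotic normal z, p and CI
(matching the z-value columns conventionally reported); each indirect
effect is the product of the mediator-model slope and the outcome-model
mediator slope. The linear decomposition total = direct + Σ indirect holds
to machine precision and is asserted on every fit in the tests. Indirect
uncertainty comes from a nonparametric bootstrap, default 1000 resamples of
participants with replacement from the pooled pair (stratified resampling
per group is available); the CI is percentile and the p-value is the
bootstrap-z (point estimate over bootstrap SD, two-sided normal) — with the
percentile CI also reported, the bootstrap-z p is the default because a
z-style column is what effect tables in this literature print. Resamples
are drawn as one integer matrix and the per-resample normal equations are
solved batched, so 1000 resamples on an 80-row pair cost milliseconds;
degenerate resamples (single group) are redrawn.

The per-test level defaults to α = 0.05/k rounded to three decimals for a
k-outcome family — 0.004 for the conventional 13-outcome battery family
(and also for 14, by rounding). The pipeline fixes α = 0.004 regardless of
family size, overridable. Selection keeps sub-scores with significant
direct effect and **neither** indirect effect significant at the same α;
an empty selection produces a warning report rather than an error.
Missing data are handled complete-case per outcome.

## Normalization, weights and composites

Min–max statistics, σ after normalization (sample SD, ddof = 1,
configurable) and per-variable AUC are all computed on the pooled
two-group subsample of the pair under analysis: weight tables and cutoffs
are pair-specific by design, and pooling a third group would change them.
Orientation precedes normalization, so values near 1 mean better
performance; the per-variable AUC is computed with the impaired group as
the positive class on the oriented scale and folded to max(AUC, 1 − AUC)
for reporting, with the polarity retained as a flag. Constant columns
cannot be normalized; they are dropped from the composite with a record.
The eight formulas are evaluated exactly as written; squaring values in
[0,1] cannot increase them, so SΣ2 ≤ SΣ per participant (asserted as a
property test).

## ROC analysis

The AUC is the normalized Mann–Whitney statistic computed from rank sums
(ties counted ½), with the Hanley–McNeil SE; the p-value versus chance uses
the tie-corrected normal approximation to Mann–Whitney; the 95% CI is a
class-stratified percentile bootstrap (default 2000 resamples) — the CI and
p methods are package choices, as source tables in this literature rarely
state theirs. Cutoffs scan midpoints between adjacent distinct scores plus
±∞ sentinels (every achievable classification, reported as data-derived
midpoints); a participant is called impaired on the impaired side of the
cutoff, inclusive. Youden ties prefer higher sensitivity (screening
preference), then the lower cutoff. Composites are higher-better, so their
impaired side is *below* the cutoff; raw error counts are the opposite.
Quality bands apply to the AUC rounded to two decimals: 1.0 perfect,
0.90–0.99 excellent, 0.80–0.89 good, 0.70–0.79 fair, 0.51–0.69 poor; below
0.51 the package labels the score non-discriminative (an explicit extension
for a case the banding otherwise leaves undefined).

## Best-formula choice and the tie question

The best formula maximizes J, ties broken by higher AUC and then by the
canonical formula order with the plain sum first — preferring the simplest
formula when nothing beats it. At study-sized n (≈ 50–60 per pair) exact
(J, AUC) ties between formulas are common, because both statistics are
rationals with small denominators and several formulas are monotone
transforms of each other whenever a single sub-score dominates (with one
selected sub-score all eight are, and the ROC is identical by monotone
invariance). Consequently, any claim that one formula family "wins more
often" must be evaluated on strictly decided runs: a formula that merely
ties the plain sum discriminates no better and no worse. The formula
comparison (driver 05, acceptance suite) therefore counts runs with a
unique (J, AUC) maximizer; at the default conditions the weighted,
non-plain-sum formulas win roughly three quarters of strictly decided runs
across pairs, with the spread-scaled and AUC²-weighted variants the most
frequent winners.

## Numerical and design choices

- Diagnosis coding 0 = cognitively better group, 1 = worse (severity order
  HC < SCD < MCI); positive direct effects on error-like scores then mean
  "worse group makes more errors".
- All seeds flow through `numpy.random.SeedSequence` spawning (master run
  seed → per-stage → per-outcome/per-formula), so reports are byte-identical
  across reruns with the same cohort and config, and independent stages do
  not share streams.
- Bootstrap normal-equation batches fall back to per-resample least squares
  on singular batches.
- Degenerate inputs raise typed errors naming the offending variable
  (constant mediator/outcome, single-class ROC input, zero-range column),
  except where the contract prefers a warning (empty selection, dropped
  degenerate column).
- Problem sizes in the test and acceptance runs (e.g. 200 recovery
  replicates at 500/group, 500 null cohorts at 100/group, 100 cohorts for
  the formula comparison, reduced bootstrap sizes where only point
  estimates matter) were chosen as the smallest sizes at which the
  Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

- The mediation stage is per-path OLS in a fully linear, observed-variable
  system; it is not a latent-variable SEM and does not model
  mediator–mediator covariance beyond their joint dependence on diagnosis.
- The generator's independence of sub-score residuals makes composite AUCs
  somewhat optimistic relative to correlated real batteries.
- Bounded-score clipping slightly biases generating effects near the
  floor/ceiling; the clip counter makes this visible.
- Three-way (multi-class) classification, cost-weighted cutoffs, smoothed
  ROC fits and DeLong formula comparisons are out of scope.
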
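# Methods

This note records the model, the defaults that matter, the numerical
choices, and the places where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and splitting

EAV events are `(patient_id, timestamp, attribute, value)` rows; the
entity is the (patient, timestamp) pair. Timestamps are timezone-naive
ISO-8601 and compared as such; rows with unparseable timestamps are
dropped and counted rather than failing the load. Values parse as floats
where possible, otherwise stay strings; numeric operators skip non-numeric
values with a warning counter. Missing CSV fields are empty strings,
flagged internally and median/mode-imputed inside each trial's training
fold — never before splitting.

The progressive schedule carves a fixed test fraction (default 0.2,
stratified for categorical targets) out of the pool, then doubles the
training sample each round from an initial size of
`min(ceil(pool/8), 500)` (floor two per class) until the full trainable
pool: `sizes[k+1] = min(2·sizes[k], pool)`. Train sets are nested by
construction — prefixes of one seeded shuffle — so a configuration's
round-k sample is contained in its round-(k+1) sample. Because the test
sample guides elimination and ensemble selection, it is optimistically
biased; a further untouched holdout (default 0.2 of the test split) is
reserved for the reported final quality.

## Temporal aggregation

Windows are half-open `(index_date − period, index_date]`: the index-date
event contributes, the event exactly at the far edge does not. Period
enumeration starts at the schedule's shortest period and elongates
exponentially (default doubling) or arithmetically; when the progression
overshoots, the longest period itself is appended so the widest clinically
meaningful window is always a candidate.

Operator conventions the catalog needed but the operator names alone do
not fix:

* *monotone* operators (value trend, medication intensified/de-intensified,
  frequency trend) require ≥ 2 in-window observations and strict
  monotonicity, else 0;
* *change* = last − first in window; *relative change* =
  (last − first)/|first|, missing when the first value is 0;
* *frequency trend* bins the window backwards from its end into whole
  weeks (7 d), months (30 d) or quarters (91 d); a partial oldest bin is
  dropped and ≥ 2 complete bins are required;
* *fraction high/low/normal* needs a per-attribute reference range from
  the knowledge base; *fraction equal* takes the comparison value as a
  parameter;
* empty windows yield 0 for presence/count/duration/monotone/flag
  operators and missing for numeric ones (imputed downstream);
* medication *intensified/de-intensified* is defined here as strict
  monotone increase/decrease of the in-window dose values — a stand-in
  definition, flagged as such; *switched* and *multiple therapies* are
  registered in the catalog but deliberately unimplemented because no
  agreed definition exists, and constructing them raises.

Selection scores every enumerated (period, operator) candidate on a seeded
sample of instances (default `min(5000, all)`, stratified on categorical
targets) by information gain in bits — numeric features discretized into
10 equal-frequency bins, missing values as their own bin — or by variance
reduction for continuous targets. Exactly one pair per (attribute,
category) is returned, ties broken toward the shorter period then catalog
order; an all-zero category is still returned (seeded tie-break) with a
warning. The winning pairs are then computed for all instances and joined
to the static columns. The pivot filters events of unused attributes
before grouping and is identical for any worker count (instances are
chunked deterministically and reassembled in order).

## Search space and surrogate

The shipped roster covers decision tree, random forest, gradient
boosting, k-NN, regularized logistic/ridge regression, linear SVM and
Gaussian naive Bayes (classification only) — enough families to exercise
elimination; roster parity with any particular toolkit is a non-goal and
the registry is extensible. Feature-selection techniques are a search
method (top-k ranking, greedy forward over the 12 best-ranked columns
with a fast proxy model) crossed with an evaluator (information gain,
correlation, variance, model-based importance; ANOVA-F and mutual
information are also registered). "none" is always legal so the space is
never empty, and the FS choice is itself a dimension of the search point.

Numeric hyper-parameters encode min-max scaled to [0, 1] (log-scaled
first when flagged); categoricals one-hot. Each algorithm has its own
encoding that excludes every other algorithm's hyper-parameters; dropping
an evaluator shrinks all encodings. Neighbor generation perturbs one
parameter at a time by one step on a 20-point (log) grid — the
neighborhood structure is a design choice, not given by the method.

The surrogate is bagged regression trees (25 bags) per algorithm over
encoded configurations plus the training-sample size as an extra feature;
the cross-bag spread provides the predictive variance for expected
improvement, `EI = (μ−best)Φ(z) + σφ(z)`, `z = (μ−best)/σ`, degenerating
to `max(μ−best, 0)` at `σ = 0`. Until `dim + 2` completed trials exist
the surrogate is undefined and proposals fall back to pure random.
`best` is the highest completed quality observed so far for that
algorithm (any sample size); cross-size comparability is delegated to
the size feature rather than resetting `best` per round. Gaussian-process
surrogates were rejected: they handle neither categorical dimensions nor
a training sample that grows across rounds.

Expensive-monotone flags mark hyper-parameters that buy accuracy with
training time (tree counts in forests and boosting, direction up). During
the main search they are sampled only inside a capped range (10–100
trees); the refinement stage afterwards doubles the flagged value
geometrically from the best model's setting, retraining on the full pool,
and stops after two consecutive improvements below ε = 10⁻³ or when the
budget (default 8 trainings) is spent. The incumbent is replaced only by
a strictly better model.

## Rounds, elimination, runtime model, ensemble

Round 1 tests each algorithm's default plus 20 random configurations and
tops up every feature evaluator to 20 trials (top-ups counted separately
from the 20). Rounds ≥ 2 test up to 20 surrogate proposals per surviving
algorithm: the best-EI neighbor of each of the 10 best previously tested
configurations, interleaved with the top 10 by EI from a 10,000-point
random pool. From round 3, 30 random-pool candidates are first screened
on the cheap round-1 sample; the 10 best screened qualities form the
random group and the other 20 enter the surrogate's training set as
*scaled estimates* — small-sample quality plus the mean uplift observed
among configurations completed at both sizes (that algorithm first, then
any, then zero), clipped to [0, 1]. Estimated entries are flagged in the
ledger and never contribute to potentials, the best-so-far curve or the
final report. The scaling rule itself is a stand-in for an external
technique whose internals are not specified here.

An algorithm's potential is its highest completed quality; survivors are
those within δ_r of the best, δ_r = 0.10·2^(1−r) — a relative-to-best
margin is scale-free across AUC and R². At least two algorithms survive
until the final two rounds; the full-data round keeps exactly the argmax
and re-tests only its best few configurations (default 3) at full size,
so full-size trainings stay rare. Evaluators are eliminated analogously —
lowest potential first, one per round, only after every evaluator has
≥ 20 completed-or-skipped trials, until at most 4 remain; a dropped
evaluator is never proposed again and leaves all encodings.

Test time is predicted as `baseline × size_ratio × hp_ratio`: the
baseline is the measured default-configuration time from round 1; the
size ratio is `(n/n_base)^p` with the known complexity exponent, or the
log–log slope fitted from ≥ 3 distinct sizes, else 1; the
hyper-parameter ratio uses whichever of two approaches — a random-forest
regression on the encoding, or a product of per-parameter ratio functions
(known-linear parameters use value/default, other numerics a fitted power
law, the rest pinned at 1) — has the lower leave-one-out absolute
log-error for that algorithm, and is pinned at 1 until five observations
exist. A candidate predicted to exceed `f × T` (default f = 2, T starting
at 10 s and doubling each round) is recorded as skipped, never started.
In deterministic mode (the default) T is enforced *only* through
predicted-time skipping — no wall-clock aborts — so a run replays
identically for any worker count; trials are fully generated before
dispatch, executed through a work queue, and written to the ledger in
submission order. Wall-clock aborts exist behind a flag and are
explicitly nondeterministic. Measured wall times still differ between
runs; ledger comparisons therefore exclude the wall-time field, and at
the default T nothing is skipped on desk-scale fixtures.

The ensemble is Caruana-style forward selection with replacement on the
guidance test sample, initialized with the single best model, weights
equal to selection counts; the best ensemble state along the path is
returned, so its selection quality never falls below the best single
model's. The model library keeps the 20 best trial models plus the
retrained winner; optionally the top-k are retrained on the full pool
first (off by default to spare full-size trainings). Classifier outputs
are combined on a probability-like surface; margin-only classifiers
(linear SVM) are min-max mapped to [0, 1] per batch — a pragmatic choice
that preserves AUC for single models and keeps heterogeneous members
commensurable. Quality is AUC for categorical targets (macro one-vs-rest
beyond two classes) and R² for continuous ones.

Task-parallelism across trials is the only parallel regime implemented;
the `m`-round switch to data-parallel training is accepted in
configuration for interface fidelity but cluster data partitioning is out
of scope at desk scale.

## Projection

The best-so-far curve records `(t, max(quality, previous best))` after
every completed trial, t in seconds from search start (shifted by +1
before fitting to avoid the `t^−c` blow-up below 1 s). Fitting minimizes
`Σ (i/n)·(f(t_i) − y_i)²` over the last `n = min(g, h)` points
(g = 20 by default) with 16 seeded starts of bounded least squares;
the increasing case is parametrized as `(a, ρ = b/a, log c)` so the
constraint `0 < b < a < 1` holds by construction, the decreasing case
(error-rate curves) leaves b unconstrained above. Fewer than three
distinct times means "projection unavailable", not an error. Increasing
projections are clipped at their own asymptote `a`. Class-pair
confusion-fraction curves are fitted independently (diagonal increasing,
off-diagonal decreasing) and the projected rows are renormalized onto the
simplex — the independent fits do not themselves respect it. Continuous
targets are discretized into quantile bins before the categorical
machinery applies. A separate raw-trace fitting entry point exists for
series that are not cumulative maxima (class-pair fractions, external
traces), since the best-so-far floor would bias a noisy trace upward.

## Synthetic data

The cohort generator draws event timestamps from a homogeneous Poisson
process per attribute per patient (defaults: emergency visits at
0.6/month, weight measurements at 1/month ~ N(80, 8²) kg, a medication
dose at 0.8/month lognormal) over a one-year horizon, and builds the
target by thresholding the planted aggregate at its cohort median,
flipping labels with the configured noise probability (continuous
targets: standardized aggregate plus Gaussian noise). With noise 0 the
construction is exactly recoverable, which is what the planted-signal
tests exploit. The benchmark generator's `rule` family labels by the
parity of axis-aligned thresholds (one feature: a single threshold any
stump expresses; two: an XOR no linear model expresses), `linear` by a
logistic score over five features, `interaction` by a product sign.
What the generators do *not* emulate: irregular visit intensity tied to
disease severity, informative missingness, coded terminologies, measurement
error structure, or covariate shift between training and deployment — so
green tests certify the machinery, not clinical performance on real
records.

## Problem sizes

The test suite and the acceptance script run on 250–2,000-patient
cohorts, 500–2,000-row benchmarks, random pools of a few hundred points
(10,000 in production defaults), 5-seed medians for search-vs-grid
comparisons and 100-replicate recovery rates; these sizes make the whole
suite complete in a couple of minutes on one CPU while leaving every
qualitative property intact.

## Known limitations

* The wall-clock execution mode is honest about being nondeterministic;
  deterministic mode cannot abort a genuinely runaway learner, it can only
  refuse to start one predicted to be slow.
* The additive-uplift scaling rule and the dose-monotonicity definition of
  medication intensification are stand-ins, documented above.
* Ensemble score fusion across margin-only classifiers uses a min-max
  surface; calibrated probabilities would be better if calibration data
  were budgeted.
* Elimination with δ_r halving assumes qualities on a [0, 1]-like scale;
  unbounded losses would need a different margin schedule.
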
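# Methods

This note documents the models, the synthetic-data generator, the sampler,
and the numerical and design choices behind `prpddm`.

## The scientific setting

In the psychological refractory period (PRP) paradigm a participant performs
two choice tasks whose stimuli are separated by a stimulus-onset asynchrony
(SOA).  The canonical finding is that RT2 — the response time to the second
task, measured from its own stimulus onset — grows steeply as the SOA
shrinks, while RT1 is nearly unaffected.  Two mechanism families compete to
explain this:

* **Serial / response-selection bottleneck (RSB):** central response
  selection handles one task at a time.  At short SOAs the Task-2 decision
  must wait ("slack") for Task 1 to clear the bottleneck, and the waiting
  time is passed ms-for-ms into RT2.
* **Parallel / capacity sharing:** both decisions run concurrently but split
  a limited central capacity, so each accumulates evidence more slowly while
  they overlap.

Fit with a diffusion decision model, the two mechanisms make distinct
parameter predictions: serial processing inflates the Task-2 *non-decision
time* t0 at short SOAs (slack is decision-free waiting), whereas capacity
sharing depresses the Task-2 *drift rate* v at short SOAs (slower evidence
accumulation).  The package implements both generators, the constrained
diffusion model, and the estimation and decision layers needed to test those
signatures on synthetic data.

## Diffusion decision model

The decision stage is a Wiener process with drift v (evidence/s), diffusion
constant s = 1, absorbing boundaries at 0 and a, and an unbiased start
z = a/2.  Observed RT = first-passage time + non-decision time t0.  Accuracy
coding maps the upper boundary to correct responses.  All inter-trial
variability parameters are fixed at 0; z and s are structural constants
(enforced by the `DDMParams` type, not by convention).

The first-passage density uses the two classical series expansions of the
standardized process — the image (small-time) series and the spectral sine
(large-time) series — selecting per time point whichever needs fewer terms
for a relative truncation error of 1e-7.  With the unbiased start two closed
forms exist and serve as oracles throughout the tests:

* absorption probability:  P(upper) = 1 / (1 + e^{-a v})
* mean decision time:      E[T] = (a / 2v) tanh(a v / 2)   (a²/4 as v → 0)

A numba-compiled scalar kernel evaluates the summed log-density on the
sampler's hot path; a test pins it to the reference numpy implementation at
1e-10 relative error, so the two code paths cannot drift apart silently.

## Synthetic-data generator

Each trial is assembled from stages: RT_k = encode_k + decision_k + motor_k.
The **serial** generator starts the Task-2 decision at
max(soa + encode_2, encode_1 + d1) on the Task-1 clock — the bottleneck —
while the **parallel** generator starts it at soa + encode_2 but runs both
accumulators in one time-stepped walk, multiplying drifts by share_1 (Task 1)
and 1 − share_1 (Task 2) whenever both decisions are simultaneously active.
Walks use Euler–Maruyama steps of dt = 0.1 ms with a Brownian-bridge
within-step crossing correction (without it, first-passage times carry an
O(√dt) upward bias that a 1e5-draw goodness-of-fit test against the exact
density detects).  A 10-s absorption cap flags — never silently truncates —
pathological walks.

Schedules reproduce the studied designs exactly: three SOA levels with
80/10/10 per-block frequency splits (the SF group's 80% on the shortest SOA,
the LF group's on the longest), 5 blocks × 80 trials, deterministic per-block
counts with randomized order, and an optional 17.5% Task-2 no-go rate
(assigned independently of SOA, exact per block).  No-go trials keep their
Task-1 processing and have undefined RT2.

Default stage parameters (chosen once for realism of simple two-choice
colour/identity discriminations; all configurable):

| parameter | Task 1 | Task 2 | between-subject sd |
|---|---|---|---|
| encode (ms) | 150 | 150 | 20 |
| motor (ms) | 100 | 100 | 15 |
| boundary a | 1.5 | 1.5 | 0.15 |
| drift v (evid/s) | 3.2 | 2.2 | 0.25 |
| share_1 | 0.7 | — | 0.05 |

These give single-task RT1 ≈ 500 ms with ~1% errors and RT2 ≈ 570 ms with
~4% errors, a PRP effect of ~120–150 ms at a 100-ms SOA, and Task-1
prioritization (share_1 = 0.7) during parallel overlap.  Subject-level
parameters are truncated-normal population draws; each subject gets an
independent RNG substream, so datasets are bit-reproducible from one seed.

What the generator does *not* emulate: response grouping (an optional
post-hoc IRI floor exists purely for stress tests), SOA-frequency-driven
time expectancy, practice/fatigue trends across blocks, fast guesses and
attention lapses, and stimulus-specific effects.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
stated generative assumptions, not validity of the diffusion model for any
particular empirical dataset.

## Preprocessing

The exclusion cascade applies, in order: (1) response errors — for RT
analyses a trial dies if *either* task was answered incorrectly; for fitting
task k only other-task errors are dropped, because accuracy coding needs
task-k error trials; (2) an RT window of [200, 2000] ms on either task's RT;
(3) optionally no-go trials; (4) optionally trials with inter-response
interval IRI = (soa + rt2) − rt1 below a floor.  Error rates are aggregated
on the pre-RT-window set so fast errors still count.  Reports reconcile
exactly and the cascade is idempotent.

A note on the IRI floor: because first-passage-time distributions are
right-skewed, a serial-mode generator necessarily produces a non-trivial
share of IRIs below 100 ms at short SOAs.  Excluding them leaves the PRP
ordering and effect size intact (the regression test asserts exactly that)
but can move small rare-SOA cells by tens of ms — robustness here means the
qualitative conclusions survive, not that cell means are frozen.

## RT-level inference

The conventional layer is a 2 (condition, between) × 3 (SOA, within) mixed
ANOVA per task and dependent variable (mean RT, error rate), computed via
pingouin and re-verified in tests against hand-computed balanced sums of
squares and an exact label-permutation oracle.  Mauchly's test gates a
Greenhouse–Geisser correction; ε (lower bound 0.5 at three levels) shrinks
both numerator and denominator dfs of the two within-factor effects, which
share the within-subject error covariance.  Partial η² is reported per
effect.  Between-condition contrasts use Welch's t (fractional df), within-
subject contrasts paired t, with Bonferroni adjustment per parameter family.
Error-rate ANOVAs use raw proportions.

## Hierarchical Bayesian estimation

One model per task, both conditions jointly.  Structure: v and t0 vary by
condition × SOA class (short vs long; medium-SOA trials are excluded before
fitting), a is subject-level only with a single population distribution, and
subject parameters are normal population draws whose means and spreads are
the group nodes.  Priors are weakly informative: group means
N(1.5, 1²) for a, N(2, 3²) for v, N(0.4 s, 0.5²) for t0; group variances
inverse-gamma(2, β) with β matched to plausible spreads (0.09, 0.25, 0.01)
— the inverse-gamma choice buys a conjugate Gibbs step for the spreads.

Sampling is Metropolis-within-Gibbs: conjugate normal/inverse-gamma updates
for the group nodes and scalar random-walk Metropolis for subject-level
nodes, with proposal scales adapted toward 44% acceptance during burn-in
only.  Because a, v and t0 are posterior-correlated within a subject, each
retained draw runs `subject_sweeps = 2` full subject-level sweeps, which
keeps rank-normalized split R-hat (computed via arviz) at ~1.02–1.04 where a
single sweep leaves it hovering at the 1.05 threshold.  At least two chains
are required so R-hat is meaningful; defaults are 6000 draws with 1000
burn-in (5000 retained per chain — the "full" pipeline profile), with
smaller documented profiles for smoke ("tiny") and recovery-scale
("scaled") runs.  The constraint
t0 < min(rt) holds automatically through the likelihood (density is zero for
rt ≤ t0), which also handles all-correct cells — the error boundary is
simply unobserved.  Non-convergence is reported in the diagnostics object,
never raised, and propagates into pipeline reports.

### Recovery behaviour and its limits

On the Exp-1 geometry with 20 subjects per condition, the rare-SOA cells
contain only 40 trials per subject.  The group-mean drift estimate then
carries irreducible noise of roughly 0.09–0.11 evidence/s per rare cell
(between-subject spread ⊕ per-subject estimation noise), so recovery of v to
±0.15 is a ~1.4σ statement per rare cell: correct machinery will
occasionally land outside that band on unlucky seeds, while t0 recovers to
within ~12 ms against a ±25 ms band with room to spare.  The acceptance
script reports the realized maximum cell errors for its seed rather than
hiding this variability.

## Posterior decision layer

Within one joint model, parameters are compared by the posterior proportion
P — the fraction of (iteration-paired) draws in which one node exceeds the
other — with P > 0.950 declared substantial.  Pairing is the default
because nodes of one posterior are correlated through the shared data; a
pooled all-pairs variant exists for sensitivity analyses.  Ties (possible in
finite-precision persisted draws) count against the strict inequality, so
P(a>b) + P(b>a) + P(tie) = 1 exactly.  Interactions use the
difference-of-differences construction: (short − long) per condition,
compared across conditions in the same paired fashion.  Across tasks —
separate models, so no joint draws — posteriors are collapsed to
per-participant means and compared with paired t tests; across conditions,
Welch tests.

## Pipeline and reproducibility

`run_pipeline` chains generate → preprocess → RT stats → fit → compare →
report, persisting every artifact as delimited or structured text with
SHA-256 hashes in a JSON manifest; a rerun with the same config is
byte-identical for the deterministic stages.  Every stochastic component
(schedules, walks, subject sampling, chains) derives from a single seed via
independent substreams.  The CLI (`prpddm generate|preprocess|rtstats|fit|
compare|report|all|loglik`) is a thin layer over the library.

Problem sizes used by the shipped tests and the acceptance script — chosen
as the package's own scaled-down study conditions — are: 20 subjects per
condition at full Exp-1 geometry with 2 chains × 2000 retained draws for
recovery and signature fits; 1e5 draws for the walker/density goodness of
fit; and 500 replicate mini-experiments (5 subjects/condition, one 40-trial
block) for ANOVA type-I calibration.

## Known limitations

* The parallel generator shares capacity only between the two *decision*
  stages; encoding and motor stages never compete.
* The sampler is single-site Metropolis within Gibbs — robust but not fast
  for much larger designs; no NUTS/slice machinery.
* Model comparison (DIC/WAIC/LOO), stimulus-coded fitting, and inter-trial
  variability parameters are out of scope.
* The posterior-predictive layer is limited to basic report overlays;
  quantile-probability plots are not implemented.
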
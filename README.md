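# prpddm

Serial vs. parallel dual-task processing, simulated and estimated with a
drift–diffusion model.

`prpddm` is a research pipeline for the **psychological refractory period
(PRP)** paradigm: two choice tasks separated by a stimulus-onset asynchrony
(SOA), where responses to the second task slow dramatically as the SOA
shrinks.  The package is built for researchers who want to test whether that
slowing reflects a **serial response-selection bottleneck** (Task-2 decision
waits for Task 1; the waiting "slack" loads onto Task-2 non-decision time
t0) or **central capacity sharing** (both decisions run in parallel at
reduced speed; the Task-2 drift rate v drops at short SOAs) — and to verify,
on fully synthetic data with known ground truth, that a hierarchical
Bayesian diffusion-model analysis can actually tell the two apart.

It provides:

* **Generators** for trial-level PRP experiments under explicit serial or
  capacity-sharing mechanisms: between-subjects SOA-frequency conditions
  (SF: 80% short / 10% medium / 10% long SOAs; LF mirrored), SOA sets
  {100, 300, 800} or {300, 500, 1000} ms, 5 × 80-trial blocks with exact
  per-block composition, optional 17.5% Task-2 no-go trials, Euler–Maruyama
  diffusion walks (0.1-ms steps, Brownian-bridge crossing correction).
* **Preprocessing**: the error / RT-window (200–2000 ms) / no-go /
  inter-response-interval exclusion cascade with exact bookkeeping, and per
  subject × SOA cell aggregation.
* **RT statistics**: 2 (condition) × 3 (SOA) mixed ANOVA with Mauchly's
  test, Greenhouse–Geisser correction and partial η²; Welch and paired t
  tests with Bonferroni adjustment.
* **Diffusion mathematics**: exact Wiener first-passage densities
  (small-/large-time series, relative error ≤ 1e-7) and accuracy-coded
  log-likelihoods, with closed-form oracles for the unbiased start
  (P(upper) = 1/(1+e^{-av}), E[T] = (a/2v)·tanh(av/2)).
* **Hierarchical Bayesian estimation**: per task, v and t0 vary by
  condition × SOA (short vs long), boundary a per subject, z = a/2, s = 1;
  Metropolis-within-Gibbs sampling, ≥ 2 chains, rank-normalized split R̂.
* **Posterior decisions**: the posterior-proportion criterion (substantial
  if P > 0.950), difference-of-differences interaction tests, and
  per-participant posterior means feeding frequentist cross-task contrasts.

See `docs/methods.md` for the models, priors, numerics and limitations.

## Worked example

Simulate a full study in which the SF group shares capacity (parallel) and
the LF group processes serially, then run the entire analysis chain:

```bash
prpddm all --experiment exp1 --profile scaled --seed 7 --outdir run_scaled
```

The run directory contains the trial table, ground-truth sidecar, exclusion
report, cell means, ANOVA tables, posterior draws with diagnostics, the
comparison table, and `report.txt`, which for this seed prints:

```
Mean RT (ms) by task, condition and SOA:
soa_ms          100.0  300.0  800.0
task condition
1    LF         481.0  486.6  479.6
     SF         505.0  481.1  479.3
2    LF         719.1  605.9  579.5
     SF         624.9  588.0  574.0
```

RT2 rises steeply at the 100-ms SOA (the PRP effect) and does so less in the
SF group — the capacity-sharing group is 94 ms faster than the serial group
at short SOAs while paying with a slower RT1, exactly the trade-off the two
mechanisms predict.  The ANOVA quantifies it:

```
ANOVA, task 2, dv=mean_rt
  condition: F(1, 38) = 4.61, p = 0.038, eta_p^2 = 0.11
  soa: F(2, 76) = 68.29, p = 0.000, eta_p^2 = 0.64, eps = 0.944
  condition x soa: F(2, 76) = 15.61, p = 0.000, eta_p^2 = 0.29, eps = 0.944
```

and the diffusion-model layer separates the mechanisms that produced it
(P is the posterior proportion; * marks P > 0.950):

```
Task 1 fit: converged (max R-hat 1.034)
Task 2 fit: converged (max R-hat 1.013)

Posterior comparisons (P > 0.950 marked *):
  task 2 v[SF] short vs long (less): P = 1.000 *
  task 2 t0[LF] short vs long (greater): P = 0.995 *
  task 2 t0[SF] short vs long (greater): P = 0.800
  task 2 t0[SF-LF] diff of diffs (less): P = 0.937
```

The parallel (SF) group shows the drift-rate signature — v(short) < v(long)
with P = 1.000 — while the serial (LF) group shows the non-decision-time
signature — t0(short) > t0(long) with P = 0.995 — recovering from raw
simulated RTs the mechanisms that generated them.

The same machinery is available as a library:

```python
from prpddm import (preset, default_population, simulate_experiment,
                    exclude_trials, ModelSpec, fit_hierarchical, bayesian_p)

configs = {c: preset("exp1", c, n_subjects_per_condition=20) for c in ("SF", "LF")}
pops = {"SF": default_population("parallel"), "LF": default_population("serial")}
trials, truth = simulate_experiment(configs, pops, seed=7)

fit_trials, _ = exclude_trials(trials, drop_nogo=True, error_policy="task2")
post, diag = fit_hierarchical(fit_trials, ModelSpec(task=2, n_samples=3000,
                                                    burn_in=1000, seed=1))
res = bayesian_p(post.group_node("t0", "LF", "short"),
                 post.group_node("t0", "LF", "long"), "greater")
print(res.report())   # P(... greater) = 0.995 [substantial]
```

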
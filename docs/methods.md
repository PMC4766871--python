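# Methods

## The beads-task decision model

A trial presents beads drawn i.i.d. from one of two jars with complementary
colour ratios; the majority proportion `q` (default 0.80) and the 20-bead
cap `d_max` are task constants. The model is an ideal Bayesian observer
with two subject-level departures from optimality:

- **Cost of sampling `Cs ≥ 0`** — a utility penalty per bead viewed,
  expressed in units of the declaration reward (correct declaration = 1,
  incorrect = 0). On this scale a `Cs` of 0.02 means "one bead costs 2% of
  the prize".
- **Cognitive noise `T > 0`** — a softmax temperature applied to the action
  values. It plays two roles at once: it randomises choice (consistency),
  and because the value propagated backwards through the lattice is the
  *policy-weighted* expected action value, a large `T` dilutes the value of
  outcomes that are many decisions away. High-noise agents therefore stop
  early, not because sampling is costly but because the benefit of distant
  evidence is attenuated.

Backward induction runs from the forced declaration at `d_max` to the empty
state. At each belief state `(n_a, n_b)`:

- `Q(declare J) = P(J | state)`,
- `Q(sample) = −Cs + E[V(successor)]` under the posterior-predictive bead
  probability (absent at the cap),
- `π = softmax(Q / T)` over the available actions,
- `V = Σ_a π(a) Q(a)`.

An alternative propagation rule `V = T · logsumexp(Q / T)` is implemented
behind `BeadsConfig.value_rule="logsumexp"`; the two coincide as `T → 0`
and differ in how strongly noise discounts the future. The policy-weighted
rule is the default because it makes the noise parameter's "attenuated
look-ahead" interpretation literal; the switch exists because the
propagation rule is a genuinely open modelling choice and the default was
chosen on interpretability, not fit.

**Deterministic limit.** `T = 0` is accepted and solved exactly (argmax
policy, max-propagated values). Exact value ties — which arise structurally,
e.g. sampling vs declaring at zero cost when one more bead cannot change
the decision — are detected with an absolute tolerance of 1e-9 (the tie is
exact in real arithmetic but not in floating point) and resolved by
`tie_break`: `prefer_sample` (default, matches ideal-observer behaviour at
zero cost) or `prefer_declare`. A residual declare–declare tie (symmetric
evidence) splits evenly.

**Likelihood.** A trial record (bead sequence, draws-to-decision `d`,
declared jar) implies the action "sample" at decision points `1..d−1` and a
declaration at `d`; the first decision point follows the first bead, so
`draws ≥ 1` and declaring before any bead is disallowed. The trial log
likelihood is the sum of log policy probabilities of those actions along
the belief states visited. All log probabilities are natural-log and all
posterior arithmetic is done in log space (at `d_max = 20` and `q = 0.8`
raw likelihood products underflow).

The backward induction is vectorised across parameter settings (one solve
for a whole grid), which is what makes the hierarchical fit cheap: the
per-grid-point trial likelihoods are independent of the hyperparameters and
are computed exactly once per fit.

## Hierarchical empirical-Bayes fit

Subject parameters are assumed drawn from population gamma distributions,
`Cs ~ Gamma(a_c, b_c)` and `T ~ Gamma(a_t, b_t)` (shape/rate). Fitting is
EM:

- **E-step.** Each subject's posterior over `(Cs, T)` is evaluated on a
  fixed log-spaced grid (default 40 × 40 over `Cs ∈ [1e-4, 0.5]`,
  `T ∈ [0.01, 5]`). Posterior masses are `exp(log prior + log likelihood +
  log Δ)` normalised, where `log Δ` is the trapezoid cell measure: without
  it, a log-spaced grid silently imposes a `1/x` weighting and grid
  expectations stop approximating posterior moments. The MAP estimate is
  the argmax of the density log-joint (no measure term), ties broken toward
  the smallest `Cs`, then the smallest `T`.
- **M-step.** For each parameter the posterior-weighted first moment and
  mean log, averaged over subjects, are the gamma sufficient statistics;
  the shape solves `log a − ψ(a) = log m̄ − mean-log` by bracketed Brent
  root finding (ψ = digamma), with moment matching as fallback. When the
  statistics degenerate (all posterior mass effectively at one point) the
  shape is capped at 1e6, i.e. a near-point-mass population.
- **Convergence.** Relative change of all four hyperparameters < 1e-3, at
  most 200 iterations; non-convergence is flagged on the result, not
  raised. The log marginal likelihood of the hyperparameters is recorded
  per iteration and is non-decreasing (EM ascent), which the tests assert
  to 1e-6.

**Weak identification of `Cs`.** With few trials and small true costs the
likelihood is nearly flat in `Cs`; the population `Cs` distribution then
collapses toward a spike near its initialisation mean, and EM creeps toward
that degenerate fixed point slowly (this is the usual reason for the
non-convergence flag at 200 iterations; with 20 trials per subject the fit
converges). The fitted `Cs` level should be read as "negligible relative to
the noise parameter", not as a measured quantity — which is also the
substantive conclusion the model supports.

**Fit metric.** Per subject, the summed trial log likelihood at the MAP
point divided by the number of decision points ("log probability per
action", nats). The denominator counts every sample/declare choice, i.e.
total draws across trials; reading "per draw" as "per action" is a
documented interpretation choice.

**Exclusion rule.** Subjects whose draws equal `d_max` on *every* trial are
consistent with a simple "always sample to the end" heuristic rather than
horizon-aware valuation; the pipeline always reports both the all-subjects
fit and the fit excluding them.

## IST scoring

- **P(correct):** with `m` opened cells of the chosen colour and `u`
  unopened cells, each unopened cell is an independent fair coin and
  `P = Σ_{j: m+j ≥ 13} C(u, j) / 2^u`, evaluated in exact rational
  arithmetic. This is exact for the near-50:50 board-generation model and
  is an approximation for boards with strong known majorities.
- **Points:** fixed-win +100 for a correct choice regardless of boxes;
  decreasing-win `max(250 − 10·boxes, 0)`. The instrument prints only the
  win schedule, so the error penalty (default −100) and the floor (default
  0) are configuration.
- **Errors:** an incorrect choice that *follows* the opened-box majority is
  a sampling error (evidence insufficient); one that goes against it is a
  discrimination error (evidence misread); opened-box ties count as
  sampling errors. The pipeline reports the sampling-error rate.

## Discount rate (27-item questionnaire)

Candidate `k` values are the item indifference points
`(delayed/immediate − 1)/delay`. The assigned `k` maximises agreement
between the implied deterministic pattern (immediate iff `k > k_indiff`,
hyperbolic value `A/(1+kD)`) and the observed responses; ties take the
geometric mean of the maximising candidates (a single winner is returned
exactly, avoiding a log/exp round trip); consistency is the maximal
agreement proportion. The 27 item amounts/delays ship as an editable CSV —
they are data, not code.

## Group statistics

Square-root transform for beads draws and IST boxes, log10 for `k`
(non-positive `k` is an error naming the subject); one-pass per-group
outlier screening at mean ± 3 sample SD (zero-SD groups remove nothing;
originals are kept alongside); pooled-variance two-sample t-tests (Welch by
flag); 2×2 mixed ANOVA (between: group, within: reward condition) via
`pingouin.mixed_anova`, cross-checked in the tests against an independent
sums-of-squares decomposition; Wilcoxon rank-sum via `mannwhitneyu`
(exact method for small samples) for the fitted noise parameter; Pearson
correlation of beads draws against the severity covariate.

## Synthetic cohorts

The generator emulates a two-group design of 30 + 30 subjects with three
beads trials each, ten IST trials per reward condition and the 27-item
questionnaire:

- `(Cs, T)` per subject from group gamma hyperpriors. Defaults: both groups
  `Cs ~ Gamma(mean 0.02, SD 0.01)`; healthy volunteers
  `T ~ Gamma(mean 0.25, SD 0.12)`; binge drinkers
  `T ~ Gamma(mean 0.6, SD 0.35)` — a higher-mean, higher-variance noise
  distribution, which forward-simulates into fewer draws-to-decision.
- IST agents open boxes in random order until the opened-colour margin
  reaches a subject threshold (normal, mean 5, SD 2, clipped to [1, 12]),
  lowered by 2 under the decreasing-win schedule, then choose the opened
  majority. Both groups share the same defaults (the emulated design found
  no IST group differences). Boards have a majority count uniform on 13–17.
- Questionnaire agents discount hyperbolically with
  `log k ~ Normal(log 0.01, 1)` in both groups and logistic choice noise
  (τ = 2 currency units).
- An AUDIT-like severity covariate is drawn per group (HV ≈ 4 ± 2.8,
  BD ≈ 15.5 ± 5.5, clipped at 0) with correlation 0.3 to the subject's
  noise parameter through a Gaussian copula.

**What the generator does not emulate:** the original fixed bead orders
(unpublished — sequences are drawn i.i.d. per trial, or can be supplied via
file), sequence-position effects, confidence ratings (stored as a data
field, never modelled), learning or fatigue across blocks, and
questionnaire-item response biases. Passing recovery tests on this
generator shows the estimator inverts its own generative model at realistic
sizes; it cannot certify fit quality on real participants.

Three trials per subject (the emulated protocol) identify group contrasts
but not individual parameters; recovery studies therefore use ≥ 20 trials
per subject, and the subject-level MAP recovery test evaluates hits at the
resolution of a 15 × 15 grid, which is what the weakly identified `Cs`
supports.

## Problem sizes and numerical choices

- Acceptance-scale simulations: 52 subjects × 20 trials (parameter
  recovery), 24 vs 28 subjects × 20 trials (group contrast), 20 seeded
  replicates each; the vectorised fit takes well under a second per cohort.
- Exhaustive oracles: horizons ≤ 6 for the valuation recursion, 4 for path
  enumeration, `u ≤ 12` unopened cells for IST enumeration.
- Ties, tolerances: value-tie tolerance 1e-9 (deterministic mode only); EM
  ascent tolerance 1e-6; DP-vs-oracle agreement 1e-10; MAP tie-break
  smallest-`Cs`-then-`T`.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; simulation under common random numbers uses a
  fixed cumulative action ordering so stopping times are coupled across
  parameter settings.

## Known limitations

- The E-step grid bounds clip extreme subjects (`T > 5` or `Cs > 0.5` land
  on the boundary); widen `GridSpec` for populations outside the default
  support.
- The gamma population model cannot represent bimodal cohorts (e.g. a
  subgroup of cap-samplers); the exclusion rule is a blunt instrument for
  that case.
- P(correct) assumes fair-coin unopened boxes regardless of the true board
  composition.
- The mixed ANOVA is the classical univariate F (no sphericity issue in a
  2-level within factor, but no robust/permutation variant is provided).
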
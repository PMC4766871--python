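# reflectim

Modelling and scoring of **reflection impulsivity** — how much evidence a
person gathers before committing to a decision — for two-group behavioural
studies (e.g. healthy volunteers vs binge drinkers). The package implements:

- a **Bayesian ideal-observer model of the beads task** with two free
  parameters per subject: a subjective cost of sampling `Cs` and a
  "cognitive noise" (softmax temperature) `T`, both in units of the
  declaration reward;
- **hierarchical empirical-Bayes fitting** of `(Cs, T)` across a cohort by
  expectation maximisation under population gamma distributions;
- deterministic scoring of the **Information Sampling Task** (boxes opened,
  exact P(correct), points, sampling vs discrimination errors) and the
  **27-item Monetary Choice Questionnaire** (hyperbolic discount rate `k`);
- the **behavioural statistics battery** (3-SD outlier screening, sqrt /
  log10 transforms, pooled t-tests, 2×2 mixed ANOVA, exact Wilcoxon
  rank-sum, Pearson correlations);
- a **synthetic cohort generator** with known ground truth, so the whole
  pipeline is testable without any participant data.

## The model

Beads are drawn from one of two jars with complementary colour ratios
(majority proportion `q = 0.8`). After each bead the subject may draw
another (up to `d_max = 20`) or declare a jar. The belief state is the
colour count pair `(n_a, n_b)`; by Bayes' rule

```
P(A | n_a, n_b) = q^{n_a} (1-q)^{n_b} / [ q^{n_a}(1-q)^{n_b} + (1-q)^{n_a} q^{n_b} ]
```

Action values come from backward induction over the belief lattice:
declaring jar `J` is worth `P(J | state)` (unit reward, 0 for errors);
sampling is worth `−Cs` plus the predictive-expected value of the successor
state. Choice is a softmax with temperature `T`, and the value propagated
backwards is the *policy-weighted* action value, so large `T` both
randomises choice and attenuates the influence of distant future outcomes —
noisy subjects decide early. `T → 0` recovers the deterministic ideal
observer, whose decision boundaries relax as the horizon approaches.

Per-subject parameters are estimated on a log-spaced `(Cs, T)` grid under
gamma population priors; EM alternates subject posteriors with gamma
maximum-likelihood hyperparameter updates. Subjects who sample to the cap
on every trial are conservatively excluded in a second fit pass.

## Worked example

```
python analysis/01_synthesize_cohort.py --seed 1
python analysis/02_fit_beads_model.py
python analysis/03_score_tasks.py
python analysis/04_group_statistics.py
```

prints (seed 1):

```
  HV: n=30, median true noise t=0.235, median cost cs=0.0172, mean beads drawn=1.88
  BD: n=30, median true noise t=0.475, median cost cs=0.0188, mean beads drawn=1.60
[excl20] population: cs mean 0.0500, t mean 0.491; median MAP t per group: BD=0.337, HV=0.163; ...
-> t_beads_draws: statistic=1.264, p=0.2113 (not significant at 0.05)
-> wilcoxon_map_t: statistic=239.000, p=0.0017 (significant at 0.05)
```

The generated binge-drinking group has noisier decision making (higher
ground-truth `T`), so it draws fewer beads; the hierarchical fit recovers
the group contrast in the *fitted* noise parameter (Wilcoxon p ≈ 0.002)
even when the raw draws-to-decision difference is not significant at this
cohort's three trials per subject. The IST ANOVAs show the expected strong
effect of the cost condition on P(correct) and sampling errors and no group
effect, and the discount-rate comparison is null — both by construction of
the generator.

The same pipeline runs on real data from CSV tables (see the schemas in the
module docstrings) via the CLI:

```
reflectim run-all --config run.yaml
reflectim synthesize | validate | fit | score | stats   # stage-wise
```

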
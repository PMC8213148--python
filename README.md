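# delaydisc

Hierarchical Bayesian and model-free analysis of two-group intertemporal
choice (delay discounting) data, with synthetic cohort generators for a
seconds-scale experiential task and a days-scale hypothetical task.

Delay discounting experiments ask people to choose between a smaller-sooner
reward (SS) and a larger-later one (LL, delivered after delay D). The rate
at which the delayed reward loses subjective value — the discount rate
k — is a widely used behavioral marker of choice impulsivity, and clinical
studies routinely compare it between a patient group and matched controls.
`delaydisc` implements the full analysis chain for such two-group studies:

- **Choice models** — hyperbolic SV = LL/(1 + kD) and exponential
  SV = LL·e^(−kD) discounting, a softmax choice rule
  P(LL) = 1/(1 + e^(−β(SV_LL − SV_SS))) with inverse temperature β, and the
  Bernoulli trial likelihood.
- **Hierarchical Bayesian inference** — subject-level (log k, β_raw)
  partially pooled under group-level normal hyperparameters, sampled by an
  adaptive Metropolis-within-Gibbs MCMC (2 chains by default), with the
  classic Gelman-Rubin R̂ (< 1.01 acceptable), highest-density intervals,
  and DIC model comparison (lower = better).
- **Group contrasts** — posterior difference distributions of group-level
  means, paired by iteration; directional Bayes factors (dBF) as the
  KDE-integrated ratio of posterior mass above vs below zero; dominance
  probabilities; conventional evidence bands (1–3 anecdotal, >3 moderate,
  >10 strong, >30 very strong, >100 extreme, reciprocals for the opposite
  direction).
- **Model-free track** — proportion of LL choices with arcsine-square-root
  transform and Welch's t (grid designs); per-delay indifference points and
  the trapezoid area under the normalized discounting curve, AUC ∈ [0, 1]
  (titration designs); Pearson chi-square for 2×2 demographic tables.
- **Synthetic cohorts** — both task designs (a 50-trial cents/seconds grid;
  a 140-trial euros/days set built around a simulated adaptive pretest) with
  known ground-truth parameters, so estimation, model selection and
  calibration are testable end to end without any external data.

See `docs/methods.md` for the model, priors, sampler, estimators and the
generator's operating points.

## Worked example

Simulate a two-group cohort on the seconds-scale grid (19 subjects per
group; the generator shifts the patient group's mean log k by −1.0, i.e.
patients discount less) and run the full report:

```bash
delaydisc simulate --preset study1_adolescent --n 19 --seed 7 --out-dir demo
delaydisc report --data demo/dataset.csv --seed 7 \
    --iters 12000 --burnin 4000 --out-dir demo
```

Output (abridged):

```
Model comparison (DIC; lower = better fit)
family        DIC        pD     max R-hat  converged
hyperbolic     1091.54    59.95     1.0070  True
exponential    1139.37    57.65     1.0048  True
preferred family: hyperbolic

Group contrast mu_log_k: patients - controls
  dBF (positive) = 0.024
  evidence: very strong (opposite direction)
  dominance P(diff > 0) = 0.022
  85% HDI [-0.978, -0.160]
  95% HDI [-1.173, -0.019]

Model-free summary (group means)
          proportion_ll  arcsin_prop_ll
group
controls       0.631579        0.928067
patients       0.727368        1.031300
Welch t on arcsin_prop_ll: t=1.9083, df=33.91, p=0.0648
```

Reading this: the data were generated hyperbolically and DIC prefers the
hyperbolic family by ~48 points. The dBF of 0.024 on the (patients −
controls) contrast means a *decrease* in the patients' group-level mean
log k is 1/0.024 ≈ 41 times more likely than an increase — very strong
evidence in the generated direction; only 2.2% of the paired posterior
difference mass lies above zero. The model-free track agrees: patients
chose the delayed option more often (72.7% vs 63.2%).

The same pipeline is available as library calls (`simulate_cohort`,
`fit_hierarchical`, `compare_groups`, `subject_summary`, ...), and
`delaydisc fit / compare / modelfree` run the stages separately on any
choice-data CSV (format documented in `delaydisc/io.py`).

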
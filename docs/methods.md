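# Methods

## The model

Each trial offers a smaller-sooner amount SS (delivered now) against a
larger-later amount LL delivered after delay D. The delayed amount is
devalued by a subject-specific discount rate k under one of two families:

- hyperbolic: SV = LL / (1 + k·D)
- exponential: SV = LL · exp(−k·D)

A softmax (logistic) rule with inverse temperature β maps the value
difference to the probability of choosing the delayed option:

    P(LL) = 1 / (1 + exp(−β · (SV_LL − SV_SS)))

β = 0 makes choice random; large β approaches deterministic value
maximization. Observed choices are conditionally independent Bernoulli
draws given (k, β).

Both parameters are estimated on the real line — log k directly, and β
through an exponential link β = exp(β_raw). The link keeps β positive and
mirrors the log-space treatment of k; a softplus link would differ only for
β near zero, where the likelihood barely distinguishes the two.

### Hierarchy

Subject parameters are partially pooled through group-level normals:

    log k_s ~ N(μ_logk[g(s)], σ_logk[g(s)]),  β_raw_s ~ N(μ_β[g(s)], σ_β[g(s)])

with weakly informative hyperpriors chosen to span both delay units
(seconds and days):

| hyperparameter | prior | rationale |
|---|---|---|
| μ_logk | N(ln 0.01, 5) | ±5 log units covers k from ~1e−6 to ~1e2 per unit time |
| σ_logk | Half-N(2) | permits 2 orders of magnitude of subject heterogeneity |
| μ_β_raw | N(0, 2) | β between ~0.02 and ~50 at ±2 SD |
| σ_β_raw | Half-N(2) | as above |

`grouping="by_group"` indexes the hyperparameters by group so that group
contrasts are paired differences within a single joint posterior;
`grouping="pooled"` shares one set across all subjects (the "full model"
of the DIC comparison table).

### Sampler

Adaptive random-walk Metropolis-within-Gibbs:

- each subject's (log k, β_raw) pair is proposed jointly from an isotropic
  Gaussian with a per-subject step size; since subject likelihoods are
  conditionally independent given the hyperparameters, all subject blocks
  are accepted/rejected independently in one vectorized pass;
- group means use exact normal-normal Gibbs draws;
- group SDs use a random-walk on log σ (half-normal prior plus the log
  Jacobian).

Step sizes follow a Robbins-Monro recursion `log s ← log s + t^(−0.6)·
(accept − 0.35)` during burn-in and are frozen afterwards, so the retained
draws come from a fixed, detailed-balance-preserving kernel. Defaults are
2 chains × 20,000 iterations with 10,000 burn-in (chain c seeded with
`base_seed + c`); the test suite and acceptance script use 2 × 2,500–6,000
iterations, which these small cohorts mix well within (typical max R̂
1.005–1.03; unconverged fits are flagged, never silently accepted). The
single-subject grid-quadrature comparison uses 2 × 60,000 iterations
because its tolerance (2% of a posterior SD) is Monte-Carlo-error bound.

Convergence is the classic Gelman-Rubin potential scale reduction factor
√(((n−1)/n·W + B/n)/W), with R̂ < 1.01 on every parameter required to mark
a fit converged. When every chain is constant, R̂ is 1 by convention.
Highest-density intervals use the sorted-window method (shortest interval
containing the requested mass), valid for the unimodal marginals this
model produces.

### Model comparison

DIC = D̄ + pD with pD = D̄ − D(θ̄), where the deviance D = −2·log L is
focused on the subject-level parameters (θ̄ their posterior means in
sampling space). Lower is better; negative pD is reported with a warning
(a known DIC pathology under posterior asymmetry).

### Group contrasts

The contrast parameter is a group-level mean hyperparameter (μ_logk, or
μ_β_raw). Differences are computed on draws paired by iteration from one
joint posterior. The directional Bayes factor is the ratio of posterior
mass of the difference above zero to the mass below zero, obtained by
fitting a Gaussian KDE (Silverman bandwidth) and integrating by trapezoid
on a 4,096-point grid extended 6 bandwidths past the sample range, with an
exact grid node at zero. When the denominator holds < 1e−4 of the mass the
ratio is capped at 1e4 and flagged. Evidence bands: 1–3 anecdotal, >3
moderate, >10 strong, >30 very strong, >100 extreme; values below 1 read
as their reciprocal in favor of the opposite direction. The dominance
probability P(diff > 0) is the raw draw fraction (zeros count half) and
should approximately satisfy dbf ≈ dominance/(1 − dominance) away from the
tails — a built-in consistency check.

## Model-free track

Seconds-scale grid data are summarized per subject by the proportion of
larger-later choices, arcsine-square-root transformed before a Welch
unequal-variance t test (with only four distinct SS amounts, indifference
points would be poorly resolved on this design). Days-scale titration data
get per-delay indifference points: a rising logistic of choice on LL
amount is profiled over a 61-point grid of crossing points with the slope
maximized at each, and the indifference point is the amount at P = 0.5,
clipped to the observed amount range; complete separation falls back to
the midpoint between the highest always-SS and lowest always-LL amount.
Points are normalized (x = D/180, y = SS/indifference amount, anchor
(0, 1)) and summarized by the trapezoid area under the curve; AUC ∈ [0, 1]
with smaller values meaning steeper discounting. 2×2 demographic tables
use Pearson's chi-square without continuity correction.

## Synthetic cohorts

The generator is the package's test bed: it emulates the two task designs
and draws choices from the same softmax model the fits assume.

- Seconds-scale grid: SS ∈ {0,…,4} cents now vs 5 cents after
  {10,20,30,40,60} s; each of the 25 combinations twice; 50 trials;
  maximum payout 250 cents.
- Days-scale titration: 20 € now vs LL ∈ [20.5, 80] € after
  {1,2,7,14,30,90,180} days; per delay, 10 uniformly spaced amounts plus
  10 at ±5/10/15/20/25% of the hyperbolic indifference point
  20·(1 + k·D) implied by that subject's simulated pretest (uniform again
  where the indifference point exceeds 80 €); 140 trials.
- Pretest: per delay, a 5-step bisection on LL amount brackets the choice
  reversal; delays where even 80 € is refused are censored out, delays
  where 20.5 € is accepted contribute an indifference point at 20 €
  (no measurable discounting); k is the least-squares slope of the
  indifference points through 20·(1 + k·D), clipped to [1e−4, 3] per day.
- Trial order is pseudorandomly permuted per subject under the cohort
  seed; the likelihood is order-invariant.

Default operating points (the presets `study1_adolescent` and
`study2_adult`): 19 and 25 subjects per group, matching the two cohort
sizes. For the seconds task μ_logk = ln 0.03 (k·D near 1 in the middle of
the grid, i.e. maximally informative trials), σ_logk = 1, μ_β_raw = 1
(β ≈ 2.7 per cent of value difference); the patient group's μ_logk is
shifted −1.0 (reduced discounting), the direction and a magnitude the
seconds-scale design can resolve. For the days task μ_logk = ln 0.01 per
day (a typical adult discount rate on this delay range), β ≈ 0.2 per euro,
and no group shift (the adult comparison is null). These are simulation
operating points, not estimates of any real cohort.

What the generator does not emulate: waiting-time opportunity costs and
feedback effects of the experiential task, magnitude effects across the
cents/euros scales, response times, and any model misspecification —
subjects truly are softmax discounters here. Passing recovery tests
therefore demonstrates correctness of the inference machinery, not that
real adolescents or adults obey these models.

## Numerical choices

- Softmax computed as a logistic of β·(SV_LL − SV_SS); per-trial log
  probabilities floored at log(1e−12).
- Bisection/indifference estimators clip to their amount ranges; the
  pretest k to [1e−4, 3] per day.
- Degenerate Welch input (both groups constant and equal) returns t = 0,
  p = 1 by convention.
- All randomness flows from explicit integer seeds (numpy Generator /
  SeedSequence); cohort generation is a pure function of its spec.

## Problem sizes

Simulation-based checks use 10 seeded replicates of 15-per-group cohorts
(both designs) for recovery coverage, DIC direction, and Bayes-factor
calibration — large enough that the ≥8/10 decision rules sit far from
their binomial noise floor under the default operating points, and small
enough to run routinely.

## Known limitations

- The random-walk sampler mixes slowly for very weakly informative
  subjects (near-flat likelihoods on saturated designs); R̂ flags this.
- DIC with conditional focus penalizes less than WAIC/LOO would;
  comparisons are within-dataset only.
- The KDE Bayes factor is undefined for one-sided posteriors — hence the
  1e4 cap and flag.
- k is never converted between delay units; cross-design comparisons of k
  are intentionally unsupported.
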
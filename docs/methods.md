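# Methods

## The scientific problem

Parents and adolescents routinely disagree when rating the severity of
conflict in their relationship. When the thing being rated is a shared
context — as parent–adolescent conflict is — that disagreement is not
measurement noise but a signal of its own: the dyad lacks a shared
representation of the state of the relationship. `ldsirt` implements a
Bayesian pipeline for asking whether that *informant discrepancy*, rather
than the reported conflict level itself, predicts a clinician-rated
3-level hopelessness score in depressed adolescents.

## Model

### Measurement: 2PL IRT with a latent difference score

Each informant answers J binary conflict items. For a respondent with
latent trait t, item j is endorsed with probability

    P(y_j = 1 | t) = logistic(a_j (t − b_j)),    a_j > 0.

Four response sets exist per study (adolescent-about-mother, mother,
adolescent-about-father, father) and all share one set of item parameters
(a, b). This sharing *is* the measurement-invariance assumption: latent
difference scores are only interpretable if both informants' responses map
onto the same latent scale.

The latent difference score constraint ties the two informants of a dyad
together: the parent's latent trait is defined as θ + Δ, where θ is the
adolescent's trait and Δ the latent difference score. Per dyad,

    (θ, Δ) ~ N( (0, μ_Δ), [[1, ρ], [ρ, 1]] ),

with variances fixed at 1 and the θ mean fixed at 0 for identification;
μ_Δ (mean discrepancy) and ρ (trait–discrepancy correlation) are free,
estimated separately per parent role. Positive discriminations fix the
orientation (higher θ = more reported conflict), so the model has no
reflection symmetry; Δ = parent − adolescent, so negative Δ means the
parent reports *less* conflict than the adolescent.

An adolescent appearing in both a mother-dyad and a father-dyad gets an
independent (θ, Δ) pair per dyad; no cross-dyad correlation is modelled.
Missing single items simply drop out of the likelihood (MCAR at the item
level), so latent variables are estimated from the observed items.

### Outcome: ordinal probit regression

Hopelessness y ∈ {1, 2, 3} follows an ordered probit with linear predictor
η and cutpoints c1 < c2 (role-specific, as are the coefficients):

    P(y=1) = Φ(c1 − η),  P(y=2) = Φ(c2 − η) − Φ(c1 − η),  P(y=3) = 1 − Φ(c2 − η).

Four variants differ only in η: β·θ (adolescent report), β·(θ+Δ) (parent
report), β₁·θ + β₂·(θ+Δ) (multi-informant), β·Δ (informant discrepancy).

### Priors

The prior ledger (`PriorLedger`) is centralised and overridable:
a_j ~ LogNormal(0, 0.5); b_j ~ Normal(0, 2); β ~ Normal(0, 1); cutpoints
independent Normal(0, 2) restricted to the ordered region; μ_Δ ~
Normal(0, 1); ρ ~ Uniform(−1, 1). These are weakly informative on the
unit-variance latent scale: discriminations concentrate around 1 while
allowing a factor-of-~3 spread, difficulty and cutpoint scales comfortably
cover the range a probit/logit predictor of standardised inputs can
occupy, and the β prior keeps standardised coefficients in a plausible
range without meaningfully shrinking effects of magnitude ≤ 1.

## Inference

Sampling is dynamic Hamiltonian Monte Carlo (multinomial NUTS with
dual-averaging step-size adaptation, target acceptance 0.8, and windowed
diagonal mass-matrix estimation), implemented in numpy against the
model's analytic gradient. The unconstrained parameterisation uses log a,
(c1, log(c2−c1)), atanh ρ, with the corresponding Jacobians; latent θ, Δ
are sampled jointly with the parameters (no marginalisation). Divergence
threshold: Hamiltonian error > 1000; max tree depth 10. Chains run
sequentially with independent generators derived from one seed, so runs
are exactly reproducible. Defaults are 4 chains × 2,500 draws after 1,000
warmup iterations; results are gated on split rank-normalised R-hat < 1.01
for every parameter and zero divergent transitions (both computed per the
standard definitions; R-hat/ESS via arviz). The gradient implementation is
verified against finite differences, and the sampler against closed-form
conjugate posteriors, in the test suite.

Numerical details worth knowing: middle-category probit mass is evaluated
on whichever normal tail keeps the subtraction well conditioned and
floored at 1e-300 before logging; tanh(z_ρ) is clipped to ±(1 − 1e-10) so
1 − ρ² never underflows during warmup exploration; the zero-variance
(constant-draws) case makes R-hat/ESS return NaN rather than raising.

## Model comparison

The comparison currency is the *outcome* likelihood only: one held-out
unit is one adolescent's hopelessness observation within one parent-role
regression. Item-response likelihoods are deliberately excluded — the
question is which predictor of hopelessness generalises, not which
measurement model fits. Pointwise likelihoods are conditional on each
draw's sampled latent variables, the standard choice when latents are
sampled; whether the original analysis marginalised latent uncertainty
instead is unknown, and this definition is documented as the package's.

PSIS-LOO follows the usual recipe: per unit, importance log-ratios are the
negative per-draw log-likelihoods; the ratio tail is smoothed by a fitted
generalised Pareto distribution (tail size min(0.2 S, 3√S); arviz's
`psislw` provides the smoothing), giving elpd_loo, its SE from the
pointwise spread, p_loo as the in-sample/LOO gap, and the Pareto shape k
per unit with k > 0.7 flagged. An exact-LOO oracle (one refit per held-out
outcome, keeping the unit's item responses so its latents stay informed)
validates the approximation on small N.

Stacking weights maximise Σᵢ log Σₖ wₖ exp(elpd_ik) over the simplex
(SLSQP with analytic gradient, multiple deterministic starts, tolerance
1e-8). The objective is concave; among optima the maximum-entropy weight
vector is returned (a second entropy-maximisation stage constrained to the
optimal objective value), so duplicated models get equal weights and the
result is deterministic.

The measurement-invariance check fits shared vs respondent-group-specific
item parameters and compares them by PSIS-LOO over the *item-response*
likelihood, plus per-item posterior contrasts of (a, b). The outcome
likelihood is useless here; note also that a *uniform* difficulty shift in
the parent response sets is exactly absorbed by the free μ_Δ and is
therefore undetectable in principle — the violation simulations in the
tests use item-varying, mean-zero shifts, which cannot be absorbed.

## Reporting

HDIs are the shortest contiguous interval containing ⌈mass·S⌉ sorted
draws. Threshold probabilities use strict inequality (ties count as "not
below"). Stacked predictive curves combine draws by proportional
subsampling (⌈wₖ·S⌉ seeded draws per model) over a symmetric Δ grid
(default [−2, 2]) with the adolescent trait held at its mean, reported
with 66%/90% HDI bands.

## Interrater reliability

The ICC for the two-clinician re-scoring design uses a one-way
random-effects model on the 1–3 scores treated as continuous, y_ij = μ +
b_i + e_ij with half-normal(0, 2) priors on both SDs, sampled by the same
NUTS engine (non-centred subject effects); ICC = σ_b²/(σ_b²+σ_w²) ∈ [0,1]
by construction. This is an interpretation of the reliability design, not
a reconstruction of the original computation (whose exact likelihood is
not public); treating a 3-point ordinal score as continuous compresses
variance at the scale ends and can mildly understate reliability.

## Synthetic data generator

`generate_dyads` emulates the study conditions: 60 adolescents,
participation probabilities 57/60 (mothers) and 43/60 (fathers) sampled
independently per role with at least one parent enforced by rejection;
unit-variance bivariate-normal latents with defaults ρ = −0.33 (the
reported posterior-mean correlation) and μ_Δ = 0 (not reported; zero mean
discrepancy chosen as the neutral default); 2PL responses to 10 binary
items per administration (the instrument's true/false format implies
dichotomous items; the subscale's item count is not public, 10 is a
configurable choice) with discriminations 0.8–2.0 and difficulties −1.5 to
1.5; outcome cutpoints (−0.88, 0.05) and discrepancy coefficient −0.25
(the reported mother-dyad posterior means); 0.3% MCAR single-item
missingness, capped at two missing items per respondent by rejection.

Each adolescent gets *one* (θ, Δ) pair, shared by their mother- and
father-dyads, and one outcome generated from it: the clinician score is a
property of the adolescent, and treating the discrepancy as a family-level
quantity keeps that single outcome coherently related to both parent-role
regressions (with independent per-dyad latents, the outcome could track at
most one role's discrepancy and the other role's regression would be null
by construction). The fitted model still estimates separate latents per
dyad; each role block marginally satisfies the model's bivariate-normal
assumption exactly.

What the generator does *not* emulate: clinical covariates, informant
response styles (e.g. acquiescence), non-random missingness, any
cross-dyad correlation for two-parent adolescents, or ordinal/Likert item
formats. Passing recovery tests therefore shows the estimator is correct
*under the model's own assumptions*, not that the model is right for real
dyads.

## Built-in calibration studies and their scale

`ldsirt.experiments` packages three studies, sized so a full pass runs on
one CPU in minutes; these sizes are the package's reduced-scale defaults
and are fixed, not tuned:

- **Parameter recovery**: 10 replicates of n = 150 adolescents generated
  with β = −0.4, μ_Δ = 0.2, ρ = −0.3; discrepancy-variant fits with 2
  chains × (300 warmup + 400 draws). Scored by 90%-HDI coverage per
  structural parameter pooled over parent roles, and mean posterior-mean
  bias of β.
- **PSIS vs exact LOO**: a 20-observation ordinal probit regression of
  the outcome on the *known* generated discrepancy (a plain GLM, so the
  comparison isolates the PSIS machinery); 20 exact refits at
  2 × (300 + 1,000) against a 2 × (400 + 2,000) reference fit. PSIS uses
  per-unit relative ESS of the likelihood values, as the methodology
  requires for autocorrelated draws. For the *full latent model* at small
  N, conditional pointwise likelihoods put several units above the
  Pareto-k 0.7 reliability threshold — there PSIS is visibly optimistic
  relative to exact refits, which is precisely what the k diagnostic
  flags; `LooResult.flagged_units` surfaces those units, and conclusions
  should not lean on them.
- **Variant dominance**: 3 replicate datasets of n = 150 generated under
  the discrepancy model with β = −0.4, the study's own effect scale; all
  four variants fit at 2 × (300 + 400) per replicate. Averaged over
  replicates and parent roles, the discrepancy variant should take the
  largest stacking weight and the two-coefficient multi-informant variant
  the largest p_loo. The averaging matters: stacking weights computed on
  one dataset are a noisy statistic (on single datasets the winner can
  flip), so the qualitative pattern is asserted on replicate means. The effect size matters structurally: β·Δ is nested in
  the multi-informant predictor β₁·θ + β₂·(θ+Δ), so with an implausibly
  strong signal the two models become predictively indistinguishable and
  the stacking objective is flat between them; at realistic effect sizes
  the multi model's extra flexibility costs out-of-sample accuracy and
  the parsimonious discrepancy model wins the stack — the regime the
  published comparison itself sits in.

## Known limitations

- The original study's supplementary prior list is not public; the prior
  ledger is a reasoned substitute, so this package replicates the *method*,
  not the exact posterior.
- The published raw data are not deposited; post-processing checks of the
  published derived summaries run on a synthetic normal reconstruction of
  the coefficient posteriors from their printed means/SDs
  (`synthetic_reference.py`), which ignores any skew in the true
  posteriors.
- Exact LOO at reduced refit lengths carries Monte-Carlo error of its own;
  agreement is assessed in units of the pointwise-difference SE.
- The NUTS implementation is single-threaded and favours clarity over raw
  speed; very large n or very long chains are better served by a compiled
  PPL.
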
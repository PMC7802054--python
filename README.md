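# ldsirt

Bayesian modelling of **informant discrepancies** in parent–adolescent
conflict reports, and of how those discrepancies predict clinician-rated
hopelessness in depressed adolescents. Built for researchers in clinical
child psychology and psychiatric epidemiology who work with
multi-informant questionnaire data and ordinal clinical outcomes.

## The model

Parents and adolescents each answer J binary conflict items. Responses
follow a two-parameter logistic IRT model with item parameters shared
across informants (the measurement-invariance assumption):

    P(y_j = 1 | t) = logistic(a_j (t − b_j))

The **latent difference score** constraint defines the parent's latent
trait as θ + Δ, where θ is the adolescent's latent conflict trait and Δ
the discrepancy; per dyad (θ, Δ) ~ N((0, μ_Δ), [[1, ρ], [ρ, 1]]) with unit
variances for identification. The 3-level hopelessness score follows an
ordinal probit regression, P(y = 1) = Φ(c1 − η) etc., with four variants
of the predictor η: β·θ (adolescent report), β·(θ+Δ) (parent report),
β₁·θ + β₂·(θ+Δ) (multi-informant), β·Δ (informant discrepancy). A
negative discrepancy coefficient means hopelessness rises when the parent
reports *less* conflict than the adolescent.

Everything is fit jointly per variant (mother- and father-dyads
simultaneously, shared item parameters) by a built-in NUTS sampler with
analytic gradients, gated on R-hat < 1.01 and zero divergences. Variants
are compared by PSIS-LOO over the outcome likelihood and combined by
predictive **stacking**; an exact leave-one-out oracle (one refit per
held-out outcome) validates the importance-sampling approximation. A
synthetic dyad generator with known ground truth makes the whole pipeline
testable end to end, and a one-way random-effects Bayesian ICC covers
interrater reliability of the clinical rating. See `docs/methods.md` for
assumptions, priors and numerical choices.

## Worked example

`examples/` contains one short script per capability. Fitting the
discrepancy model to a simulated 60-adolescent study
(`python examples/02_fit_discrepancy_model.py`) prints:

```
convergence PASS: max R-hat 1.0068, 0 divergences
      parameter  mean   sd  median  hdi66_lower  hdi66_upper  hdi90_lower  hdi90_upper     ess
 beta_mother[0] -0.12 0.22   -0.12        -0.29         0.13        -0.48         0.24  581.15
      c1_mother -0.90 0.19   -0.90        -1.06        -0.71        -1.21        -0.58 1253.41
      c2_mother  0.01 0.16    0.01        -0.17         0.14        -0.22         0.28 1514.97
mu_delta_mother -0.04 0.17   -0.04        -0.18         0.14        -0.31         0.25  796.24
     rho_mother -0.42 0.16   -0.43        -0.60        -0.31        -0.69        -0.20  508.37
 beta_father[0]  0.06 0.23    0.07        -0.16         0.26        -0.31         0.43  687.11
...
```

`beta_mother` is the regression of hopelessness on the mother–adolescent
latent difference score (generating value −0.4; negative means
adolescents whose mothers under-report conflict relative to them are
rated more hopeless). Note how wide the 90% HDIs are at n = 60 — single
small studies identify these coefficients only loosely, which is why the
replicate recovery study below looks at coverage across many simulated
studies rather than any single fit. `c1`/`c2` are the ordinal cutpoints,
`mu_delta` the mean discrepancy, `rho` the trait–discrepancy correlation
(generated at −0.33).

`examples/03_compare_and_stack.py` runs the full four-variant comparison
and prints per-role PSIS-LOO difference tables plus stacking weights;
with a strong true discrepancy effect the discrepancy variant takes most
of the weight. A thin CLI wraps the same functions
(`ldsirt simulate/run/icc --help`).

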
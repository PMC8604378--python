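# combimeta

Comparative frequentist and Bayesian random-effects meta-analysis, built
around the question of whether people living with HIV (PLHIV) who also have
an age-associated comorbidity — diabetes, hypertension, cardiovascular
disease, respiratory disease or chronic kidney disease — face worse severe
COVID-19 outcomes than people with HIV monoinfection.  The per-study log
odds ratios of the underlying nine-study evidence base ship with the
package, and every stage of the analysis (effect computation, pooling,
heterogeneity, prediction, shrinkage, publication-bias diagnostics,
synthetic-data calibration) is exposed as a small, tested API.

## The models

Each study contributes a log odds ratio `y_i` with known within-study
standard error `sigma_i` under the normal-normal hierarchical model

    y_i ~ N(theta_i, sigma_i^2),     theta_i ~ N(mu, tau^2).

**Frequentist engine.**  The between-study SD `tau` is estimated by the
classic one-step DerSimonian–Laird moment estimator from Cochran's `Q`;
the pooled effect is the inverse-variance weighted mean under weights
`1/(sigma_i^2 + tau^2)` with a Wald 95% CI, heterogeneity is summarized by
`Q`, `I^2` and a Q-profile confidence interval for `tau`.

**Bayesian engine.**  An improper uniform prior on `mu` (integrated out
analytically) and a proper prior on `tau` — half-normal(0.5) by default,
half-normal(1.0) and half-Cauchy(0.5) for sensitivity analysis.  The `tau`
marginal is computed by deterministic quadrature on an adaptive grid (no
MCMC; results are exactly reproducible), and the posteriors of `mu`, of a
future study's effect `theta_new` (the predictive distribution) and of
each study's true effect `theta_i` (shrinkage intervals) are finite
mixtures of normals over that grid.  Reported intervals are 95%
highest-density ("shortest") credible intervals.

**Bias diagnostics.**  Begg–Mazumdar rank correlation and an Egger-type
mixed-effects meta-regression of effects on their standard errors, plus
funnel-plot data export.

## A worked example

```sh
python examples/reproduce_published_analysis.py
```

prints, for the diabetes group (9 studies):

```
diabetes (k=9)
  frequentist : OR  6.69 (3.18-14.08)  tau 0.74  Q 18.27  I2 56.2%
  bayesian    : OR  6.95 (3.45-13.27)  tau 0.54 (0.00-1.05)
  predictive  : OR  7.03 (1.53-29.45)
```

PLHIV with diabetes show roughly seven-fold higher odds of a severe
COVID-19 outcome than PLHIV without comorbidities under either engine.
The Bayesian credible interval is visibly narrower than the frequentist
CI — the informative heterogeneity prior stabilizes `tau` when only nine
studies are available — while the predictive interval is much wider than
either, since a future study carries its own between-study deviation.
For the respiratory-disease group the predictive interval crosses OR = 1
(`3.48 (0.98–11.39)`): the pooled effect is clearly positive, but a new
study could plausibly find no elevated risk.

Other narrative entry points in `examples/`: `prior_sensitivity.py`,
`publication_bias.py`, `simulate_and_recover.py`.  The same pipeline is
scriptable from the shell:

```sh
combimeta reproduce --out results/            # embedded datasets
combimeta simulate --k 20 --seed 7 --out sim.csv
combimeta analyze sim.csv --prior half_normal:0.5 --out sim_results/
```

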
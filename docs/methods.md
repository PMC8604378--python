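# Methods

## Model and data

All analyses operate on study-level log odds ratios under the
normal-normal hierarchical model (NNHM): observed effects
`y_i ~ N(theta_i, sigma_i^2)` with the within-study standard errors
`sigma_i` treated as known, and true study effects
`theta_i ~ N(mu, tau^2)`.  `mu` is the population-average log odds ratio
of a severe COVID-19 outcome for PLHIV with a given comorbidity relative
to HIV monoinfection; `tau` is the between-study SD on the log-OR scale.

The embedded evidence base (`combimeta.datasets`) stores, per study, the
published log odds ratio and within-study variance for five comorbidity
groups (diabetes k=9, hypertension k=8, cardiovascular disease k=6,
respiratory disease k=6, chronic kidney disease k=5).  Two transcription
decisions matter and are deliberate:

* the published per-study dispersion column is a **variance**, not a
  standard deviation — squaring the CI-implied standard errors
  `((hi - lo)/3.92)^2` reproduces that column row by row, and only the
  variance reading reproduces the published pooled results.
  `StudyEffect.sigma` therefore stores its square root;
* the Isernia respiratory-disease entry is stored as `y = 2.29`, the
  centre of its published interval `(-1.13, 5.71)`; the published point
  value 0.29 is inconsistent with that interval and with the published
  pooled respiratory results, which `y = 2.29` reproduces exactly
  (`Q = 2.29`).

Raw 2x2 counts were not published, so the embedded studies carry none;
the `effects` CSV schema is the primary input path, with the `counts`
schema (and the Haldane–Anscombe +0.5 correction, applied to all four
cells only when some cell is zero) available for primary data.  Wald
(Woolf) standard errors and a fixed 1.96 multiplier are used for 95%
intervals throughout the frequentist side, matching the reporting
convention of the source studies.

## Frequentist engine

One-step DerSimonian–Laird: `tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1))`
with fixed-effect weights, no iteration.  Pooling uses
`w_i* = 1/(sigma_i^2 + tau^2)`; `I^2 = max(0, (Q - df)/Q) * 100` (for DL
this is algebraically the `tau^2/(tau^2 + s^2)` form with the typical
sampling variance `s^2`).  The CI for `tau` is the Q-profile interval:
the set of `tau` with `Q(tau)` inside the central 95% chi-square(k-1)
region; `Q(tau)` is monotone decreasing so each endpoint is a single
root, bracketed by doubling and solved with Brent's method (xtol 1e-8),
truncated at 0.  A single study returns `tau = 0`, `Q = 0`, `I^2 = 0` and
no `tau` CI.

These choices reproduce R `metafor::rma(method="DL")` plus
`confint()` to ~1e-6 (frozen oracle values in the test suite).  A known
caveat: the *published* heterogeneity summaries for these data
(e.g. diabetes `tau = 0.82`, `I^2 = 61.4%`, and the slightly wider pooled
CIs) correspond to a likelihood-based (REML) `tau` estimate, although the
accompanying text names DerSimonian–Laird.  This package implements the
named method; on the embedded inputs it gives diabetes `tau = 0.74`,
`I^2 = 56.2%`.  The pooled odds ratios are essentially unaffected (both
estimators agree on `mu` to two decimals on every dataset).  The
corresponding test documents the published value and fails honestly.

## Bayesian engine

Priors: improper uniform on `mu` over the real line (the conventional
choice for NNHM meta-analysis; it makes `mu` integrable in closed form),
and a proper `HeterogeneityPrior` on `tau`: half-normal with scale 0.5 by
default — an informative prior appropriate for log-OR endpoints, placing
~95% mass on `tau < 1` — with half-normal(1.0) and half-Cauchy(0.5) as
sensitivity companions.

With `mu` integrated out, the marginal likelihood is
`L(tau) = (sum w_i)^(-1/2) prod(w_i)^(1/2) exp(-Q(tau)/2)` with
`w_i = 1/(sigma_i^2 + tau^2)`; the `tau` posterior is tabulated on a
deterministic grid and every downstream posterior (`mu`, predictive
`theta_new`, per-study `theta_i`) is a finite mixture of normals over
that grid:

* `mu | tau, y ~ N(mu_hat(tau), s^2(tau))`;
* `theta_new | tau, y ~ N(mu_hat, s^2 + tau^2)`;
* `theta_i | tau, y ~ N(b_i y_i + (1-b_i) mu_hat, b_i sigma_i^2 +
  (1-b_i)^2 s^2)` with shrinkage factor `b_i = tau^2/(tau^2 + sigma_i^2)`.

Numerical choices:

* **Grid.**  Uniform in `u = tau/(tau + s)` with adaptation scale
  `s = prior scale + DL tau-hat`, 4001 points by default, extending to
  the prior's `1 - 1e-7` quantile so the omitted tail mass is below 1e-6
  even for the heavy-tailed half-Cauchy (for which a uniform `tau` grid
  would be hopeless).  Log-space accumulation avoids underflow with very
  precise studies (the most precise embedded study has variance 0.04).
  Doubling the grid changes every reported summary by < 1e-4 (tested).
* **Summaries.**  Posterior medians, and 95% *shortest* (highest-density)
  intervals.  Shortest intervals are solved from the HDI condition
  `pdf(lo) = pdf(hi)`, `cdf(hi) - cdf(lo) = 0.95` by a bracketed root
  search on the left endpoint; for densities supported on `[0, inf)`
  whose maximum sits at the origin the interval is one-sided from 0 —
  which is why reported `tau` intervals have a lower bound of exactly 0,
  matching the published credible intervals.  Central intervals would
  have strictly positive lower bounds.  Mixture CDF roots are solved by
  Brent's method to 1e-10.
* **Degenerate limits** (tested): a prior collapsing to `tau = 0` recovers
  the fixed-effect conjugate normal for `mu`, makes the predictive equal
  the `mu` posterior and every shrinkage interval equal the `mu`
  posterior; a study with enormous `sigma_i` has a shrinkage posterior
  equal to the predictive distribution; with one study the `tau`
  posterior equals the prior.

The engine is verified against an independent brute-force 2-D trapezoid
integration over `(mu, tau)` (and `(theta_i, tau)` for shrinkage) on
dense uniform grids: all medians and interval endpoints agree within
1e-3 on batches of random small meta-analyses.

Reproduction caveat: on the embedded inputs the Bayesian medians match
the published values closely for hypertension, cardiovascular and
respiratory disease (within ~0.01–0.02 on the log scale; where the
published table and the published text disagree on hypertension's `tau`
— 0.41 vs 0.36 — the computation supports the text), but the diabetes
and chronic-kidney pooled medians come out ~0.02 and ~0.035 higher on
the log scale (OR 6.95 vs 6.82; 8.37 vs 8.08).  The brute-force oracle
confirms the quadrature, and re-deriving the inputs from the published
per-study CIs instead of the variance column does not close the gap, so
the published values were presumably computed from unrounded inputs that
were never published.  The chronic-kidney test documents the published
value and fails honestly.

## Publication-bias diagnostics

* **Rank test** (Begg–Mazumdar): Kendall's tau between
  `(y_i - mu_FE)/sqrt(sigma_i^2 - 1/sum(w))` and `sigma_i^2`; exact
  p-value for k <= 8 without ties, normal approximation otherwise.
* **Regression test** (Egger-type, mixed-effects): `y_i` regressed on a
  moderator (standard error by default; variance and `1/n` exposed as
  options since the choice is conventional), with the moderated model's
  `tau^2` from the generalized DL moment estimator and a Wald z on the
  moderator coefficient.  Reproduces `metafor::regtest(model="rma",
  method="DL", predictor="sei")` to ~1e-8.  All-equal moderators raise a
  degenerate-design error.

Both tests require k >= 3 and are invariant to a common shift of the
effects.  Under null simulations (k=20 effects drawn from the NNHM with
`mu=1.5`, `tau=0.5`, variances uniform on (0.05, 2) — the spread of the
embedded data), the regression test rejects at ~6% at the 5% level over
500 seeded replicates; the rank test is conservative (~3%), as expected
for rank statistics at this k.

## Synthetic-data generator

`simulate_dataset` emulates exactly the structure the models assume:
`theta_i ~ N(mu, tau^2)`, comparator risk `p0 ~ U(0.05, 0.30)`, exposed
risk through the logit link, binomial counts with per-arm sizes uniform
on 30–300, Haldane correction on zero cells, bounded resampling of
degenerate (all-zero-margin) tables.  Defaults (k=20, mu=1.5, tau=0.5)
mirror the effect sizes and study sizes of the embedded evidence base.
One integer seed drives a single `numpy` Generator; exports are
byte-identical across runs.  Two deliberate departures from realism are
available as toggles only: an additive risk-difference effect scale (a
misspecification probe) and a crude suppression mechanism that censors
below-average effects (for the bias tests' alternative hypothesis).

Because `sigma_i` is estimated from the simulated counts but treated as
known by both engines — exactly as in real meta-analyses — calibration is
approximate: over 500 seeded replicates at the defaults the 95% Bayesian
HDI for `mu` covers the truth ~94% of the time and the mean DL estimate
is unbiased within Monte-Carlo error (both tested).  Passing these checks
shows the engines are correctly calibrated *for the assumed generative
process*; it says nothing about non-normal random effects, correlated
estimates, outcome misclassification or real selection effects.

## Known limitations

* No REML/ML/Paule–Mandel `tau` estimators, no Knapp–Hartung adjustment,
  no meta-regression beyond the asymmetry moderator, no trim-and-fill or
  selection models, and no risk/hazard ratios — log odds ratios only.
* The `sigma_i` are treated as known in both engines; with very small
  studies this understates uncertainty.
* Shortest-interval reporting was chosen to match the published credible
  intervals; whether those were shortest or central is not stated in the
  source, and the two differ most for `tau`.
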
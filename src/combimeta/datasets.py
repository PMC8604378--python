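"""The embedded PLHIV/COVID-19 comorbidity dataset.

Per-study log odds ratios of severe COVID-19 outcomes comparing people
living with HIV (PLHIV) who have an age-associated comorbidity against
PLHIV without comorbidities (HIV monoinfection), as published in the model
summary table of the source meta-analysis (nine primary studies, five
comorbidity groups).  The published table reports, per study, the log odds
ratio with its 95% CI and the *within-study variance* ``sigma_i^2``; the
variance column reproduces the squared CI-implied standard errors, and the
variance reading is the one that reproduces the published pooled results,
so that is what is stored here.  ``StudyEffect.sigma`` is its square root.

One transcription correction: the Isernia respiratory-disease entry is
stored with y = 2.29, the centre of its published interval (-1.13, 5.71);
the published point value 0.29 is inconsistent with both that interval and
the published pooled respiratory-disease results, which y = 2.29 reproduces
exactly.

Raw 2x2 counts were not published, so ``counts`` is ``None`` throughout.
"""
from __future__ import annotations

import math

from .data import ComorbidityDataset, StudyEffect

__all__ = [
    "COMORBIDITIES",
    "plhiv_comorbidity_studies",
    "published_study_intervals",
    "published_summaries",
]

COMORBIDITIES = (
    "diabetes",
    "hypertension",
    "cardiovascular_disease",
    "respiratory_disease",
    "chronic_kidney_disease",
)

# comorbidity -> (study_label, year, country, sample_size, outcome_type, y, variance)
_TABLE: dict[str, tuple[tuple[str, int, str, int, str, float, float], ...]] = {
    "diabetes": (
        ("Bhaskaran", 2021, "UK", 27480, "mortality", 3.63, 0.57),
        ("Boulle", 2020, "South Africa", 3978, "mortality", 2.26, 0.04),
        ("Ceballos", 2020, "Chile", 36, "mortality", 2.2, 2.11),
        ("Dandachi", 2020, "US", 286, "hospitalization", 1.14, 0.18),
        ("Etienne", 2020, "France", 54, "severe_critical", 3.91, 2.45),
        ("Isernia", 2020, "France", 30, "hospitalization", 2.93, 2.49),
        ("Meyerowitz", 2020, "US", 36, "hospitalization", 0.73, 0.98),
        ("Pujari", 2021, "India", 86, "severe_critical", 1.53, 0.70),
        ("Vizcarra", 2020, "Spain", 51, "severe_critical", -0.47, 1.48),
    ),
    "hypertension": (
        ("Bhaskaran", 2021, "UK", 27480, "mortality", 3.02, 0.57),
        ("Ceballos", 2020, "Chile", 36, "mortality", 2.2, 1.78),
        ("Dandachi", 2020, "US", 286, "hospitalization", 1.08, 0.13),
        ("Etienne", 2020, "France", 54, "severe_critical", 1.86, 0.55),
        ("Isernia", 2020, "France", 30, "hospitalization", 2.25, 2.49),
        ("Meyerowitz", 2020, "US", 36, "hospitalization", 0.04, 0.82),
        ("Pujari", 2021, "India", 86, "severe_critical", 1.56, 0.51),
        ("Vizcarra", 2020, "Spain", 51, "severe_critical", 0.37, 0.59),
    ),
    "cardiovascular_disease": (
        ("Ceballos", 2020, "Chile", 36, "mortality", 3.3, 2.44),
        ("Dandachi", 2020, "US", 286, "hospitalization", 1.95, 0.34),
        ("Etienne", 2020, "France", 54, "severe_critical", 1.61, 0.47),
        ("Isernia", 2020, "France", 30, "hospitalization", 1.84, 2.94),
        ("Meyerowitz", 2020, "US", 36, "hospitalization", 2.4, 2.63),
        ("Vizcarra", 2020, "Spain", 51, "severe_critical", -0.47, 0.90),
    ),
    "respiratory_disease": (
        ("Ceballos", 2020, "Chile", 36, "mortality", 0.75, 3.44),
        ("Dandachi", 2020, "US", 286, "hospitalization", 1.58, 0.22),
        ("Etienne", 2020, "France", 54, "severe_critical", 1.2, 1.13),
        ("Isernia", 2020, "France", 30, "hospitalization", 2.29, 3.04),
        ("Meyerowitz", 2020, "US", 36, "hospitalization", 0.22, 1.45),
        ("Vizcarra", 2020, "Spain", 51, "severe_critical", 0.22, 1.65),
    ),
    "chronic_kidney_disease": (
        ("Bhaskaran", 2021, "UK", 27480, "mortality", 3.74, 0.61),
        ("Ceballos", 2020, "Chile", 36, "mortality", 2.2, 2.11),
        ("Dandachi", 2020, "US", 286, "hospitalization", 1.58, 0.22),
        ("Etienne", 2020, "France", 54, "severe_critical", 3.46, 2.56),
        ("Meyerowitz", 2020, "US", 36, "hospitalization", 0.22, 1.45),
    ),
}

# Published per-study 95% CIs, in the row order of _TABLE.  Kept for
# transcription checks only: each must equal y +/- 1.96*sqrt(variance)
# within rounding.  The models never consume them.
_STUDY_CIS: dict[str, tuple[tuple[float, float], ...]] = {
    "diabetes": (
        (2.15, 5.11), (1.88, 2.64), (-0.65, 5.04), (0.31, 1.96), (0.84, 6.98),
        (-0.16, 6.03), (-1.21, 2.68), (-0.11, 3.17), (-2.86, 1.92),
    ),
    "hypertension": (
        (1.55, 4.50), (-0.42, 4.81), (0.36, 1.80), (0.40, 3.32),
        (-0.84, 5.34), (-1.73, 1.81), (0.16, 2.96), (-1.14, 1.88),
    ),
    "cardiovascular_disease": (
        (0.23, 6.36), (0.81, 3.10), (0.27, 2.95), (-1.52, 5.19),
        (-0.78, 5.57), (-2.33, 1.39),
    ),
    "respiratory_disease": (
        (-2.89, 4.38), (0.67, 2.50), (-0.88, 3.29), (-1.13, 5.71),
        (-2.14, 2.58), (-2.29, 2.74),
    ),
    "chronic_kidney_disease": (
        (2.20, 5.27), (-0.65, 5.04), (0.67, 2.50), (0.33, 6.60), (-2.14, 2.58),
    ),
}


def published_study_intervals() -> dict[str, tuple[tuple[float, float], ...]]:
    """Published per-study 95% CIs, for transcription consistency checks."""
    return dict(_STUDY_CIS)


# Published pooled results (for side-by-side comparison output).  Frequentist
# values on the log-OR scale: pooled effect with CI, tau with CI, Q, I2(%).
# Bayesian values (half-normal scale-0.5 prior): posterior medians and 95%
# credible intervals for the pooled effect, tau and the predictive
# distribution, log-OR scale.
_PUBLISHED: dict[str, dict[str, object]] = {
    "diabetes": dict(
        freq_mu=1.90, freq_mu_ci=(1.11, 2.69), freq_tau=0.82, freq_tau_ci=(0.12, 2.42),
        freq_or=6.69, q=18.35, i2=61.40,
        bayes_mu=1.92, bayes_mu_cri=(1.22, 2.57), bayes_or=6.82,
        bayes_tau=0.54, bayes_tau_cri=(0.0, 1.05),
        predictive=1.94, predictive_cri=(0.41, 3.37), predictive_or=6.96,
    ),
    "hypertension": dict(
        freq_mu=1.42, freq_mu_ci=(0.75, 2.10), freq_tau=0.56, freq_tau_ci=(0.0, 1.84),
        freq_or=4.14, q=10.49, i2=36.41,
        bayes_mu=1.38, bayes_mu_cri=(0.76, 2.02), bayes_or=3.97,
        bayes_tau=0.36, bayes_tau_cri=(0.0, 0.90),
        predictive=1.37, predictive_cri=(0.20, 2.62), predictive_or=3.94,
    ),
    "cardiovascular_disease": dict(
        freq_mu=1.56, freq_mu_ci=(0.64, 2.48), freq_tau=0.58, freq_tau_ci=(0.0, 2.82),
        freq_or=4.75, q=6.56, i2=26.79,
        bayes_mu=1.55, bayes_mu_cri=(0.69, 2.41), bayes_or=4.71,
        bayes_tau=0.35, bayes_tau_cri=(0.0, 0.94),
        predictive=1.55, predictive_cri=(0.20, 2.89), predictive_or=4.71,
    ),
    "respiratory_disease": dict(
        freq_mu=1.30, freq_mu_ci=(0.58, 2.02), freq_tau=0.0, freq_tau_ci=(0.0, 1.43),
        freq_or=3.67, q=2.29, i2=0.00,
        bayes_mu=1.23, bayes_mu_cri=(0.35, 2.08), bayes_or=3.42,
        bayes_tau=0.28, bayes_tau_cri=(0.0, 0.82),
        predictive=1.24, predictive_cri=(-0.04, 2.42), predictive_or=3.46,
    ),
    "chronic_kidney_disease": dict(
        freq_mu=2.20, freq_mu_ci=(0.93, 3.47), freq_tau=1.02, freq_tau_ci=(0.0, 3.96),
        freq_or=9.02, q=8.74, i2=55.01,
        bayes_mu=2.09, bayes_mu_cri=(1.15, 3.07), bayes_or=8.08,
        bayes_tau=0.47, bayes_tau_cri=(0.0, 1.08),
        predictive=2.09, predictive_cri=(0.54, 3.72), predictive_or=8.08,
    ),
}


def plhiv_comorbidity_studies() -> dict[str, ComorbidityDataset]:
    """Return the five embedded comorbidity datasets keyed by name.

    Dataset sizes: diabetes 9, hypertension 8, cardiovascular disease 6,
    respiratory disease 6, chronic kidney disease 5.
    """
    out: dict[str, ComorbidityDataset] = {}
    for name in COMORBIDITIES:
        studies = tuple(
            StudyEffect(
                study_label=label,
                year=year,
                country=country,
                sample_size=n,
                outcome_type=outcome,
                y=y,
                sigma=math.sqrt(var),
            )
            for (label, year, country, n, outcome, y, var) in _TABLE[name]
        )
        out[name] = ComorbidityDataset(name=name, studies=studies)
    return out


def published_summaries() -> dict[str, dict[str, object]]:
    """Published pooled summaries per comorbidity, for comparison reports."""
    return {name: dict(values) for name, values in _PUBLISHED.items()}
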
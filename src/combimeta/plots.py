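"""Thin plotting layer over the analysis results (matplotlib).

All numeric content lives in the result objects and exported CSVs; these
helpers only draw them.
"""
from __future__ import annotations

import numpy as np

from .bayesian import BayesResult
from .bias import funnel_data
from .data import ComorbidityDataset
from .frequentist import FrequentistResult


def forest_plot(
    dataset: ComorbidityDataset,
    frequentist: FrequentistResult | None = None,
    bayesian: BayesResult | None = None,
    ax=None,
):
    """Forest plot: per-study 95% CIs, optional shrinkage intervals,
    pooled diamond and predictive bar.  Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * dataset.k + 2))
    ys = np.arange(dataset.k, 0, -1, dtype=float)
    for pos, study in zip(ys, dataset):
        lo, hi = study.ci
        ax.plot([lo, hi], [pos, pos], color="black")
        ax.plot(study.y, pos, "s", color="black", ms=5)
    if bayesian is not None:
        for pos, shrink in zip(ys, bayesian.shrinkage):
            ax.plot(shrink.interval, [pos - 0.22, pos - 0.22], color="grey", lw=2, alpha=0.8)
    bottom = 0.0
    if frequentist is not None:
        lo, hi = frequentist.mu_ci
        ax.plot([lo, frequentist.mu_hat, hi], [0.4, 0.25, 0.4], color="black")
        ax.plot([lo, frequentist.mu_hat, hi], [0.4, 0.55, 0.4], color="black")
        bottom = -0.3
    if bayesian is not None:
        ax.plot(bayesian.predictive_cri, [bottom, bottom], color="black", lw=4)
    ax.axvline(0.0, color="grey", ls=":", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels(dataset.labels)
    ax.set_xlabel("log odds ratio")
    ax.set_title(dataset.name)
    return ax


def funnel_plot(dataset: ComorbidityDataset, ax=None):
    """Funnel plot: effects against standard error with the pooled line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    df = funnel_data(dataset)
    pooled = float(df["pooled_log_or"].iloc[0])
    se_max = float(df["se"].max()) * 1.1
    ax.plot(df["log_or"], df["se"], "o", color="black")
    ax.plot(
        [pooled - 1.96 * se_max, pooled, pooled + 1.96 * se_max],
        [se_max, 0.0, se_max],
        color="grey",
        ls="--",
        lw=1,
    )
    ax.axvline(pooled, color="grey", lw=1)
    ax.set_ylim(se_max, 0.0)
    ax.set_xlabel("log odds ratio")
    ax.set_ylabel("standard error")
    ax.set_title(dataset.name)
    return ax
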
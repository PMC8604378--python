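"""Publication-bias (funnel-plot asymmetry) diagnostics.

Two classical small-study tests: the Begg-Mazumdar rank correlation between
variance-stabilized standardized effects and the within-study variances, and
an Egger-type mixed-effects meta-regression of the effects on their
precision moderator.  Funnel-plot coordinates are exported as data; plotting
is a thin optional layer (see :mod:`combimeta.plots`).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ComorbidityDataset, StudyEffect
from .effects import DomainError
from .frequentist import _arrays, pool

__all__ = [
    "RankTest",
    "RegressionTest",
    "BiasReport",
    "rank_correlation_test",
    "regression_test",
    "funnel_data",
    "assess_bias",
]

MODERATORS = ("se", "variance", "inverse_n")


@dataclass(frozen=True)
class RankTest:
    """Begg-Mazumdar rank correlation result."""

    tau: float
    p_value: float
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class RegressionTest:
    """Egger-type mixed-effects meta-regression asymmetry result."""

    intercept: float
    slope: float
    se_slope: float
    z: float
    p_value: float
    moderator: str
    tau2: float


@dataclass(frozen=True)
class BiasReport:
    funnel: pd.DataFrame
    rank_test: RankTest
    regression_test: RegressionTest

    def to_dict(self) -> dict:
        return {
            "rank_tau": self.rank_test.tau,
            "rank_p": self.rank_test.p_value,
            "rank_method": self.rank_test.method,
            "regression_slope": self.regression_test.slope,
            "regression_z": self.regression_test.z,
            "regression_p": self.regression_test.p_value,
            "regression_moderator": self.regression_test.moderator,
        }


def _check_k(y: np.ndarray) -> None:
    if y.size < 3:
        raise DomainError("asymmetry tests require at least 3 studies")


def rank_correlation_test(studies: Sequence[StudyEffect] | ComorbidityDataset) -> RankTest:
    """Begg-Mazumdar rank correlation test for funnel-plot asymmetry.

    Deviations of each effect from the fixed-effect pooled estimate are
    standardized by the variance-stabilized SD ``sqrt(sigma_i^2 - 1/sum(w))``
    (the variance of ``y_i - mu_fe``), then Kendall's tau is computed
    between the standardized effects and the variances.  The p-value is
    exact for k <= 8 (unless ties force the normal approximation) and a
    normal approximation otherwise.
    """
    y, v = _arrays(studies)
    _check_k(y)
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    v_star = v - 1.0 / np.sum(w)
    z_std = (y - mu_fe) / np.sqrt(v_star)

    has_ties = len(np.unique(z_std)) < z_std.size or len(np.unique(v)) < v.size
    method = "exact" if (y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.kendalltau(z_std, v, method=method)
    return RankTest(
        tau=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if method == "exact" else "normal",
    )


def _moderator(studies, name: str) -> np.ndarray:
    y, v = _arrays(studies)
    if name == "se":
        return np.sqrt(v)
    if name == "variance":
        return v
    if name == "inverse_n":
        if isinstance(studies, ComorbidityDataset):
            sizes = [s.sample_size for s in studies]
        else:
            sizes = [s.sample_size for s in studies]
        if any(n is None for n in sizes):
            raise DomainError("inverse_n moderator requires sample_size on every study")
        return 1.0 / np.asarray(sizes, dtype=float)
    raise ValueError(f"unknown moderator {name!r}; expected one of {MODERATORS}")


def regression_test(
    studies: Sequence[StudyEffect] | ComorbidityDataset, moderator: str = "se"
) -> RegressionTest:
    """Egger-type asymmetry test via random-effects meta-regression.

    The effects are regressed on the moderator (standard error by default)
    in a mixed-effects model: the between-study variance of the moderated
    model is estimated by the generalized DerSimonian-Laird moment method,
    the coefficients are re-fitted by weighted least squares under
    ``1/(sigma_i^2 + tau^2)`` weights, and the asymmetry statistic is the
    Wald z of the moderator coefficient.
    """
    y, v = _arrays(studies)
    _check_k(y)
    x = _moderator(studies, moderator)
    if np.ptp(x) == 0:
        raise DomainError(
            f"moderator {moderator!r} is constant across studies; the asymmetry "
            "regression is degenerate"
        )
    X = np.column_stack([np.ones_like(x), x])
    k, p = X.shape

    # fixed-effects fit and generalized Q of the moderated model
    W = 1.0 / v
    XtWX = X.T @ (X * W[:, None])
    beta_fe = np.linalg.solve(XtWX, X.T @ (W * y))
    resid = y - X @ beta_fe
    q_e = float(np.sum(W * resid**2))
    # trace of P = W - W X (X'WX)^-1 X'W
    trace_p = float(np.sum(W) - np.trace(np.linalg.solve(XtWX, X.T @ (X * (W**2)[:, None]))))
    tau2 = max(0.0, (q_e - (k - p)) / trace_p)

    W_star = 1.0 / (v + tau2)
    XtWX_star = X.T @ (X * W_star[:, None])
    beta = np.linalg.solve(XtWX_star, X.T @ (W_star * y))
    cov = np.linalg.inv(XtWX_star)
    se_slope = float(np.sqrt(cov[1, 1]))
    z = float(beta[1] / se_slope)
    return RegressionTest(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        se_slope=se_slope,
        z=z,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        moderator=moderator,
        tau2=tau2,
    )


def funnel_data(studies: Sequence[StudyEffect] | ComorbidityDataset) -> pd.DataFrame:
    """Funnel-plot coordinates: per-study effect and SE plus the pooled line."""
    if isinstance(studies, ComorbidityDataset):
        labels = studies.labels
    else:
        labels = [s.study_label for s in studies]
    y, v = _arrays(studies)
    pooled = pool(list(zip_studies(studies)))
    return pd.DataFrame(
        {
            "study_label": labels,
            "log_or": y,
            "se": np.sqrt(v),
            "pooled_log_or": pooled.mu_hat,
        }
    )


def zip_studies(studies):
    if isinstance(studies, ComorbidityDataset):
        return list(studies.studies)
    return list(studies)


def assess_bias(
    studies: Sequence[StudyEffect] | ComorbidityDataset, moderator: str = "se"
) -> BiasReport:
    """Run both asymmetry tests and assemble funnel data."""
    return BiasReport(
        funnel=funnel_data(studies),
        rank_test=rank_correlation_test(studies),
        regression_test=regression_test(studies, moderator=moderator),
    )
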
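"""Classical random-effects meta-analysis with the DerSimonian-Laird estimator.

The model is the normal-normal hierarchy y_i ~ N(theta_i, sigma_i^2),
theta_i ~ N(mu, tau^2).  The between-study variance tau^2 is estimated by
the classic one-step DerSimonian-Laird moment estimator from Cochran's Q;
the pooled effect is the inverse-variance weighted mean under the
random-effects weights 1/(sigma_i^2 + tau^2) with a Wald z interval.  A
confidence interval for tau comes from the Q-profile method (the set of
tau values whose generalized Q statistic falls inside the central
chi-square acceptance region).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .data import ComorbidityDataset, StudyEffect
from .effects import DomainError, Z95

__all__ = ["FrequentistResult", "dl_tau2", "cochran_q", "pool", "tau_ci"]


def _arrays(studies) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(studies, ComorbidityDataset):
        studies = studies.studies
    studies = list(studies)
    if len(studies) == 0:
        raise DomainError("meta-analysis requires at least one study")
    y = np.array([s.y for s in studies], dtype=float)
    v = np.array([s.sigma**2 for s in studies], dtype=float)
    return y, v


@dataclass(frozen=True)
class FrequentistResult:
    """Pooled random-effects summary of one meta-analysis.

    All effect quantities are on the log odds ratio scale; ``to_dict``
    additionally reports the exponentiated (odds ratio) scale.
    """

    mu_hat: float
    se: float
    mu_ci: tuple[float, float]
    tau2_hat: float
    tau_hat: float
    tau_ci: tuple[float, float] | None
    q: float
    df: int
    p_q: float
    i2: float
    weights: tuple[float, ...]  # normalized random-effects weights

    def to_dict(self) -> dict:
        d = {
            "mu_hat": self.mu_hat,
            "se": self.se,
            "mu_ci_low": self.mu_ci[0],
            "mu_ci_high": self.mu_ci[1],
            "tau_hat": self.tau_hat,
            "tau_ci_low": None if self.tau_ci is None else self.tau_ci[0],
            "tau_ci_high": None if self.tau_ci is None else self.tau_ci[1],
            "q": self.q,
            "df": self.df,
            "p_q": self.p_q,
            "i2": self.i2,
            "or": float(np.exp(self.mu_hat)),
            "or_ci_low": float(np.exp(self.mu_ci[0])),
            "or_ci_high": float(np.exp(self.mu_ci[1])),
        }
        return d


def dl_tau2(studies: Sequence[StudyEffect] | ComorbidityDataset) -> float:
    """One-step DerSimonian-Laird moment estimate of tau^2.

    ``tau2 = max(0, (Q - (k-1)) / (S1 - S2/S1))`` with fixed-effect weights
    ``w_i = 1/sigma_i^2``, ``S1 = sum(w_i)``, ``S2 = sum(w_i^2)``.  A single
    study carries no information on heterogeneity and returns 0.
    """
    y, v = _arrays(studies)
    k = y.size
    if k == 1:
        return 0.0
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    return max(0.0, (q - (k - 1)) / (s1 - s2 / s1))


def cochran_q(studies: Sequence[StudyEffect] | ComorbidityDataset) -> tuple[float, int, float]:
    """Cochran's Q about the fixed-effect mean, its df and chi-square p-value."""
    y, v = _arrays(studies)
    k = y.size
    if k == 1:
        return 0.0, 0, 1.0
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def _generalized_q(tau: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau**2)
    mu = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - mu) ** 2))


def tau_ci(
    studies: Sequence[StudyEffect] | ComorbidityDataset, level: float = 0.95
) -> tuple[float, float]:
    """Q-profile confidence interval for the between-study SD tau.

    The interval is ``{tau >= 0 : chi2_{alpha/2, k-1} <= Q(tau) <=
    chi2_{1-alpha/2, k-1}}`` where ``Q(tau)`` is the generalized Q statistic
    under weights ``1/(sigma_i^2 + tau^2)``.  ``Q`` is decreasing in tau, so
    each endpoint is a single root; bounds are truncated at 0 when the
    acceptance region already covers homogeneity.
    """
    y, v = _arrays(studies)
    k = y.size
    if k < 2:
        raise DomainError("tau confidence interval requires at least 2 studies")
    alpha = 1.0 - level
    df = k - 1
    q_hi = stats.chi2.ppf(1 - alpha / 2, df)
    q_lo = stats.chi2.ppf(alpha / 2, df)

    def solve(target: float) -> float:
        if _generalized_q(0.0, y, v) <= target:
            return 0.0
        upper = 1.0
        while _generalized_q(upper, y, v) > target:
            upper *= 2.0
            if upper > 1e8:  # pragma: no cover - pathological inputs
                raise RuntimeError("failed to bracket Q-profile root")
        return float(
            optimize.brentq(
                lambda t: _generalized_q(t, y, v) - target, 0.0, upper, xtol=1e-8
            )
        )

    return solve(q_hi), solve(q_lo)


def pool(studies: Sequence[StudyEffect] | ComorbidityDataset) -> FrequentistResult:
    """DerSimonian-Laird random-effects pooled estimate.

    Returns the pooled log odds ratio with its 95% Wald interval, the DL
    heterogeneity estimate with Q-profile CI (when k >= 2), Cochran's Q,
    I^2 = max(0, (Q - df)/Q) * 100 and the normalized random-effects
    weights.
    """
    y, v = _arrays(studies)
    k = y.size
    tau2 = dl_tau2(studies)
    q, df, p_q = cochran_q(studies)
    w_star = 1.0 / (v + tau2)
    mu_hat = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    ci = tau_ci(studies) if k >= 2 else None
    return FrequentistResult(
        mu_hat=mu_hat,
        se=se,
        mu_ci=(mu_hat - Z95 * se, mu_hat + Z95 * se),
        tau2_hat=tau2,
        tau_hat=float(np.sqrt(tau2)),
        tau_ci=ci,
        q=q,
        df=df,
        p_q=p_q,
        i2=i2,
        weights=tuple(w_star / np.sum(w_star)),
    )
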
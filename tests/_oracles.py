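"""Independent brute-force oracles used by the tests.

Everything here recomputes posterior quantities from first principles on
dense uniform grids with trapezoid integration and interpolated quantile
functions — deliberately avoiding the package's transformed-grid
quadrature, its conditional-normal mixture machinery and its root-finding
paths, so agreement is a real cross-check.
"""
from __future__ import annotations

import numpy as np


def _halfnormal_logpdf(tau: np.ndarray, scale: float) -> np.ndarray:
    return np.where(
        tau >= 0,
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (tau / scale) ** 2,
        -np.inf,
    )


def _halfcauchy_logpdf(tau: np.ndarray, scale: float) -> np.ndarray:
    return np.where(
        tau >= 0,
        np.log(2.0 / np.pi) - np.log(scale) - np.log1p((tau / scale) ** 2),
        -np.inf,
    )


def prior_logpdf(tau: np.ndarray, family: str, scale: float) -> np.ndarray:
    if family == "half_normal":
        return _halfnormal_logpdf(tau, scale)
    if family == "half_cauchy":
        return _halfcauchy_logpdf(tau, scale)
    raise ValueError(family)


class GriddedDensity:
    """A 1-D density tabulated on a uniform grid, with interp quantiles."""

    def __init__(self, x: np.ndarray, density: np.ndarray):
        self.x = x
        area = np.trapezoid(density, x)
        self.density = density / area
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.density[1:] + self.density[:-1]) * np.diff(x))]
        )
        self.cdf_values = cum / cum[-1]

    def pdf(self, q: float) -> float:
        return float(np.interp(q, self.x, self.density))

    def cdf(self, q: float) -> float:
        return float(np.interp(q, self.x, self.cdf_values))

    def ppf(self, p: float) -> float:
        return float(np.interp(p, self.cdf_values, self.x))

    def median(self) -> float:
        return self.ppf(0.5)

    def hdi(self, level: float = 0.95, bounded_below: bool = False) -> tuple[float, float]:
        """Shortest interval by scanning left endpoints on the grid.

        The candidate right endpoint for each left endpoint comes from the
        interpolated quantile function; the scan is refined by golden-ratio
        free parabolic polish around the best grid point.
        """
        lo_candidates = self.x[self.cdf_values <= 1.0 - level]
        if bounded_below and self.pdf(self.x[0]) >= self.pdf(self.ppf(level)):
            return float(self.x[0]), self.ppf(self.cdf(self.x[0]) + level)
        widths = np.array(
            [self.ppf(self.cdf(l) + level) - l for l in lo_candidates]
        )
        i = int(np.argmin(widths))
        # parabolic refinement on the three nearest scan points
        if 0 < i < len(lo_candidates) - 1:
            l0, l1, l2 = lo_candidates[i - 1 : i + 2]
            w0, w1, w2 = widths[i - 1 : i + 2]
            denom = (w0 - 2 * w1 + w2)
            if denom > 0:
                shift = 0.5 * (w0 - w2) / denom * (l1 - l0)
                l_best = l1 + np.clip(shift, l0 - l1, l2 - l1)
            else:
                l_best = l1
        else:
            l_best = lo_candidates[i]
        return float(l_best), self.ppf(self.cdf(float(l_best)) + level)


def nnhm_bruteforce(
    y,
    v,
    family: str = "half_normal",
    scale: float = 0.5,
    n_mu: int = 2001,
    n_tau: int = 1501,
    tau_tail: float = 1e-7,
):
    """Brute-force 2-D trapezoid integration of the NNHM posterior.

    Returns gridded marginal densities of mu, tau and the predictive
    distribution of a new study effect.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    sd = np.sqrt(v)
    mu_lo = float(np.min(y - 8 * sd) - 2)
    mu_hi = float(np.max(y + 8 * sd) + 2)
    mu = np.linspace(mu_lo, mu_hi, n_mu)
    if family == "half_normal":
        from scipy.stats import halfnorm

        tau_max = float(halfnorm(scale=scale).ppf(1 - tau_tail))
    else:
        from scipy.stats import halfcauchy

        tau_max = float(halfcauchy(scale=scale).ppf(1 - 1e-4))
    tau = np.linspace(0.0, tau_max, n_tau)

    M, T = np.meshgrid(mu, tau, indexing="ij")
    log_joint = np.zeros_like(M)
    for yi, vi in zip(y, v):
        var = vi + T**2
        log_joint += -0.5 * np.log(2 * np.pi * var) - 0.5 * (yi - M) ** 2 / var
    log_joint += prior_logpdf(T, family, scale)
    log_joint -= log_joint.max()
    joint = np.exp(log_joint)

    mu_marginal = GriddedDensity(mu, np.trapezoid(joint, tau, axis=1))
    tau_marginal = GriddedDensity(tau, np.trapezoid(joint, mu, axis=0))

    # predictive: theta_new | tau ~ N(mu_hat(tau), s2(tau) + tau^2) mixed over
    # the brute-force tau marginal on its uniform grid
    w = 1.0 / (v[None, :] + tau[:, None] ** 2)
    sw = w.sum(axis=1)
    mu_hat = (w * y[None, :]).sum(axis=1) / sw
    pred_var = 1.0 / sw + tau**2
    theta = np.linspace(mu_lo - 3, mu_hi + 3, n_mu)
    dens_tau = tau_marginal.density
    comp = np.exp(
        -0.5 * (theta[:, None] - mu_hat[None, :]) ** 2 / pred_var[None, :]
    ) / np.sqrt(2 * np.pi * pred_var[None, :])
    pred_density = np.trapezoid(comp * dens_tau[None, :], tau, axis=1)
    predictive = GriddedDensity(theta, pred_density)
    return {"mu": mu_marginal, "tau": tau_marginal, "predictive": predictive}


def shrinkage_bruteforce(
    y,
    v,
    index: int,
    family: str = "half_normal",
    scale: float = 0.5,
    n_theta: int = 1501,
    n_tau: int = 1001,
):
    """Brute-force posterior of one study's true effect theta_i.

    Integrates mu out analytically by treating theta_i as an observation
    with variance tau^2 alongside the other studies with variances
    v_j + tau^2, then tabulates the joint over a (theta_i, tau) grid —
    a different decomposition from the package's shrinkage-factor mixture.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    others = np.arange(y.size) != index
    yo, vo = y[others], v[others]
    sd_i = np.sqrt(v[index])
    theta = np.linspace(
        min(np.min(y) - 8 * np.max(np.sqrt(v)), y[index] - 8 * sd_i) - 2,
        max(np.max(y) + 8 * np.max(np.sqrt(v)), y[index] + 8 * sd_i) + 2,
        n_theta,
    )
    from scipy.stats import halfnorm

    tau_max = float(halfnorm(scale=scale).ppf(1 - 1e-7)) if family == "half_normal" else 50 * scale
    tau = np.linspace(1e-9, tau_max, n_tau)

    TH, T = np.meshgrid(theta, tau, indexing="ij")
    # observation term for study i
    log_joint = -0.5 * np.log(2 * np.pi * v[index]) - 0.5 * (y[index] - TH) ** 2 / v[index]
    # integrate mu out of N(theta_i; mu, tau^2) * prod_j N(y_j; mu, v_j + tau^2)
    w_i = 1.0 / T**2
    sw = w_i.copy()
    swx = w_i * TH
    log_det = np.log(w_i)
    for yj, vj in zip(yo, vo):
        wj = 1.0 / (vj + T**2)
        sw += wj
        swx += wj * yj
        log_det += np.log(wj)
    xbar = swx / sw
    q = w_i * (TH - xbar) ** 2
    for yj, vj in zip(yo, vo):
        q += (yj - xbar) ** 2 / (vj + T**2)
    log_joint += 0.5 * log_det - 0.5 * np.log(sw) - 0.5 * q
    log_joint += prior_logpdf(T, family, scale)
    log_joint -= log_joint.max()
    joint = np.exp(log_joint)
    return GriddedDensity(theta, np.trapezoid(joint, tau, axis=1))
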
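"""Exact Gaussian-process regression engine for 1-D time series.

Squared-exponential kernel plus independent Gaussian noise; hyperparameters
(signal variance, lengthscale in hours, noise variance) are fit by maximizing
the exact log marginal likelihood with L-BFGS-B in log-space, from several
seeded random restarts.  The marginal likelihood is the quantity that feeds
the downstream BIC model comparison, so it is computed exactly (Cholesky)
with analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

JITTER = 1e-8

DEFAULT_BOUNDS = {
    "signal_variance": (1e-6, 1e3),
    "lengthscale": (0.5, 50.0),
    "noise_variance": (1e-6, 1e3),
}


@dataclass
class GpFit:
    signal_variance: float
    lengthscale: float
    noise_variance: float
    log_marginal_likelihood: float
    n_obs: int
    n_hyperparams: int = 3

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_marginal_likelihood):
            raise ValueError("log marginal likelihood must be finite")


def se_kernel(times_a, times_b, signal_variance: float, lengthscale: float) -> np.ndarray:
    ta = np.asarray(times_a, dtype=float)[:, None]
    tb = np.asarray(times_b, dtype=float)[None, :]
    return signal_variance * np.exp(-0.5 * (ta - tb) ** 2 / lengthscale ** 2)


def gp_log_marginal(times, values, signal_variance, lengthscale, noise_variance) -> float:
    """Exact GP log marginal likelihood for fixed hyperparameters."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    d2 = (t[:, None] - t[None, :]) ** 2
    lml, _ = _lml_and_grad(np.log([signal_variance, lengthscale, noise_variance]), d2, y)
    return lml


def _lml_and_grad(log_theta, d2, y):
    """Log marginal likelihood and gradient w.r.t. log hyperparameters."""
    sf2, ls, sn2 = np.exp(log_theta)
    n = y.shape[0]
    Kse = sf2 * np.exp(-0.5 * d2 / ls ** 2)
    K = Kse + (sn2 + JITTER * max(sf2, sn2)) * np.eye(n)
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(3)
    alpha = cho_solve((c, low), y)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    lml = -0.5 * (y @ alpha) - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
    # gradient: dL/dtheta = 0.5 tr((alpha alpha^T - K^-1) dK/dtheta)
    Kinv = cho_solve((c, low), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    dK_dlog_sf2 = Kse
    dK_dlog_ls = Kse * (d2 / ls ** 2)
    grad = np.array([
        0.5 * (W * dK_dlog_sf2).sum(),
        0.5 * (W * dK_dlog_ls).sum(),
        0.5 * np.trace(W) * sn2,
    ])
    return lml, grad


def fit_gp(times, values, restarts: int = 5, seed: int = 0,
           bounds: dict | None = None) -> GpFit:
    """Maximize the GP marginal likelihood over hyperparameters.

    Restarts draw initial points log-uniformly within the bounds (first
    restart is a moment-based initialization).  Constant input returns a
    degenerate noise-only fit with the signal variance at its lower bound.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if t.size < 3:
        raise ValueError("need at least 3 observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    lb = np.log([b["signal_variance"][0], b["lengthscale"][0], b["noise_variance"][0]])
    ub = np.log([b["signal_variance"][1], b["lengthscale"][1], b["noise_variance"][1]])

    var_y = float(y.var())
    if var_y == 0.0 or np.ptp(y) == 0.0:
        sn2 = max(var_y, b["noise_variance"][0])
        lml = float(-0.5 * np.sum((y - y.mean()) ** 2) / sn2
                    - 0.5 * t.size * np.log(2 * np.pi * sn2))
        # all-equal values: noise-only model at the variance floor
        return GpFit(signal_variance=b["signal_variance"][0],
                     lengthscale=float(np.exp(0.5 * (lb[1] + ub[1]))),
                     noise_variance=sn2, log_marginal_likelihood=lml, n_obs=t.size)

    d2 = (t[:, None] - t[None, :]) ** 2
    span = max(np.ptp(t), 1.0)

    def neg(lt):
        lml, g = _lml_and_grad(lt, d2, y)
        if not np.isfinite(lml):
            return 1e10, np.zeros(3)
        return -lml, -g

    rng = np.random.default_rng(seed)
    x0s = [np.clip(np.log([var_y, span / 4.0, var_y / 4.0]), lb, ub)]
    for _ in range(max(restarts - 1, 0)):
        x0s.append(lb + rng.uniform(size=3) * (ub - lb))

    best = None
    for x0 in x0s:
        res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B",
                                bounds=list(zip(lb, ub)), options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    lml, _ = _lml_and_grad(best.x, d2, y)
    if not np.isfinite(lml):
        raise FloatingPointError("GP optimization produced non-finite marginal likelihood")
    sf2, ls, sn2 = np.exp(best.x)
    return GpFit(signal_variance=float(sf2), lengthscale=float(ls),
                 noise_variance=float(sn2), log_marginal_likelihood=float(lml),
                 n_obs=t.size)
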
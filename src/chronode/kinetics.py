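"""Bayesian change-point analysis of module eigengene time series.

A piecewise-constant Gaussian level model with conjugate
normal-inverse-gamma segment priors: for m = 0, 1, 2 change points the
marginal likelihood is computed by exact enumeration over ordered
change-time configurations, giving (i) model evidence per m, (ii) a
model-averaged posterior probability of a regime change at each candidate
time, and (iii) a MAP change configuration.  Modules are then classified
into the kinetic taxonomy: early / intermediate / late onset, up / down
direction, transitory or sustained.

Priors are scaled to the series' own mean and variance, which makes the
posterior over change configurations exactly invariant to adding a constant
to the series and to positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy.special import logsumexp

DEFAULT_TIME_BINS = {"early": (0.0, 2.0), "intermediate": (2.0, 6.0), "late": (10.0, 13.0)}


@dataclass
class NigPrior:
    """Normal-inverse-gamma prior for one segment's (mean, variance)."""
    mu0: float
    kappa0: float = 0.2
    alpha0: float = 1.0
    beta0: float = 1.0


def segment_log_marginal(y: np.ndarray, prior: NigPrior) -> float:
    """Closed-form marginal likelihood of a Gaussian segment under the NIG prior."""
    y = np.asarray(y, float)
    n = y.size
    if n == 0:
        return 0.0
    ybar = y.mean()
    ss = ((y - ybar) ** 2).sum()
    kn = prior.kappa0 + n
    an = prior.alpha0 + n / 2.0
    bn = (prior.beta0 + 0.5 * ss
          + prior.kappa0 * n * (ybar - prior.mu0) ** 2 / (2.0 * kn))
    return (-0.5 * n * np.log(2.0 * np.pi)
            + 0.5 * (np.log(prior.kappa0) - np.log(kn))
            + prior.alpha0 * np.log(prior.beta0) - an * np.log(bn)
            + lgamma(an) - lgamma(prior.alpha0))


@dataclass
class ChangePointPosterior:
    times: np.ndarray
    change_prob: np.ndarray            # model-averaged P(regime change just before times[i])
    map_changes: tuple                 # MAP change times (midpoint convention)
    map_change_indices: tuple          # index of the first point of each new regime
    log_evidence: dict                 # m -> log marginal likelihood
    model_posterior: dict              # m -> posterior probability (uniform model prior)
    config_posteriors: dict = field(default_factory=dict)  # m -> {config: prob}

    @property
    def map_n_changes(self) -> int:
        return max(self.model_posterior, key=self.model_posterior.get)


def _default_prior(y: np.ndarray) -> NigPrior:
    var = float(np.var(y))
    return NigPrior(mu0=float(np.mean(y)), kappa0=0.2, alpha0=1.0,
                    beta0=max(var, 1e-12))


def changepoint_posterior(times, values, max_changes: int = 2,
                          prior: NigPrior | None = None) -> ChangePointPosterior:
    """Exact enumeration of piecewise-constant change-point configurations.

    A configuration for m changes is an ordered tuple of indices
    (c_1 < ... < c_m), each marking the first point of a new segment.
    Within each model, configurations carry a uniform prior; models get a
    uniform prior over the m values that the series length supports.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    n = t.size
    p = prior or _default_prior(y)

    # prefix stats for O(1) segment marginals
    def seg(i, j):  # y[i:j]
        return segment_log_marginal(y[i:j], p)

    log_evidence: dict = {}
    config_logliks: dict = {}
    for m in range(max_changes + 1):
        if n < m + 1:  # each segment needs >= 1 point
            continue
        if m == 0:
            configs = [()]
        elif m == 1:
            configs = [(c,) for c in range(1, n)]
        else:
            configs = [(c1, c2) for c1 in range(1, n - 1) for c2 in range(c1 + 1, n)]
        lls = []
        for cfg in configs:
            bounds = (0,) + cfg + (n,)
            ll = sum(seg(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
            lls.append(ll)
        lls = np.asarray(lls)
        log_evidence[m] = float(logsumexp(lls) - np.log(len(configs)))
        config_logliks[m] = (configs, lls)

    models = sorted(log_evidence)
    le = np.array([log_evidence[m] for m in models])
    model_post = dict(zip(models, np.exp(le - logsumexp(le))))

    change_prob = np.zeros(n)
    config_posteriors: dict = {}
    for m in models:
        configs, lls = config_logliks[m]
        post = np.exp(lls - logsumexp(lls))
        config_posteriors[m] = dict(zip(configs, post))
        if m == 0:
            continue
        for cfg, pr in zip(configs, post):
            for c in cfg:
                change_prob[c] += model_post[m] * pr

    m_map = max(model_post, key=model_post.get)
    if m_map == 0:
        map_changes: tuple = ()
        best: tuple = ()
    else:
        configs, lls = config_logliks[m_map]
        best = configs[int(np.argmax(lls))]
        # a change between consecutive observations is located between them
        map_changes = tuple(0.5 * float(t[c - 1] + t[c]) for c in best)
    return ChangePointPosterior(times=t, change_prob=change_prob,
                                map_changes=map_changes,
                                map_change_indices=tuple(best),
                                log_evidence=log_evidence,
                                model_posterior=model_post,
                                config_posteriors=config_posteriors)


@dataclass
class KineticClass:
    module: int | str
    timing: str                 # early / intermediate / late / unclassified
    direction: str              # up / down / none
    transitory: bool
    onset_h: float | None
    second_change_support: float = 0.0


def _segment_means(y: np.ndarray, cfg: tuple) -> list[float]:
    bounds = (0,) + cfg + (len(y),)
    return [float(np.mean(y[bounds[i]:bounds[i + 1]])) for i in range(len(bounds) - 1)]


def classify_module(times, values, posterior: ChangePointPosterior,
                    time_bins: dict = DEFAULT_TIME_BINS,
                    transitory_support: float = 0.5,
                    module="") -> KineticClass:
    """Map a change-point posterior onto the kinetic taxonomy.

    Timing comes from the bin containing the MAP onset change; direction is
    the sign of the post-onset minus pre-onset mean level; a module is
    transitory when a second, opposite-signed change carries posterior
    support of at least ``transitory_support``.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if posterior.map_n_changes == 0 or not posterior.map_changes:
        return KineticClass(module=module, timing="unclassified", direction="none",
                            transitory=False, onset_h=None)
    onset = posterior.map_changes[0]
    timing = "unclassified"
    for name, (lo, hi) in time_bins.items():
        if (lo <= onset <= hi) if name != "early" else (onset < hi):
            timing = name
            break

    cfg = tuple(posterior.map_change_indices)
    means = _segment_means(y, cfg)
    direction = "up" if means[1] - means[0] > 0 else "down"

    # posterior support for a second change whose sign opposes the first
    support = 0.0
    for m, cfg_post in posterior.config_posteriors.items():
        if m < 2:
            continue
        for config, pr in cfg_post.items():
            mm = _segment_means(y, config)
            d1 = mm[1] - mm[0]
            d2 = mm[2] - mm[1]
            if d1 * d2 < 0:
                support += posterior.model_posterior[m] * pr
    return KineticClass(module=module, timing=timing, direction=direction,
                        transitory=support >= transitory_support,
                        onset_h=float(onset), second_change_support=float(support))
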
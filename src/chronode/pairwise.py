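"""Two-sample negative-binomial exact test without replicates.

For single-library contrasts (e.g. inhibitor vs vehicle at one time point)
no dispersion can be estimated, so a fixed biological coefficient of
variation (BCV) is assumed: dispersion phi = BCV^2, default BCV 0.2.
Libraries are first rescaled to the geometric mean of their sizes; the test
then conditions on the per-gene sum s = y_A + y_B and enumerates
P(Y_A = a, Y_B = s - a) for all a, with Y ~ NB(mean s/2, dispersion phi).
The two-sided p-value is the total conditional probability of configurations
no more likely than the observed one.  Calls require both
|log2 fold change| >= 1 and p <= 0.01 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

EXACT_LIMIT = 10 ** 6  # above this sum, switch to a continuity-corrected normal


def normalize_pair(counts_a, counts_b) -> tuple[np.ndarray, np.ndarray, float]:
    """Rescale two libraries to the geometric mean of their totals.

    Returns the rounded (half-to-even) scaled counts and the common
    effective library size.  Equal library sizes are an identity.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    na, nb = a.sum(), b.sum()
    if na == 0 or nb == 0:
        raise ValueError("zero-total library: cannot normalize")
    eff = float(np.sqrt(na * nb))
    a_s = np.round(a * (eff / na))
    b_s = np.round(b * (eff / nb))
    return a_s.astype(np.int64), b_s.astype(np.int64), eff


def nb_exact_test(y_a: int, y_b: int, bcv: float = 0.2) -> float:
    """Exact two-sided p-value for one gene at fixed dispersion bcv^2."""
    a, b = int(y_a), int(y_b)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    s = a + b
    if s == 0:
        return 1.0
    phi = bcv * bcv
    mu = s / 2.0
    if s > EXACT_LIMIT:
        sigma = np.sqrt((mu + phi * mu * mu) / 2.0)
        z = (abs(a - mu) - 0.5) / sigma
        return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
    i = np.arange(s + 1)
    if phi > 0:
        r = 1.0 / phi
        logpmf = stats.nbinom.logpmf(i, r, r / (r + mu))
    else:
        logpmf = stats.poisson.logpmf(i, mu)
    log_cfg = logpmf + logpmf[::-1]
    norm = logsumexp(log_cfg)
    obs = log_cfg[a]
    keep = log_cfg <= obs + 1e-9  # tie tolerance
    p = float(np.exp(logsumexp(log_cfg[keep]) - norm))
    return min(p, 1.0)


@dataclass
class PairwiseDeResult:
    gene: str
    count_a: int
    count_b: int
    log2_fc: float
    p_value: float
    called: bool
    approximate: bool = False


def pairwise_de(counts_a, counts_b, genes=None, bcv: float = 0.2,
                lfc_min: float = 1.0, p_max: float = 0.01,
                prior_count: float = 0.5) -> pd.DataFrame:
    """Full no-replicate contrast: normalize, test, and call every gene.

    log2 fold change is (count_a + prior)/(count_b + prior) on the
    library-size-equalized scale: condition A over condition B.
    """
    a_s, b_s, eff = normalize_pair(counts_a, counts_b)
    if genes is None:
        genes = [f"g{i}" for i in range(len(a_s))]
    rows = []
    for g, a, b in zip(genes, a_s, b_s):
        p = nb_exact_test(a, b, bcv=bcv)
        lfc = float(np.log2((a + prior_count) / (b + prior_count)))
        rows.append({"gene": g, "count_a": int(a), "count_b": int(b),
                     "log2_fc": lfc, "p_value": p,
                     "called": bool(abs(lfc) >= lfc_min and p <= p_max),
                     "approximate": bool(a + b > EXACT_LIMIT)})
    return pd.DataFrame(rows).set_index("gene")


def call_pairwise(results: pd.DataFrame, lfc_min: float = 1.0,
                  p_max: float = 0.01) -> list:
    """Re-apply (inclusive) thresholds to an existing result table."""
    if results.empty:
        return []
    called = (results["log2_fc"].abs() >= lfc_min) & (results["p_value"] <= p_max)
    return list(results.index[called])
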
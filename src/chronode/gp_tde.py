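"""Gaussian-process temporal differential expression with BIC model selection.

For each gene and condition pair, two hypotheses are compared: a single GP
fit to the pooled observations of both conditions (no differential
expression) versus two independent GPs, one per condition.  The log marginal
likelihoods are penalized with BIC = k*ln(N) - 2*logML, where N is the total
number of observations in both conditions under either hypothesis, and the
reported score is BIC_shared - BIC_separate: positive scores favor
condition-specific trajectories, and a score >= 10 is conventionally very
strong evidence.  Genes are finally called when the score reaches the
threshold against both the uninjured and the sham control (intersection
rule), and the pair of scores is summarized as a 2-D histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gp import fit_gp, GpFit

K_SHARED = 3
K_SEPARATE = 6


@dataclass
class GpDeResult:
    gene: str
    condition_pair: tuple
    logml_shared: float
    logml_separate: float
    n_obs: int
    score: float
    flags: tuple = ()

    @property
    def separate_preferred(self) -> bool:
        return self.score > 0


def bic(k: int, n: int, logml: float) -> float:
    return k * np.log(n) - 2.0 * logml


def de_score(times_a, values_a, times_b, values_b, gene: str = "",
             condition_pair: tuple = ("A", "B"), restarts: int = 5,
             seed: int = 0) -> GpDeResult:
    """BIC difference between the shared-trajectory and separate models.

    Both fits see the observations on a common standardized scale (pooled
    mean/SD) so their marginal likelihoods are comparable.  Symmetric in the
    two conditions by construction.
    """
    ta = np.asarray(times_a, float)
    tb = np.asarray(times_b, float)
    ya = np.asarray(values_a, float)
    yb = np.asarray(values_b, float)
    if ta.size < 3 or tb.size < 3:
        raise ValueError("each condition needs at least 3 observations")
    pooled = np.concatenate([ya, yb])
    m, s = pooled.mean(), pooled.std()
    if s == 0:
        s = 1.0
    ya_s, yb_s = (ya - m) / s, (yb - m) / s
    n_total = ta.size + tb.size

    flags = []
    if ta.min() > tb.max() or tb.min() > ta.max():
        flags.append("non_overlapping_time_support")

    try:
        shared = fit_gp(np.concatenate([ta, tb]), np.concatenate([ya_s, yb_s]),
                        restarts=restarts, seed=seed)
        fit_a = fit_gp(ta, ya_s, restarts=restarts, seed=seed + 1)
        fit_b = fit_gp(tb, yb_s, restarts=restarts, seed=seed + 2)
    except FloatingPointError:
        return GpDeResult(gene=gene, condition_pair=tuple(condition_pair),
                          logml_shared=np.nan, logml_separate=np.nan,
                          n_obs=n_total, score=np.nan, flags=("degenerate_fit",))

    logml_sep = fit_a.log_marginal_likelihood + fit_b.log_marginal_likelihood
    score = (bic(K_SHARED, n_total, shared.log_marginal_likelihood)
             - bic(K_SEPARATE, n_total, logml_sep))
    return GpDeResult(gene=gene, condition_pair=tuple(condition_pair),
                      logml_shared=shared.log_marginal_likelihood,
                      logml_separate=logml_sep, n_obs=n_total,
                      score=float(score), flags=tuple(flags))


def score_genes(matrix: pd.DataFrame, meta: pd.DataFrame, condition_a: str,
                condition_b: str, restarts: int = 5, seed: int = 0,
                genes=None) -> pd.DataFrame:
    """Score every gene of a normalized matrix for one condition pair.

    Returns a DataFrame indexed by gene with columns score, logml_shared,
    logml_separate, n_obs, flags.  Genes whose optimization degenerates get
    a NaN score and a flag, never a silent zero.
    """
    meta = meta.loc[matrix.columns]
    mask_a = (meta["condition"] == condition_a).to_numpy()
    mask_b = (meta["condition"] == condition_b).to_numpy()
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("each condition needs at least 3 samples")
    times_a = meta.loc[mask_a, "time_hpt"].to_numpy(float)
    times_b = meta.loc[mask_b, "time_hpt"].to_numpy(float)
    gene_list = list(matrix.index if genes is None else genes)
    rows = []
    vals = matrix.to_numpy()
    gene_pos = {g: i for i, g in enumerate(matrix.index)}
    for j, g in enumerate(gene_list):
        v = vals[gene_pos[g]]
        res = de_score(times_a, v[mask_a], times_b, v[mask_b], gene=g,
                       condition_pair=(condition_a, condition_b),
                       restarts=restarts, seed=seed + 7 * j)
        rows.append((g, res.score, res.logml_shared, res.logml_separate,
                     res.n_obs, ";".join(res.flags)))
    return pd.DataFrame(rows, columns=["gene", "score", "logml_shared",
                                       "logml_separate", "n_obs", "flags"]).set_index("gene")


@dataclass
class DeCallSet:
    table: pd.DataFrame          # gene x [score_vs_uninjured, score_vs_sham, called]
    threshold: float
    hist: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    hist_edges: tuple = ()
    dropped: tuple = ()

    @property
    def called(self) -> list:
        return list(self.table.index[self.table["called"]])


def call_de(results_vs_uninjured: pd.DataFrame, results_vs_sham: pd.DataFrame,
            threshold: float = 10.0, hist_bins: int = 40) -> DeCallSet:
    """Intersection call: both scores must reach the threshold (inclusive).

    Genes present in only one comparison, or with a non-finite score in
    either, are excluded from calling and listed in ``dropped``.  The 2-D
    histogram bins (score_vs_sham, score_vs_uninjured) pairs.
    """
    u = results_vs_uninjured["score"]
    s = results_vs_sham["score"]
    common = u.index.intersection(s.index)
    dropped = sorted(set(u.index).symmetric_difference(s.index))
    tab = pd.DataFrame({"score_vs_uninjured": u.loc[common],
                        "score_vs_sham": s.loc[common]})
    finite = np.isfinite(tab["score_vs_uninjured"]) & np.isfinite(tab["score_vs_sham"])
    dropped += sorted(tab.index[~finite])
    tab = tab.loc[finite]
    tab["called"] = (tab["score_vs_uninjured"] >= threshold) & (tab["score_vs_sham"] >= threshold)

    if len(tab):
        hist, xe, ye = np.histogram2d(tab["score_vs_sham"], tab["score_vs_uninjured"],
                                      bins=hist_bins)
        edges = (xe, ye)
    else:
        hist, edges = np.zeros((0, 0)), ()
    return DeCallSet(table=tab, threshold=threshold, hist=hist, hist_edges=edges,
                     dropped=tuple(dropped))


def write_hist(callset: DeCallSet, path) -> None:
    """Write the 2-D score histogram as a TSV of bin counts."""
    if callset.hist.size == 0:
        pd.DataFrame().to_csv(path, sep="\t")
        return
    xe, ye = callset.hist_edges
    df = pd.DataFrame(callset.hist,
                      index=[f"{a:.3f}" for a in xe[:-1]],
                      columns=[f"{a:.3f}" for a in ye[:-1]])
    df.to_csv(path, sep="\t", index_label="score_vs_sham_bin")
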
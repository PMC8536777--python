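"""Weighted co-expression network construction and module detection.

Biweight midcorrelation similarity, signed-hybrid soft-threshold adjacency
(cor^beta for positive correlations, 0 otherwise) with the power chosen by
scale-free topology fit, topological overlap, average-linkage hierarchical
clustering with a simplified dynamic branch cut, and module eigengenes with
per-gene module membership (kME).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

DEFAULT_POWERS = tuple(range(1, 21))


def _bicor_weights(x: np.ndarray, c: float = 9.0, max_p_outliers: float = 0.1):
    """Robust standardized deviations for biweight midcorrelation.

    Returns the weighted, centered vector x_tilde such that
    bicor(x, y) = <x_tilde, y_tilde> / (||x_tilde|| ||y_tilde||), or None if
    MAD is zero (Pearson fallback applies).

    ``max_p_outliers`` caps the fraction of points per side that can be
    zero-weighted as outliers: when a side's u-quantile at that fraction
    exceeds 1 in magnitude, u is rescaled on that side so only the capped
    fraction is excluded.  Without the cap, bimodal profiles (e.g. a step
    between two expression regimes) would have most of one regime treated
    as outliers because MAD collapses onto the majority level.
    """
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (c * mad)
    if 0 < max_p_outliers < 1:
        lo = np.quantile(u, max_p_outliers)
        hi = np.quantile(u, 1.0 - max_p_outliers)
        if lo < -1.0:
            u = np.where(u < 0, u / abs(lo), u)
        if hi > 1.0:
            u = np.where(u > 0, u / hi, u)
    w = (1.0 - u ** 2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation of two vectors (Pearson fallback on MAD=0)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xt = _bicor_weights(x, c)
    yt = _bicor_weights(y, c)
    if xt is None:
        xt = x - x.mean()
    if yt is None:
        yt = y - y.mean()
    nx, ny = np.linalg.norm(xt), np.linalg.norm(yt)
    if nx == 0 or ny == 0:
        return 0.0
    return float(np.clip(xt @ yt / (nx * ny), -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    genes: list
    method: str = "bicor"
    fallback_genes: tuple = ()  # zero-MAD genes handled by Pearson


def bicor_matrix(expr: pd.DataFrame, c: float = 9.0) -> CorrelationMatrix:
    """All-pairs biweight midcorrelation of a genes x samples matrix."""
    X = expr.to_numpy(float)
    if X.shape[1] < 4:
        raise ValueError("need at least 4 samples for a robust correlation")
    n = X.shape[0]
    tilde = np.empty_like(X)
    fallback = []
    for i in range(n):
        t = _bicor_weights(X[i], c)
        if t is None:
            t = X[i] - X[i].mean()
            fallback.append(expr.index[i])
        tilde[i] = t
    norms = np.linalg.norm(tilde, axis=1)
    zero = norms == 0
    norms[zero] = 1.0
    tilde /= norms[:, None]
    R = np.clip(tilde @ tilde.T, -1.0, 1.0)
    R[zero, :] = 0.0  # constant genes: correlation undefined, recorded as 0
    R[:, zero] = 0.0
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(values=R, genes=list(expr.index),
                             fallback_genes=tuple(fallback))


def signed_hybrid_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """adjacency = cor^beta where cor > 0, else 0; unit diagonal."""
    adj = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution regression.

    Bins log10(k), regresses log10 p(k) on mean log10 k per bin; the sign of
    the slope is folded into R^2 (scale-free topology requires a negative
    slope).  Returns (signed R^2, slope).
    """
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if k.size < 10:
        return -1.0, 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    which = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() > 0:
            xs.append(logk[m].mean())
            ys.append(np.log10(m.sum() / k.size))
    if len(xs) < 3:
        return -1.0, 0.0
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_res = (resid ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(cor: CorrelationMatrix, powers=DEFAULT_POWERS,
                        r2_cut: float = 0.8) -> tuple[float, pd.DataFrame]:
    """Choose the soft-threshold power by scale-free topology fit.

    Smallest candidate power whose signed R^2 reaches ``r2_cut``; if none
    does, the R^2-maximizing power.  Returns the power and the full table.
    """
    R = cor.values
    if R.shape[0] < 50:
        raise ValueError("need at least 50 genes for a meaningful degree distribution")
    off = ~np.eye(R.shape[0], dtype=bool)
    if not (R[off] > 0).any():
        raise ValueError("all correlations non-positive: no network to threshold")
    rows = []
    for p in powers:
        adj = signed_hybrid_adjacency(R, p)
        k = adj.sum(axis=0) - 1.0  # exclude self
        r2, slope = scale_free_fit(k)
        rows.append((p, r2, slope, float(k.mean()), float(np.median(k)), float(k.max())))
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "slope",
                                        "mean_k", "median_k", "max_k"])
    ok = table[table["signed_r2"] >= r2_cut]
    beta = float(ok["power"].iloc[0]) if len(ok) else float(table.loc[table["signed_r2"].idxmax(), "power"])
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap:
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), diag 1."""
    A = np.asarray(adjacency, float)
    if not np.allclose(A, A.T):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    L = A @ A
    kmin = np.minimum(k[:, None], k[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(tom_dissim: np.ndarray, min_module_size: int = 30,
                   scatter_frac: float = 0.97, assign_close: bool = True) -> np.ndarray:
    """Average-linkage clustering with a simplified dynamic branch cut.

    The dendrogram is decomposed recursively: a branch becomes a module
    when it has at least ``min_module_size`` leaves and its mean internal
    dissimilarity is below ``scatter_frac`` times the matrix-wide median
    off-diagonal dissimilarity — the core-scatter criterion, which rejects
    diffuse branches of unstructured genes whose internal dissimilarities
    hug the background (for unstructured genes the topological overlap is
    near zero, so their dissimilarities pile up just under 1).  Recursion
    prefers the finest decomposition, so nested tight branches split into
    separate modules.  With ``assign_close``, leftover genes closer (on
    average) to a module than the scatter threshold are attached to the
    nearest module, a simplified analogue of the hybrid cut's assignment
    stage.  Labels are renumbered by decreasing module size; 0 means
    unassigned.
    """
    D = np.asarray(tom_dissim, float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if n < min_module_size:
        return np.zeros(n, dtype=int)
    Ds = 0.5 * (D + D.T)
    np.fill_diagonal(Ds, 0.0)
    Z = hierarchy.linkage(squareform(Ds, checks=False), method="average")
    root = hierarchy.to_tree(Z)

    offdiag = Ds[np.triu_indices(n, 1)]
    scatter_cut = scatter_frac * np.median(offdiag)

    def leaves(node):
        return node.pre_order(lambda leaf: leaf.id)

    def scatter(idx):
        if len(idx) < 2:
            return 0.0
        sub = Ds[np.ix_(idx, idx)]
        return sub.sum() / (len(idx) * (len(idx) - 1))

    def is_candidate(node):
        if node.count < min_module_size:
            return False
        return scatter(leaves(node)) <= scatter_cut

    def decompose(node):
        if node.count < min_module_size:
            return []
        subs = []
        if not node.is_leaf():
            subs = decompose(node.left) + decompose(node.right)
        if subs:
            return subs
        if is_candidate(node):
            return [node]
        return []

    module_nodes = decompose(root)
    labels = np.zeros(n, dtype=int)
    found = sorted(((leaves(nd)) for nd in module_nodes), key=len, reverse=True)
    for lab, idx in enumerate(found, start=1):
        labels[idx] = lab

    if assign_close and found:
        unassigned = np.where(labels == 0)[0]
        centers = {lab: idx for lab, idx in enumerate(found, start=1)}
        for g in unassigned:
            dists = {lab: Ds[g, idx].mean() for lab, idx in centers.items()}
            best = min(dists, key=dists.get)
            if dists[best] <= scatter_cut:
                labels[g] = best

    # renumber by decreasing final size
    sizes = [(int((labels == lab).sum()), lab) for lab in np.unique(labels) if lab > 0]
    sizes.sort(key=lambda t: (-t[0], t[1]))
    remap = {old: new for new, (_, old) in enumerate(sizes, start=1)}
    return np.array([remap.get(l, 0) for l in labels], dtype=int)


@dataclass
class ModuleSet:
    labels: pd.Series                  # gene -> module (0 unassigned)
    eigengenes: pd.DataFrame           # module x sample, unit-norm rows
    kme: pd.Series                     # gene -> membership in own module
    explained_variance: dict = field(default_factory=dict)
    time_correlation: dict = field(default_factory=dict)

    def module_genes(self, module: int) -> list:
        return list(self.labels.index[self.labels == module])


def module_eigengene(expr: pd.DataFrame, labels, times=None) -> ModuleSet:
    """Eigengenes and module membership for a labelled expression matrix.

    The eigengene is the first right-singular vector of the per-gene
    standardized module submatrix, sign-oriented to correlate positively
    with the module's average standardized profile.  kME is the biweight
    midcorrelation of each gene with its own module's eigengene.
    """
    labels = pd.Series(np.asarray(labels, int), index=expr.index, name="module")
    modules = sorted(set(labels) - {0})
    if not modules:
        raise ValueError("no non-zero module to summarize")
    X = expr.to_numpy(float)
    sd = X.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    eig_rows, expl, tcorr = {}, {}, {}
    for m in modules:
        idx = np.where(labels.to_numpy() == m)[0]
        sub = Xs[idx]
        if idx.size == 1:
            v = sub[0] / np.linalg.norm(sub[0])
            expl[m] = 1.0
        else:
            u, s, vt = np.linalg.svd(sub, full_matrices=False)
            v = vt[0]
            expl[m] = float(s[0] ** 2 / (s ** 2).sum())
        if np.corrcoef(v, sub.mean(axis=0))[0, 1] < 0:
            v = -v
        eig_rows[m] = v
        if times is not None:
            tcorr[m] = float(np.corrcoef(v, np.asarray(times, float))[0, 1])
    eig = pd.DataFrame.from_dict(eig_rows, orient="index", columns=expr.columns)
    eig.index.name = "module"

    kme = pd.Series(np.nan, index=expr.index, name="kme")
    for m in modules:
        genes = labels.index[labels == m]
        e = eig.loc[m].to_numpy()
        kme.loc[genes] = [bicor(expr.loc[g].to_numpy(), e) for g in genes]
    return ModuleSet(labels=labels, eigengenes=eig, kme=kme,
                     explained_variance=expl, time_correlation=tcorr)


def build_network(expr: pd.DataFrame, beta: float | None = None,
                  min_module_size: int = 30, powers=DEFAULT_POWERS,
                  times=None) -> tuple[ModuleSet, dict]:
    """End-to-end: bicor -> soft threshold -> TOM -> modules -> eigengenes.

    ``beta=None`` selects the power by scale-free fit.  Returns the module
    set and a dict of intermediate artifacts (correlation, beta, R^2 table,
    TOM) for export.
    """
    cor = bicor_matrix(expr)
    if beta is None:
        beta, table = pick_soft_threshold(cor, powers=powers)
    else:
        table = None
    adj = signed_hybrid_adjacency(cor.values, beta)
    tom = tom_similarity(adj)
    labels = detect_modules(1.0 - tom, min_module_size=min_module_size)
    if (labels > 0).any():
        modules = module_eigengene(expr, labels, times=times)
    else:
        modules = ModuleSet(labels=pd.Series(labels, index=expr.index, name="module"),
                            eigengenes=pd.DataFrame(columns=expr.columns),
                            kme=pd.Series(np.nan, index=expr.index, name="kme"))
    artifacts = {"correlation": cor, "beta": beta, "power_table": table, "tom": tom}
    return modules, artifacts
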
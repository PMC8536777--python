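"""Count-matrix I/O, low-count filtering, VST normalization and consistency QC.

The container mirrors a bulk time-series design: a gene x sample integer
count matrix plus per-sample metadata (condition, sampling series, hours
post-treatment, batch).  Filtering keeps genes detected at a minimum count in
a minimum number of distinct time points within at least one condition; VST
is the closed-form negative-binomial variance-stabilizing transform with
median-of-ratios size factors and a parametric mean-dispersion trend.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

META_COLUMNS = ["sample_id", "condition", "series", "time_hpt", "batch"]


@dataclass
class TimeSeriesCounts:
    """Gene x sample integer counts with per-sample time-course metadata.

    ``meta`` is indexed by sample id with columns condition, series,
    time_hpt and batch; columns of ``counts`` must equal ``meta.index``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicated gene ids: {dup[:5]}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicated sample ids: {dup[:5]}")
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        for col in ("condition", "series", "time_hpt", "batch"):
            if col not in self.meta.columns:
                raise ValueError(f"sample sheet lacks required column {col!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        name = self.meta.index.name or "sample_id"
        self.meta = self.meta.loc[self.counts.columns]
        self.meta.index.name = name

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """Normalized expression on a log-like scale, with provenance."""

    values: pd.DataFrame
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("normalized values must be finite")


@dataclass
class ConsistencyReport:
    neighbor_rho: list[float]
    overlap_rho: list[float]
    replicate_rho: list[float]

    def summary(self) -> dict:
        out = {}
        for name in ("neighbor_rho", "overlap_rho", "replicate_rho"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size:
                out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                             "n_pairs": int(vals.size)}
            else:
                out[name] = {"mean": None, "sd": None, "n_pairs": 0}
        return out

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def read_counts(counts_path, samplesheet_path) -> TimeSeriesCounts:
    """Read a TSV count matrix (genes as rows) and its sample sheet."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samplesheet_path, sep="\t")
    missing_cols = [c for c in META_COLUMNS if c not in sheet.columns]
    if missing_cols:
        raise ValueError(f"sample sheet missing columns: {missing_cols}")
    meta = sheet.set_index("sample_id")
    if meta.index.duplicated().any():
        raise ValueError("duplicated sample ids in sample sheet")
    return TimeSeriesCounts(counts=counts, meta=meta)


def read_counts_mtx(mtx_path, genes_path, samples_path,
                    samplesheet_path) -> TimeSeriesCounts:
    """Read counts from MatrixMarket (genes x samples) with row/column files."""
    from scipy.io import mmread
    mat = mmread(mtx_path)
    genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
    samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
    counts = pd.DataFrame(np.asarray(mat.todense() if hasattr(mat, "todense") else mat),
                          index=genes, columns=samples)
    sheet = pd.read_csv(samplesheet_path, sep="\t")
    meta = sheet.set_index("sample_id")
    return TimeSeriesCounts(counts=counts, meta=meta)


def write_counts(data: TimeSeriesCounts, counts_path, samplesheet_path) -> None:
    data.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    sheet = data.meta.reset_index()
    sheet = sheet.rename(columns={sheet.columns[0]: "sample_id"})
    sheet[META_COLUMNS].to_csv(samplesheet_path, sep="\t", index=False)


def filter_low_counts(data: TimeSeriesCounts, min_count: int = 5,
                      min_timepoints: int = 4) -> TimeSeriesCounts:
    """Keep genes with >= min_count counts at >= min_timepoints distinct time
    points within at least one condition.

    A time point with replicates counts once if any replicate reaches
    ``min_count``.  Gene order is preserved; the filter is idempotent.
    """
    keep = np.zeros(len(data.counts), dtype=bool)
    for _, samples in data.meta.groupby("condition").groups.items():
        sub = data.counts[list(samples)]
        times = data.meta.loc[list(samples), "time_hpt"]
        detected = (sub >= min_count).T.groupby(times.values).any()  # time x gene
        keep |= (detected.sum(axis=0) >= min_timepoints).to_numpy()
    return TimeSeriesCounts(counts=data.counts.loc[keep].copy(), meta=data.meta.copy())


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes expressed in every sample."""
    if (counts.sum(axis=0) == 0).any():
        bad = np.where(counts.sum(axis=0) == 0)[0]
        raise ValueError(f"samples with all-zero counts (size factor undefined): {bad.tolist()}")
    with np.errstate(divide="ignore"):
        logc = np.log(counts.astype(float))
    log_geo = logc.mean(axis=1)
    use = np.isfinite(log_geo)
    if not use.any():
        raise ValueError("no gene expressed in every sample; cannot compute size factors")
    sf = np.exp(np.median(logc[use] - log_geo[use, None], axis=0))
    return sf


def _dispersion_trend(q: np.ndarray) -> tuple[float, float]:
    """Fit the parametric trend alpha(mu) = a1/mu + a0 by moments.

    ``q`` is the size-factor-normalized count matrix.  Gene-wise dispersions
    come from the NB identity var = mu + alpha*mu^2; the trend is fit by
    least squares on genes with informative means.
    """
    mu = q.mean(axis=1)
    var = q.var(axis=1, ddof=1)
    ok = mu > 0.5
    if ok.sum() < 10:
        return 0.1, 1.0
    alpha = (var[ok] - mu[ok]) / mu[ok] ** 2
    alpha = np.clip(alpha, 1e-8, 10.0)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha, rcond=None)
    a0 = float(max(coef[0], 1e-8))
    a1 = float(max(coef[1], 0.0))
    return a0, a1


def vst_closed_form(q: np.ndarray, a0: float, a1: float) -> np.ndarray:
    """Closed-form VST for NB counts under the trend alpha(mu)=a1/mu+a0.

    Monotone in q; asymptotically log2 for large counts.
    """
    q = np.asarray(q, dtype=float)
    return np.log2((1.0 + a1 + 2.0 * a0 * q +
                    2.0 * np.sqrt(a0 * q * (1.0 + a1 + a0 * q))) / (4.0 * a0))


def vst_normalize(data: TimeSeriesCounts) -> NormalizedMatrix:
    """Variance-stabilizing transform of the count matrix.

    Median-of-ratios size factors, method-of-moments parametric
    dispersion-mean trend, then the closed-form NB transform per entry.
    """
    counts = data.counts.to_numpy()
    if counts.shape[1] < 2:
        raise ValueError("VST requires at least two samples")
    sf = _size_factors(counts)
    q = counts / sf[None, :]
    a0, a1 = _dispersion_trend(q)
    vals = vst_closed_form(q, a0, a1)
    out = pd.DataFrame(vals, index=data.counts.index, columns=data.counts.columns)
    return NormalizedMatrix(values=out, method="vst",
                            params={"size_factors": sf.tolist(), "a0": a0, "a1": a1})


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_consistency(matrix: NormalizedMatrix, meta: pd.DataFrame) -> ConsistencyReport:
    """Spearman-rho QC over three pair classes.

    (i) consecutive time points within each series, (ii) samples sharing a
    (condition, time) across different series (overlap points), and
    (iii) replicates: samples sharing (condition, series, time).
    """
    meta = meta.loc[matrix.values.columns]
    vals = matrix.values

    neighbor, overlap, replicate = [], [], []
    for (_, _), group in meta.groupby(["condition", "series"], sort=True):
        g = group.sort_values("time_hpt")
        ordered = list(g.index)
        times = g["time_hpt"].to_numpy()
        for i in range(len(ordered) - 1):
            rho = _spearman(vals[ordered[i]].to_numpy(), vals[ordered[i + 1]].to_numpy())
            if times[i + 1] == times[i]:
                replicate.append(rho)
            else:
                neighbor.append(rho)
    for (_, _), group in meta.groupby(["condition", "time_hpt"], sort=True):
        idx = list(group.index)
        series = group["series"].to_numpy()
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                if series[i] != series[j]:
                    overlap.append(_spearman(vals[idx[i]].to_numpy(), vals[idx[j]].to_numpy()))
    return ConsistencyReport(neighbor_rho=neighbor, overlap_rho=overlap, replicate_rho=replicate)
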
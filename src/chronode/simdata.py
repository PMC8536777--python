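"""Synthetic multi-condition time-course RNA-seq counts with known truth.

The generator emulates a spinal-cord-injury style study design: three
conditions (transected, sham, uninjured), several partially overlapping
sampling series that share the 0 h point, dense 30-min/1-h sampling over
0-21 h, per-series batch offsets, negative-binomial counts, and planted
gene modules following early/intermediate/late, up/down,
transitory-or-sustained kinetic profiles.  Ground truth (module labels,
kinetic specs, differential-expression flags, the latent log-mean matrix)
is returned alongside the counts so every downstream stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import rng_for, check_finite
from .counts_io import TimeSeriesCounts, write_counts

TIMINGS = ("early", "intermediate", "late")
DIRECTIONS = ("up", "down")

# Default onset windows, in hours post-treatment.
ONSET_WINDOWS = {"early": (0.0, 2.0), "intermediate": (2.0, 5.0), "late": (11.0, 12.0)}


@dataclass(frozen=True)
class KineticSpec:
    """Parametric kinetic profile of one planted module.

    The profile is zero before ``onset_time``, rises logistically to
    ``amplitude`` (in log2-fold units) at ``peak_time``, and — if
    ``transitory`` — decays exponentially afterwards at ``decay_rate``
    per hour without returning to baseline within the sampled window.
    ``direction='down'`` negates the whole trajectory.
    """

    class_label: str
    direction: str = "up"
    transitory: bool = False
    onset_time: float = 0.5
    peak_time: float = 2.0
    amplitude: float = 2.0
    decay_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.class_label not in TIMINGS:
            raise ValueError(f"class_label must be one of {TIMINGS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        for name in ("onset_time", "peak_time", "amplitude", "decay_rate"):
            check_finite(name, getattr(self, name))
        if not self.onset_time < self.peak_time:
            raise ValueError("onset_time must be < peak_time")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def kinetic_profile(spec: KineticSpec, times) -> np.ndarray:
    """Evaluate a kinetic spec on a time grid -> log2-fold deviations.

    The rise is a logistic ramp rescaled to hit exactly 0 at onset and
    exactly ``amplitude`` at the peak, so sustained profiles plateau at the
    full amplitude and transitory ones decay from it.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    u = (t - spec.onset_time) / (spec.peak_time - spec.onset_time)
    k = 10.0  # logistic steepness on the unit rise interval
    sig = 1.0 / (1.0 + np.exp(-k * (np.clip(u, 0.0, 1.0) - 0.5)))
    lo, hi = 1.0 / (1.0 + np.exp(k / 2)), 1.0 / (1.0 + np.exp(-k / 2))
    ramp = (sig - lo) / (hi - lo)
    y = np.where(u <= 0.0, 0.0, np.where(u >= 1.0, 1.0, ramp)) * spec.amplitude
    if spec.transitory:
        after = t > spec.peak_time
        y = np.where(after, spec.amplitude * np.exp(-spec.decay_rate * (t - spec.peak_time)), y)
    if spec.direction == "down":
        y = -y
    return y


@dataclass(frozen=True)
class SeriesSpec:
    series_id: str
    condition: str
    times: tuple  # hours; replicated entries mean replicate samples


@dataclass
class SimDesign:
    """Full description of a synthetic experiment."""

    n_genes: int = 2000
    module_specs: list | None = None  # (size, KineticSpec); None -> defaults
    fraction_null: float | None = None
    conditions: tuple = ("transected", "sham", "uninjured")
    series_layout: list = field(default_factory=list)  # SeriesSpec
    batch_sd: float = 0.3
    nb_dispersion: float = 0.04
    library_size_range: tuple = (8e5, 1.2e6)
    baseline_log2: tuple = (6.0, 2.0)  # mean, sd of per-gene baseline log2 expression
    sham_attenuation: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_specs is None:
            self.module_specs = default_module_specs()
        if not self.series_layout:
            self.series_layout = default_series_layout(self.conditions)
        total = sum(size for size, _ in self.module_specs)
        if total > self.n_genes:
            raise ValueError(f"module sizes sum to {total} > n_genes={self.n_genes}")
        for s in self.series_layout:
            if s.condition not in self.conditions:
                raise ValueError(f"series {s.series_id} has unknown condition {s.condition}")
            if any(t < 0 or t > 21 for t in s.times):
                raise ValueError("series time grids must lie within [0, 21] h")
        by_cond: dict = {}
        for s in self.series_layout:
            by_cond.setdefault(s.condition, []).append(s)
        for cond, series in by_cond.items():
            if len(series) > 1 and not all(0.0 in s.times for s in series):
                raise ValueError(f"series of condition {cond} must share the 0 h point")
        if self.fraction_null is not None and not 0.0 <= self.fraction_null <= 1.0:
            raise ValueError("fraction_null must be in [0, 1]")

    def n_module_genes(self) -> int:
        total = sum(size for size, _ in self.module_specs)
        if self.fraction_null is None:
            return total
        return min(total, int(round((1.0 - self.fraction_null) * self.n_genes)))


def default_module_specs() -> list:
    """Six planted modules spanning the kinetic taxonomy of the design.

    Two early-up transitory modules, intermediate up (sustained) and down,
    and late up/down — the qualitative classes an acute-injury time course
    exhibits over its first 21 h.
    """
    return [
        (60, KineticSpec("early", "up", True, onset_time=0.3, peak_time=2.0,
                         amplitude=3.0, decay_rate=0.12)),
        (70, KineticSpec("early", "up", True, onset_time=0.5, peak_time=2.5,
                         amplitude=2.5, decay_rate=0.04)),
        (100, KineticSpec("intermediate", "up", False, onset_time=2.5, peak_time=5.0,
                          amplitude=2.0)),
        (110, KineticSpec("intermediate", "down", False, onset_time=3.0, peak_time=6.0,
                          amplitude=1.8)),
        (120, KineticSpec("late", "up", False, onset_time=11.0, peak_time=14.0,
                          amplitude=2.0)),
        (90, KineticSpec("late", "down", False, onset_time=11.5, peak_time=14.0,
                         amplitude=1.8)),
    ]


def default_series_layout(conditions=("transected", "sham", "uninjured")) -> list:
    """Sampling layout mirroring a six-series injured/sham design plus two
    uninjured series: 30-min sampling over 0-2 h, hourly afterwards, every
    series anchored at 0 h with 1-3 points overlapping the next series."""
    injured_grids = {
        "S1": (0.0, 0.0, 0.5, 1.0, 1.5, 2.0),  # duplicated 0 h = replicate
        "S2": (0.0, 0.5, 1.0, 1.5, 2.0),
        "S3": (0.0, 2.0, 3.0, 4.0, 5.0, 6.0),
        "S4": (0.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0),
        "S5": (0.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0),
        "S6": (0.0, 16.0, 17.0, 18.0, 19.0, 20.0, 21.0),
    }
    layout = []
    for cond in conditions:
        if cond == "uninjured":
            layout.append(SeriesSpec("U1", cond, tuple(float(t) for t in range(0, 11))))
            layout.append(SeriesSpec("U2", cond, (0.0,) + tuple(float(t) for t in range(10, 22))))
        else:
            prefix = "T" if cond == "transected" else "H"
            for sid, grid in injured_grids.items():
                layout.append(SeriesSpec(prefix + sid[1:], cond, grid))
    return layout


@dataclass
class SyntheticExperiment:
    counts: TimeSeriesCounts
    truth: pd.DataFrame  # per gene: module, kinetic fields, DE flags
    latent: pd.DataFrame  # gene x sample log2-mean matrix
    design: SimDesign

    def __post_init__(self) -> None:
        if self.counts.counts.shape != self.latent.shape:
            raise ValueError("counts and latent dimensions differ")
        if not self.truth.index.equals(self.counts.counts.index):
            raise ValueError("truth must cover every gene")


def apply_batch_offsets(latent: np.ndarray, series_labels, batch_sd: float,
                        seed: int, series_ids=None) -> np.ndarray:
    """Add per-(gene, series) N(0, batch_sd^2) offsets to a latent matrix.

    ``series_labels`` gives the series of each column.  ``batch_sd=0`` is the
    identity.  The offset table is drawn once per series in sorted order so
    the result is reproducible for a fixed seed.
    """
    latent = np.asarray(latent, dtype=float)
    check_finite("latent", latent)
    series_labels = list(series_labels)
    if latent.shape[1] != len(series_labels):
        raise ValueError("series_labels length must match latent columns")
    known = sorted(set(series_labels)) if series_ids is None else list(series_ids)
    unknown = set(series_labels) - set(known)
    if unknown:
        raise ValueError(f"unknown series labels: {sorted(unknown)}")
    if batch_sd == 0:
        return latent.copy()
    rng = np.random.default_rng(seed)
    offsets = {s: rng.normal(0.0, batch_sd, size=latent.shape[0]) for s in known}
    out = latent.copy()
    for j, s in enumerate(series_labels):
        out[:, j] += offsets[s]
    return out


def simulate_experiment(design: SimDesign) -> SyntheticExperiment:
    """Draw one synthetic experiment from a design.

    latent log2-mean = baseline + condition-specific kinetic deviation
    (full in the transected condition, attenuated in sham, absent in
    uninjured) + per-series batch offset; counts are NB with
    library-size-scaled means and dispersion ``nb_dispersion``.
    """
    d = design
    seed = d.seed

    sample_rows = []
    for s in d.series_layout:
        rep_counter: dict = {}
        for t in s.times:
            rep_counter[t] = rep_counter.get(t, 0) + 1
            suffix = f"r{rep_counter[t]}" if rep_counter[t] > 1 else ""
            sid = f"{s.series_id}_{t:g}h{suffix}"
            sample_rows.append((sid, s.condition, s.series_id, float(t), s.series_id))
    meta = pd.DataFrame(sample_rows, columns=["sample_id", "condition", "series",
                                              "time_hpt", "batch"]).set_index("sample_id")

    genes = [f"g{i:05d}" for i in range(d.n_genes)]
    n_responding = d.n_module_genes()

    # assign genes to modules in order; remainder is null
    module_of = np.zeros(d.n_genes, dtype=int)
    spec_of: list = [None] * d.n_genes
    cursor = 0
    for m, (size, spec) in enumerate(d.module_specs, start=1):
        take = min(size, max(0, n_responding - cursor))
        module_of[cursor:cursor + take] = m
        for g in range(cursor, cursor + take):
            spec_of[g] = spec
        cursor += take

    baseline = rng_for(seed, "baseline").normal(d.baseline_log2[0], d.baseline_log2[1],
                                                size=d.n_genes)
    baseline = np.clip(baseline, 0.0, None)

    times = meta["time_hpt"].to_numpy()
    conditions = meta["condition"].to_numpy()
    latent = np.tile(baseline[:, None], (1, len(meta)))
    cond_scale = {c: (1.0 if c == "transected" else
                      d.sham_attenuation if c == "sham" else 0.0)
                  for c in d.conditions}
    for m, (size, spec) in enumerate(d.module_specs, start=1):
        idx = np.where(module_of == m)[0]
        if idx.size == 0:
            continue
        profile = kinetic_profile(spec, times)
        scales = np.array([cond_scale[c] for c in conditions])
        latent[idx] += (profile * scales)[None, :]

    latent = apply_batch_offsets(latent, meta["series"].tolist(), d.batch_sd,
                                 seed=int(rng_for(seed, "batch").integers(2**31 - 1)))

    rng_counts = rng_for(seed, "counts")
    libsizes = rng_for(seed, "libsize").uniform(*d.library_size_range, size=len(meta))
    expr = np.exp2(latent)
    mu = expr / expr.sum(axis=0, keepdims=True) * libsizes[None, :]
    phi = d.nb_dispersion
    if phi > 0:
        r = 1.0 / phi
        counts = rng_counts.negative_binomial(r, r / (r + mu))
    else:
        counts = rng_counts.poisson(mu)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=meta.index)
    latent_df = pd.DataFrame(latent, index=genes, columns=meta.index)

    truth = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    truth["module"] = module_of
    truth["is_de"] = module_of > 0
    truth["de_vs_uninjured"] = truth["is_de"]
    truth["de_vs_sham"] = truth["is_de"] & (d.sham_attenuation != 1.0)
    for col, default in (("class_label", "null"), ("direction", "none")):
        truth[col] = [getattr(s, col) if s else default for s in spec_of]
    truth["transitory"] = [bool(s.transitory) if s else False for s in spec_of]
    truth["onset_time"] = [s.onset_time if s else np.nan for s in spec_of]
    truth["peak_time"] = [s.peak_time if s else np.nan for s in spec_of]
    truth["amplitude"] = [s.amplitude if s else 0.0 for s in spec_of]

    tsc = TimeSeriesCounts(counts=counts_df, meta=meta)
    return SyntheticExperiment(counts=tsc, truth=truth, latent=latent_df, design=d)


def write_experiment(exp: SyntheticExperiment, outdir) -> dict:
    """Write counts, sample sheet and truth tables as TSV/JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samplesheet": outdir / "samples.tsv",
        "truth_tsv": outdir / "truth.tsv",
        "truth_json": outdir / "truth.json",
    }
    write_counts(exp.counts, paths["counts"], paths["samplesheet"])
    exp.truth.to_csv(paths["truth_tsv"], sep="\t")
    meta = {
        "n_genes": exp.design.n_genes,
        "seed": exp.design.seed,
        "nb_dispersion": exp.design.nb_dispersion,
        "batch_sd": exp.design.batch_sd,
        "modules": [
            {"module": m + 1, "size": int(size), **asdict(spec)}
            for m, (size, spec) in enumerate(exp.design.module_specs)
        ],
    }
    paths["truth_json"].write_text(json.dumps(meta, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


def synthetic_annotation(truth: pd.DataFrame, terms_per_module: int = 3,
                         n_background_terms: int = 10, seed: int = 0) -> dict:
    """Build a toy GO-style annotation (term -> gene set) from planted truth.

    Each planted module contributes ``terms_per_module`` overlapping terms
    drawn from its genes; background terms sample the whole universe.
    Useful for exercising the enrichment stage end-to-end on synthetic data.
    """
    rng = np.random.default_rng(seed)
    ann: dict = {}
    genes = truth.index.to_numpy()
    for m in sorted(set(truth["module"]) - {0}):
        members = truth.index[truth["module"] == m].to_numpy()
        for k in range(terms_per_module):
            size = max(3, int(len(members) * rng.uniform(0.4, 0.9)))
            ann[f"GO:M{m:02d}{k:02d}"] = set(rng.choice(members, size=min(size, len(members)),
                                                        replace=False))
    for k in range(n_background_terms):
        size = int(rng.integers(10, max(11, len(genes) // 10)))
        ann[f"GO:BG{k:04d}"] = set(rng.choice(genes, size=size, replace=False))
    return ann
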
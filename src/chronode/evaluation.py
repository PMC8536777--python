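"""Self-contained benchmark suite on synthetic data with known truth.

Each function regenerates its inputs from a seed, runs the relevant part of
the pipeline, and returns summary numbers: GP marginal-likelihood accuracy
against a dense multivariate-normal oracle, null/power calibration of the
BIC score on the count->VST pipeline, planted-module recovery, change-point
onset recovery, enrichment-statistic accuracy, exact-test calibration, and
end-to-end determinism.  Used by the acceptance script and the test suite.
"""

from __future__ import annotations

import hashlib
import tempfile
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score

from ._utils import derive_seed
from .counts_io import filter_low_counts, vst_normalize
from .enrich import AnnotationSet, fisher_enrichment, x_value
from .gp import JITTER, gp_log_marginal, se_kernel
from .gp_tde import score_genes
from .kinetics import NigPrior, changepoint_posterior, classify_module
from .network import build_network
from .pairwise import nb_exact_test
from .pipeline import PipelineConfig, run_all
from .simdata import KineticSpec, SeriesSpec, SimDesign, simulate_experiment

HOURLY = tuple(float(t) for t in range(22))
STUDY_GRID = tuple(sorted({0.0, 0.5, 1.0, 1.5} | set(map(float, range(2, 22)))))


# ---------------------------------------------------------------- GP engine

def gp_oracle_max_error(seed: int, n_max: int = 8, trials_per_n: int = 20) -> float:
    """Max |logML - dense MVN logpdf| over random small instances."""
    rng = np.random.default_rng(derive_seed(seed, "gp_oracle"))
    worst = 0.0
    for n in range(3, n_max + 1):
        for _ in range(trials_per_n):
            t = np.sort(rng.uniform(0, 21, n))
            y = rng.normal(size=n)
            sf2 = rng.uniform(0.05, 5)
            ls = rng.uniform(0.6, 20)
            sn2 = rng.uniform(0.01, 2)
            K = se_kernel(t, t, sf2, ls) + (sn2 + JITTER * max(sf2, sn2)) * np.eye(n)
            oracle = stats.multivariate_normal(mean=np.zeros(n), cov=K).logpdf(y)
            worst = max(worst, abs(gp_log_marginal(t, y, sf2, ls, sn2) - oracle))
    return float(worst)


# ------------------------------------------------- BIC score calibration

def _two_condition_design(n_genes, module_specs, fraction_null, seed,
                          phi=0.04) -> SimDesign:
    layout = [SeriesSpec("T1", "transected", HOURLY),
              SeriesSpec("U1", "uninjured", HOURLY)]
    return SimDesign(n_genes=n_genes, module_specs=module_specs,
                     fraction_null=fraction_null,
                     conditions=("transected", "uninjured"),
                     series_layout=layout, batch_sd=0.0, nb_dispersion=phi,
                     seed=seed)


def bic_calibration(seed: int, n_null: int = 2000, n_effect: int = 200,
                    restarts: int = 5, threshold: float = 10.0) -> dict:
    """Null and power calibration of the GP BIC score on NB->VST data.

    Null genes share one latent trajectory in both conditions; effect genes
    carry a sustained 1.2 log2 (= 4x the ~0.3 VST noise SD) divergence.
    Returns the fraction of null genes at or above the threshold and the
    fraction of effect genes at or above it.
    """
    null_design = _two_condition_design(n_null, [], 1.0,
                                        derive_seed(seed, "bic_null"))
    exp = simulate_experiment(null_design)
    norm = vst_normalize(filter_low_counts(exp.counts))
    res_null = score_genes(norm.values, exp.counts.meta, "transected",
                           "uninjured", restarts=restarts,
                           seed=derive_seed(seed, "bic_null_fit"))

    spec = KineticSpec("intermediate", "up", False, onset_time=3.0,
                       peak_time=6.0, amplitude=1.2)
    eff_design = _two_condition_design(10 * n_effect, [(n_effect, spec)], None,
                                       derive_seed(seed, "bic_eff"))
    exp2 = simulate_experiment(eff_design)
    norm2 = vst_normalize(filter_low_counts(exp2.counts))
    planted = [g for g in exp2.truth.index[exp2.truth["module"] > 0]
               if g in norm2.values.index]
    res_eff = score_genes(norm2.values, exp2.counts.meta, "transected",
                          "uninjured", restarts=restarts,
                          seed=derive_seed(seed, "bic_eff_fit"),
                          genes=planted)
    return {
        "null_fraction_ge_threshold": float((res_null["score"] >= threshold).mean()),
        "power_fraction_ge_threshold": float((res_eff["score"] >= threshold).mean()),
        "n_null_scored": int(len(res_null)),
        "n_effect_scored": int(len(res_eff)),
    }


# ------------------------------------------------------- module recovery

def module_recovery(seed: int, n_seeds: int = 10, beta: float = 15.0) -> dict:
    """Recovery of six planted kinetic modules over independent simulations.

    Full transected multi-series design with batch effects; counts ->
    filter -> VST -> batch adjustment -> bicor/TOM network -> modules.
    Reports the worst-case and median adjusted Rand index against the
    planted labels and the fraction of planted genes assigned.
    """
    from .batch import adjust, fit_batch_model
    from .pipeline import _protect_covariates

    aris, assigned = [], []
    for i in range(n_seeds):
        design = SimDesign(n_genes=700, conditions=("transected",),
                           batch_sd=0.3, seed=derive_seed(seed, "modules", i))
        exp = simulate_experiment(design)
        f = filter_low_counts(exp.counts)
        norm = vst_normalize(f)
        cov = _protect_covariates(f.meta, f.meta["batch"])
        model = fit_batch_model(norm, f.meta["batch"].tolist(), covariates=cov)
        corr = adjust(norm, model, f.meta["batch"].tolist(), covariates=cov)
        modules, _ = build_network(corr.values, beta=beta, min_module_size=30)
        truth = exp.truth.loc[corr.values.index, "module"]
        planted = truth > 0
        aris.append(adjusted_rand_score(truth[planted], modules.labels[planted]))
        assigned.append(float((modules.labels[planted] > 0).mean()))
    return {
        "ari_median": float(np.median(aris)),
        "ari_min": float(np.min(aris)),
        "assigned_fraction_min": float(np.min(assigned)),
        "n_seeds": n_seeds,
    }


# --------------------------------------------------- change-point suite

def _mvt_segment_logml(y: np.ndarray, prior: NigPrior) -> float:
    n = len(y)
    shape = (prior.beta0 / prior.alpha0) * (np.eye(n) + np.ones((n, n)) / prior.kappa0)
    return float(stats.multivariate_t(loc=prior.mu0 * np.ones(n), shape=shape,
                                      df=2 * prior.alpha0).logpdf(y))


def changepoint_oracle_max_error(seed: int, n: int = 10) -> float:
    """Max |log evidence - exhaustive multivariate-t enumeration| on a grid."""
    from itertools import combinations
    rng = np.random.default_rng(derive_seed(seed, "cp_oracle"))
    y = rng.normal(size=n)
    post = changepoint_posterior(np.arange(float(n)), y)
    prior = NigPrior(mu0=float(y.mean()), kappa0=0.2, alpha0=1.0,
                     beta0=float(np.var(y)))
    worst = 0.0
    for m in (0, 1, 2):
        cfgs = [()] if m == 0 else list(combinations(range(1, n), m))
        lls = []
        for cfg in cfgs:
            b = (0,) + cfg + (n,)
            lls.append(sum(_mvt_segment_logml(y[b[i]:b[i + 1]], prior)
                           for i in range(len(b) - 1)))
        oracle = logsumexp(lls) - np.log(len(cfgs))
        worst = max(worst, abs(post.log_evidence[m] - oracle))
    return float(worst)


def changepoint_recovery(seed: int, n_rep: int = 100, noise_sd: float = 0.1) -> dict:
    """Onset recovery for planted early/intermediate/late regime changes.

    Eigengene-like series on the study sampling grid: a 1-h logistic rise
    of unit amplitude starting at the planted onset, plus Gaussian noise.
    Reports the median absolute error of the MAP first change time per
    onset, and whether a flat noiseless series prefers the 0-change model.
    """
    t = np.asarray(STUDY_GRID)
    onsets = {"early": 1.5, "intermediate": 4.0, "late": 11.5}
    out = {}
    for name, onset in onsets.items():
        spec = KineticSpec(name, "up", name == "early", onset_time=onset,
                           peak_time=onset + 1.0, amplitude=1.0, decay_rate=0.12)
        profile = None
        errs = []
        for i in range(n_rep):
            rng = np.random.default_rng(derive_seed(seed, "cp", name, i))
            from .simdata import kinetic_profile
            if profile is None:
                profile = kinetic_profile(spec, t)
            y = profile + rng.normal(0, noise_sd, t.size)
            post = changepoint_posterior(t, y)
            if post.map_changes:
                errs.append(abs(post.map_changes[0] - onset))
            else:
                errs.append(np.inf)
        out[f"onset_{name}_median_abs_error_h"] = float(np.median(errs))
    flat = changepoint_posterior(t, np.full(t.size, 0.4))
    out["flat_series_prefers_zero_changes"] = float(flat.map_n_changes == 0)
    return out


def kinetic_classification_accuracy(seed: int, n_rep: int = 20,
                                    noise_sd: float = 0.1) -> dict:
    """Classification accuracy over the six default planted kinetic classes."""
    from .simdata import default_module_specs, kinetic_profile
    t = np.asarray(STUDY_GRID)
    correct_timing, correct_direction, n_total = 0, 0, 0
    for m, (_, spec) in enumerate(default_module_specs()):
        profile = kinetic_profile(spec, t)
        for i in range(n_rep):
            rng = np.random.default_rng(derive_seed(seed, "kcls", m, i))
            y = profile + rng.normal(0, noise_sd, t.size)
            post = changepoint_posterior(t, y)
            klass = classify_module(t, y, post)
            n_total += 1
            correct_timing += klass.timing == spec.class_label
            correct_direction += klass.direction == spec.direction
    return {"timing_accuracy": correct_timing / n_total,
            "direction_accuracy": correct_direction / n_total}


# ------------------------------------------------------- enrichment suite

def fisher_oracle_max_error(seed: int, trials: int = 30) -> float:
    """Max |Fisher p - exact rational hypergeometric tail| over random tables."""
    rng = np.random.default_rng(derive_seed(seed, "fisher"))
    universe = [f"g{i}" for i in range(60)]
    worst = 0.0
    for _ in range(trials):
        K = int(rng.integers(3, 30))
        n = int(rng.integers(3, 30))
        ann_genes = set(rng.choice(universe, size=K, replace=False))
        module = set(rng.choice(universe, size=n, replace=False))
        k = len(ann_genes & module)
        if k == 0:
            continue
        ann = AnnotationSet(term_genes={"T": ann_genes}, universe=universe)
        res = fisher_enrichment(module, ann, p_cutoff=1.0)
        total = comb(60, n)
        oracle = float(sum(Fraction(comb(K, i) * comb(60 - K, n - i), total)
                           for i in range(k, min(K, n) + 1)))
        worst = max(worst, abs(res[0].p_value - oracle))
    return float(worst)


def xvalue_worked_example() -> float:
    """x-value of a term with p = 1e-3 and summed BIC 100 (expected 300)."""
    return float(x_value(1e-3, 100.0))


# --------------------------------------------------------- exact test suite

def exact_test_type1(seed: int, n_per_mean: int = 600,
                     means=(25, 50, 100, 250, 500), phi: float = 0.04) -> float:
    """Fraction of null NB pairs with p <= 0.01 over a mean grid."""
    rng = np.random.default_rng(derive_seed(seed, "type1"))
    r = 1.0 / phi
    hits, total = 0, 0
    for mu in means:
        a = rng.negative_binomial(r, r / (r + float(mu)), size=n_per_mean)
        b = rng.negative_binomial(r, r / (r + float(mu)), size=n_per_mean)
        for x, y in zip(a, b):
            hits += nb_exact_test(int(x), int(y), bcv=np.sqrt(phi)) <= 0.01
            total += 1
    return hits / total


def exact_test_poisson_limit_error(a: int = 3, b: int = 17) -> float:
    """|NB exact p at phi->0  -  conditional binomial two-sided p|."""
    s = a + b
    pmf = stats.binom.pmf(np.arange(s + 1), s, 0.5)
    p_binom = float(pmf[pmf <= pmf[a] * (1 + 1e-9)].sum())
    return abs(nb_exact_test(a, b, bcv=1e-4) - p_binom)


# ----------------------------------------------------------- determinism

def _tree_hashes(folder) -> dict:
    out = {}
    for p in sorted(Path(folder).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(folder))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def determinism_check(seed: int, workdir=None) -> bool:
    """run_all twice with one seed on a compact design: byte-identical?"""
    spec_a = KineticSpec("intermediate", "up", False, onset_time=2.5,
                         peak_time=5.0, amplitude=2.0)
    spec_b = KineticSpec("late", "down", False, onset_time=11.0,
                         peak_time=14.0, amplitude=2.0)
    sim = {
        "n_genes": 100,
        "module_specs": [(35, spec_a), (35, spec_b)],
        "conditions": ("transected", "sham", "uninjured"),
        "series_layout": [SeriesSpec("T1", "transected", HOURLY),
                          SeriesSpec("H1", "sham", HOURLY),
                          SeriesSpec("U1", "uninjured", HOURLY)],
        "batch_sd": 0.0,
    }

    def _run(folder):
        cfg = PipelineConfig(outdir=str(folder), seed=seed, simulate=sim)
        cfg.gp_de["restarts"] = 2
        cfg.network["beta"] = 6.0
        cfg.network["min_module_size"] = 20
        run_all(cfg)
        return _tree_hashes(folder)

    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        h1 = _run(Path(tmp) / "a")
        h2 = _run(Path(tmp) / "b")
    return h1 == h2
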
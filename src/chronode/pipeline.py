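"""Pipeline orchestration: staged execution with manifests and determinism.

Stages run in a fixed dependency order — simulate (optional) -> qc ->
filter -> normalize -> correct-batch -> gp-de -> network -> kinetics ->
enrich [-> pairwise-de] — each writing TSV/JSON outputs plus a manifest
(stage name, parameters, input hashes, seed) into the run folder, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch as batch_mod
from . import counts_io, enrich, gp_tde, kinetics, network, simdata
from ._utils import derive_seed

log = logging.getLogger("chronode")

STAGE_ORDER = ["simulate", "qc", "filter", "normalize", "correct_batch",
               "gp_de", "network", "kinetics", "enrich", "pairwise_de"]
STAGE_DEPS = {
    "qc": ["normalize"],
    "normalize": ["filter"],
    "correct_batch": ["normalize"],
    "gp_de": ["correct_batch"],
    "network": ["gp_de"],
    "kinetics": ["network"],
    "enrich": ["network", "gp_de"],
}


class ValidationError(ValueError):
    """Configuration or dependency error, reported before any stage runs."""


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    counts: str | None = None
    samplesheet: str | None = None
    gmt: str | None = None
    obo: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    # stage parameters (defaults mirror the module-level defaults)
    simulate: dict = field(default_factory=dict)       # SimDesign overrides
    filter: dict = field(default_factory=lambda: {"min_count": 5, "min_timepoints": 4})
    gp_de: dict = field(default_factory=lambda: {"threshold": 10.0, "restarts": 5,
                                                 "condition": "transected",
                                                 "control_1": "uninjured",
                                                 "control_2": "sham"})
    network: dict = field(default_factory=lambda: {"beta": None, "min_module_size": 30})
    kinetics: dict = field(default_factory=lambda: {"max_changes": 2})
    enrich: dict = field(default_factory=lambda: {"p_cutoff": 0.01, "kme_min": 0.6,
                                                  "eps": 0.7, "min_pts": 2})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValidationError(f"unknown config key: {key}")
            if isinstance(getattr(cfg, key), dict) and isinstance(val, dict):
                getattr(cfg, key).update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        enabled = {s for s in STAGE_ORDER if self.stages.get(s, True)}
        for stage in enabled:
            for dep in STAGE_DEPS.get(stage, []):
                if dep not in enabled:
                    raise ValidationError(f"stage {stage!r} requires {dep!r} to be enabled")
        if not self.stages.get("simulate", True):
            for path, name in ((self.counts, "counts"), (self.samplesheet, "samplesheet")):
                if path is None:
                    raise ValidationError(f"{name} path required when simulate is disabled")
                if not Path(path).exists():
                    raise ValidationError(f"{name} path does not exist: {path}")
        if self.stages.get("enrich", True) and not self.stages.get("simulate", True):
            if self.gmt is None:
                raise ValidationError("enrich stage needs a GMT annotation (or simulated truth)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, inputs: list,
                    outputs: list, seed: int | None) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "seed": seed,
        "inputs": {Path(p).name: _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(Path(p).name): _sha256(Path(p)) for p in outputs},
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=repr) + "\n")


def _tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)
    return path


def run_all(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run folder.

    A stage failure aborts with the failing stage named; outputs of earlier
    stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    stage = "start"
    try:
        # ---- simulate / load --------------------------------------------
        annotation_truth = None
        if config.stages.get("simulate", True):
            stage = "simulate"
            sim_kwargs = {k: v for k, v in config.simulate.items() if k != "seed"}
            design = simdata.SimDesign(**sim_kwargs, seed=derive_seed(seed, "simulate"))
            exp = simdata.simulate_experiment(design)
            paths = simdata.write_experiment(exp, outdir)
            annotation_truth = exp.truth
            data = exp.counts
            _write_manifest(outdir, stage, {**config.simulate}, [],
                            list(paths.values()), design.seed)
        else:
            data = counts_io.read_counts(config.counts, config.samplesheet)

        # ---- filter ------------------------------------------------------
        stage = "filter"
        filtered = counts_io.filter_low_counts(data, **config.filter)
        p_counts = _tsv(filtered.counts, outdir / "filtered_counts.tsv", index_label="gene_id")
        _write_manifest(outdir, stage, config.filter, [], [p_counts], None)

        # ---- normalize ---------------------------------------------------
        stage = "normalize"
        norm = counts_io.vst_normalize(filtered)
        p_norm = _tsv(norm.values, outdir / "vst.tsv", index_label="gene_id")
        _write_manifest(outdir, stage, {"method": norm.method}, [p_counts], [p_norm], None)

        # ---- qc ----------------------------------------------------------
        if config.stages.get("qc", True):
            stage = "qc"
            report = counts_io.spearman_consistency(norm, filtered.meta)
            p_qc = outdir / "consistency.json"
            report.to_json(p_qc)
            _write_manifest(outdir, stage, {}, [p_norm], [p_qc], None)

        # ---- batch correction -------------------------------------------
        stage = "correct_batch"
        meta = filtered.meta
        batches = meta["batch"].astype(str)
        corrected = norm
        # skip when batch is aliased with condition (one batch per condition):
        # the batch effect is then unidentifiable and adjustment would erase
        # the biological contrast itself
        aliased = (meta.groupby(batches)["condition"].nunique().eq(1).all()
                   and meta.groupby("condition")[batches.name].nunique().eq(1).all())
        if batches.nunique() > 1 and not aliased:
            cov = _protect_covariates(meta, batches)
            model = batch_mod.fit_batch_model(norm, batches.tolist(), covariates=cov)
            corrected = batch_mod.adjust(norm, model, batches.tolist(), covariates=cov)
            model.to_json(outdir / "batch_model.json")
        p_corr = _tsv(corrected.values, outdir / "corrected.tsv", index_label="gene_id")
        _write_manifest(outdir, stage, {"n_batches": int(batches.nunique())},
                        [p_norm], [p_corr], None)

        # ---- GP differential expression ---------------------------------
        stage = "gp_de"
        gp_cfg = config.gp_de
        cond = gp_cfg["condition"]
        res_u = gp_tde.score_genes(corrected.values, meta, cond, gp_cfg["control_1"],
                                   restarts=gp_cfg["restarts"],
                                   seed=derive_seed(seed, "gp_de", "u"))
        res_s = gp_tde.score_genes(corrected.values, meta, cond, gp_cfg["control_2"],
                                   restarts=gp_cfg["restarts"],
                                   seed=derive_seed(seed, "gp_de", "s"))
        calls = gp_tde.call_de(res_u, res_s, threshold=gp_cfg["threshold"])
        p_de = _tsv(calls.table.assign(called=calls.table["called"].astype(int)),
                    outdir / "gp_de.tsv", index_label="gene")
        p_hist = outdir / "gp_de_hist2d.tsv"
        gp_tde.write_hist(calls, p_hist)
        _write_manifest(outdir, stage, {k: v for k, v in gp_cfg.items()},
                        [p_corr], [p_de, p_hist], derive_seed(seed, "gp_de"))

        # ---- network -----------------------------------------------------
        stage = "network"
        called = calls.called
        if len(called) < max(50, config.network["min_module_size"]):
            raise RuntimeError(f"only {len(called)} genes called; too few for a network")
        net_mask = meta["condition"] == cond
        expr = corrected.values.loc[called, meta.index[net_mask]]
        times_net = meta.loc[net_mask, "time_hpt"].to_numpy()
        modules, artifacts = network.build_network(
            expr, beta=config.network["beta"],
            min_module_size=config.network["min_module_size"], times=times_net)
        assign = pd.DataFrame({"module": modules.labels, "kme": modules.kme})
        p_mod = _tsv(assign, outdir / "modules.tsv", index_label="gene")
        p_eig = _tsv(modules.eigengenes, outdir / "eigengenes.tsv")
        _write_manifest(outdir, stage, {"beta": artifacts["beta"],
                                        "min_module_size": config.network["min_module_size"]},
                        [p_de], [p_mod, p_eig], None)

        # ---- kinetics ----------------------------------------------------
        stage = "kinetics"
        rows, post_rows = [], []
        for m in modules.eigengenes.index:
            # average replicate samples at the same time for the series
            eg = modules.eigengenes.loc[m]
            tser = pd.Series(times_net, index=eg.index)
            prof = eg.groupby(tser).mean()
            t_grid, y_grid = prof.index.to_numpy(float), prof.to_numpy()
            post = kinetics.changepoint_posterior(t_grid, y_grid,
                                                  max_changes=config.kinetics["max_changes"])
            klass = kinetics.classify_module(t_grid, y_grid, post, module=int(m))
            rows.append({"module": int(m), "timing": klass.timing,
                         "direction": klass.direction,
                         "transitory": int(klass.transitory),
                         "onset_h": klass.onset_h,
                         **{f"log_evidence_m{k}": v for k, v in post.log_evidence.items()}})
            for t, pr in zip(t_grid, post.change_prob):
                post_rows.append({"module": int(m), "time_hpt": t, "change_prob": pr})
        p_kin = _tsv(pd.DataFrame(rows), outdir / "kinetics.tsv", index=False)
        p_post = _tsv(pd.DataFrame(post_rows), outdir / "change_posteriors.tsv", index=False)
        _write_manifest(outdir, stage, config.kinetics, [p_eig], [p_kin, p_post], None)

        # ---- enrichment --------------------------------------------------
        if config.stages.get("enrich", True):
            stage = "enrich"
            universe = set(corrected.values.index)
            if config.gmt is not None:
                ann = enrich.load_annotation(config.gmt, universe, obo_path=config.obo)
            elif annotation_truth is not None:
                term_genes = simdata.synthetic_annotation(
                    annotation_truth, seed=derive_seed(seed, "annotation"))
                ann = enrich.AnnotationSet(term_genes=term_genes, universe=universe)
            else:
                raise ValidationError("enrich stage needs a GMT annotation")
            scores = pd.concat([res_u["score"], res_s["score"]], axis=1).min(axis=1)
            e_cfg = config.enrich
            all_rows = []
            for m in modules.eigengenes.index:
                mod_genes = modules.module_genes(int(m))
                terms = enrich.fisher_enrichment(mod_genes, ann,
                                                 p_cutoff=e_cfg["p_cutoff"],
                                                 kme=modules.kme, kme_min=e_cfg["kme_min"],
                                                 gene_scores=scores)
                terms = enrich.reduce_redundancy(terms)
                if not terms:
                    continue
                D = enrich.distance_matrix(terms, ann)
                clusters = enrich.cluster_terms(terms, D, eps=e_cfg["eps"],
                                                min_pts=e_cfg["min_pts"])
                tab = enrich.enrichment_table(clusters, ann.term_names)
                tab.insert(0, "module", int(m))
                all_rows.append(tab)
            enr = (pd.concat(all_rows, ignore_index=True) if all_rows
                   else pd.DataFrame(columns=["module", "cluster", "term"]))
            p_enr = _tsv(enr, outdir / "enrichment.tsv", index=False)
            _write_manifest(outdir, stage, e_cfg, [p_mod], [p_enr], None)
    except ValidationError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


def _protect_covariates(meta: pd.DataFrame, batches: pd.Series) -> np.ndarray | None:
    """Condition dummies plus a cubic polynomial in time, to protect the
    biological signal during batch adjustment.

    Columns collinear with the batch dummies are dropped: when sampling
    series are nested within condition (as in the emulated design) the
    condition indicator is confounded with batch and cannot be protected,
    but the time trend — which varies within every series — always can.
    """
    cond = pd.get_dummies(meta["condition"].astype(str), drop_first=True).to_numpy(float)
    t = meta["time_hpt"].to_numpy(float)
    tmax = t.max() if t.max() > 0 else 1.0
    ts = t / tmax
    poly = np.column_stack([ts, ts ** 2, ts ** 3])
    cov = np.column_stack([cond, poly]) if cond.size else poly
    B = pd.get_dummies(batches.astype(str)).to_numpy(float)
    base_rank = np.linalg.matrix_rank(B)
    keep: list[int] = []
    for j in range(cov.shape[1]):
        trial = np.column_stack([B, cov[:, keep + [j]]])
        if np.linalg.matrix_rank(trial) == base_rank + len(keep) + 1:
            keep.append(j)
    return cov[:, keep] if keep else None
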
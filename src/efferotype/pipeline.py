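"""End-to-end orchestration of the subtyping study at desk scale.

Stage order mirrors the study flow: simulate (optional) -> preprocess ->
subtype -> classify -> network -> score -> survival. Every stage writes its
artifacts under the output directory and registers them, with SHA-256
hashes and the stage parameters, in a single JSON run manifest, so a rerun
with the same config and seeds reproduces identical hashes.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import io as eio
from . import network as net
from . import nmf, scoring, survival
from .datatypes import ClinicalTable, ExpressionMatrix, GeneSignature
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort, write_cohort

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "subtype", "classify", "network", "score", "survival")


@dataclass
class PipelineConfig:
    out_dir: str = "efferotype_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 7
    # simulate
    cohort: dict = field(default_factory=dict)
    # preprocess
    min_days: float = 30.0
    transform: str = "log2tpm"  # {tpm, log2tpm}
    # subtype
    ranks: list[int] = field(default_factory=lambda: [2, 3, 4])
    n_restarts: int = 10
    nmf_max_iter: int = 400
    # classify
    train_frac: float = 0.7
    cv_folds: int = 5
    # network
    ci_threshold: float = 1.0
    prevalence: float = 0.66
    hub_top_k: int = 10
    # survival
    horizons: list[float] = field(default_factory=lambda: [365.0, 1095.0, 1825.0])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.data = {"config": dataclasses.asdict(config), "stages": {}}

    def record(self, stage: str, files: list[Path], params: dict, seconds: float):
        self.data["stages"][stage] = {
            "params": params,
            "seconds": round(seconds, 3),
            "files": {str(f.relative_to(self.out_dir)): _sha256(f) for f in files},
        }

    def write(self) -> Path:
        path = self.out_dir / "run_manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True))
        return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    enabled = [s for s in STAGES if s in config.stages]
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    state: dict = {}
    for stage in enabled:
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            files, params = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            manifest.write()
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, files, params, time.perf_counter() - t0)
        log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    path = manifest.write()
    log.info("run manifest written to %s", path)
    return manifest.data


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict):
    ccfg = CohortConfig(**{"seed": cfg.seed, **cfg.cohort})
    cohort = generate_cohort(ccfg)
    write_cohort(cohort, out / "cohort")
    state["cohort"] = cohort
    files = sorted((out / "cohort").glob("*"))
    return files, {"cohort_config": dataclasses.asdict(ccfg)}


def _require_cohort(state: dict) -> SyntheticCohort:
    if "cohort" not in state:
        raise RuntimeError("no cohort in pipeline state; enable the simulate stage "
                           "or load data before dependent stages")
    return state["cohort"]


def _expr_clinical(cfg: PipelineConfig, state: dict):
    """Preprocessed matrices if that stage ran, else the raw cohort."""
    if "expr" not in state:
        cohort = _require_cohort(state)
        state["expr"] = cohort.expression
        state["clinical"] = cohort.clinical
    return state["expr"], state["clinical"]


def _stage_preprocess(cfg: PipelineConfig, out: Path, state: dict):
    cohort = _require_cohort(state)
    clinical = eio.filter_short_survivors(cohort.clinical, cfg.min_days)
    expr = cohort.expression.subset_samples(clinical.sample_ids)
    if cfg.transform == "log2tpm":
        expr = eio.log2_tpm(expr)
        expr = ExpressionMatrix(expr.values.clip(lower=0.0), "log2tpm")
    state["expr"], state["clinical"] = expr, clinical
    f = out / "expression_preprocessed.tsv"
    eio.write_expression(expr, f)
    f2 = out / "clinical_filtered.tsv"
    eio.write_clinical(clinical, f2)
    return [f, f2], {"min_days": cfg.min_days, "transform": cfg.transform,
                     "n_samples": expr.n_samples}


def _stage_subtype(cfg: PipelineConfig, out: Path, state: dict):
    cohort = _require_cohort(state)
    expr, _ = _expr_clinical(cfg, state)
    labels, results, chosen = nmf.subtype_cohort(
        expr, cohort.signature, ranks=cfg.ranks, n_restarts=cfg.n_restarts,
        base_seed=cfg.seed, max_iter=cfg.nmf_max_iter)
    state["labels"] = labels
    f_lab = out / "subtype_labels.tsv"
    labels.rename("subtype").to_csv(f_lab, sep="\t", index_label="sample_id")
    metrics = {str(r): {"cophenetic": res.cophenetic, "dispersion": res.dispersion}
               for r, res in results.items()}
    f_met = out / "subtype_rank_metrics.json"
    f_met.write_text(json.dumps({"chosen_rank": chosen, "per_rank": metrics}, indent=2))
    f_cons = out / f"consensus_rank{chosen}.tsv"
    pd.DataFrame(results[chosen].consensus, index=expr.sample_ids,
                 columns=expr.sample_ids).to_csv(f_cons, sep="\t")
    return [f_lab, f_met, f_cons], {"ranks": list(cfg.ranks), "n_restarts": cfg.n_restarts,
                                    "chosen_rank": chosen}


def _stage_classify(cfg: PipelineConfig, out: Path, state: dict):
    expr, _ = _expr_clinical(cfg, state)
    labels = state["labels"]
    train, test = eio.stratified_split(expr.sample_ids, labels[expr.sample_ids],
                                       cfg.train_frac, seed=cfg.seed)
    model = clf.fit_centroid_classifier(expr.subset_samples(train), labels[train],
                                        cv_folds=cfg.cv_folds, seed=cfg.seed)
    pred, scores = clf.predict_subtype(model, expr.subset_samples(test))
    auc = clf.roc_auc(scores["C1"], (labels[test] == "C1").astype(int))
    state["classifier_auc"] = auc
    f_model = out / "centroid_model.json"
    model.to_json(f_model)
    f_pred = out / "test_predictions.tsv"
    pd.DataFrame({"predicted": pred, "score_C1": scores["C1"]}).to_csv(
        f_pred, sep="\t", index_label="sample_id")
    f_auc = out / "classifier_metrics.json"
    f_auc.write_text(json.dumps({"test_auc": auc, "delta": model.delta,
                                 "n_train": len(train), "n_test": len(test)}, indent=2))
    return [f_model, f_pred, f_auc], {"train_frac": cfg.train_frac, "test_auc": auc}


def _stage_network(cfg: PipelineConfig, out: Path, state: dict):
    cohort = _require_cohort(state)
    expr, _ = _expr_clinical(cfg, state)
    labels = state["labels"]
    files, hubs = [], {}
    for subtype in ("C1", "C2"):
        network = net.subtype_network(expr, labels, subtype, cohort.interaction_catalog,
                                      cohort.seed_genes, min_frac=cfg.prevalence,
                                      ci_threshold=cfg.ci_threshold)
        f = out / f"network_{subtype}.tsv"
        network.edges.to_csv(f, sep="\t", index=False)
        files.append(f)
        if network.graph.number_of_nodes():
            res = net.hub_intersection(network, top_k=cfg.hub_top_k)
            hubs[subtype] = {"top_mcc": res.top_mcc, "top_degree": res.top_degree,
                             "hubs": res.intersection}
        state[f"network_{subtype}"] = network
    f_h = out / "network_hubs.json"
    f_h.write_text(json.dumps(hubs, indent=2))
    files.append(f_h)
    return files, {"ci_threshold": cfg.ci_threshold, "prevalence": cfg.prevalence}


def _stage_score(cfg: PipelineConfig, out: Path, state: dict):
    cohort = _require_cohort(state)
    expr, _ = _expr_clinical(cfg, state)
    labels = state["labels"]
    collection = {"signature_program": list(cohort.signature)}
    scores = scoring.score_collection(expr, collection)
    tests = scoring.compare_group_scores(scores, labels, adjust=False)
    f_s = out / "geneset_scores.tsv"
    scores.to_csv(f_s, sep="\t", index_label="set")
    f_t = out / "geneset_group_tests.tsv"
    tests.to_csv(f_t, sep="\t")
    return [f_s, f_t], {"n_sets": len(collection)}


def _stage_survival(cfg: PipelineConfig, out: Path, state: dict):
    _, clinical = _expr_clinical(cfg, state)
    labels = state["labels"]
    table = clinical.table.copy()
    table["subtype"] = labels[table.index]
    clin = ClinicalTable(table)
    curves, lr_stat, lr_p = survival.km_logrank(clin, table["subtype"])
    uni = survival.cox_fit(clin, ["subtype", "age", "grade"], mode="univariate")
    multi = survival.cox_fit(clin, ["subtype", "age", "grade"], mode="multivariate")
    horizons = [t for t in cfg.horizons if t <= table["os_time"].max()]
    nom = survival.build_nomogram(multi, horizons=horizons)
    design = survival.design_matrix(clin, multi.variables)
    risk = nom.linear_predictor(design)
    aucs = {str(int(t)): survival.time_dependent_auc(risk, clin, t) for t in horizons}
    calib = {str(int(t)): survival.calibration_curve(nom, clin, t).to_dict("records")
             for t in horizons}
    results = {
        "logrank": {"statistic": lr_stat, "p": lr_p},
        "univariate": {v: fit.summary.reset_index().to_dict("records") for v, fit in uni.items()},
        "multivariate": multi.summary.reset_index().to_dict("records"),
        "time_dependent_auc": aucs,
        "calibration": calib,
    }
    f = out / "survival_results.json"
    f.write_text(json.dumps(results, indent=2, default=float))
    state["survival_results"] = results
    return [f], {"horizons": horizons, "logrank_p": lr_p}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "subtype": _stage_subtype,
    "classify": _stage_classify,
    "network": _stage_network,
    "score": _stage_score,
    "survival": _stage_survival,
}
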
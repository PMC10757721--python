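"""Synthetic glioma-like cohort generator.

Produces bulk expression + clinical cohorts with the statistical structure
the downstream analyses assume, so every stage can be validated against a
known ground truth:

* two latent subtypes (C1/C2) that shift a signature-gene program,
* planted ligand-receptor pairs co-expressed within C1 through a shared
  latent factor, plus uncoupled decoy pairs in the interaction catalog,
* proportional-hazards survival with a subtype effect and a per-year age
  effect, under independent exponential censoring calibrated to a target
  censoring fraction.

Defaults mirror the glioma study the pipeline re-implements: a 137-gene
signature, a subtype hazard ratio of 5.583 and an age hazard ratio of
1.070 per year.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSignature

log = logging.getLogger(__name__)

BASELINE_LOG2_MEAN = 3.0
BASELINE_MEDIAN_SURVIVAL_DAYS = 1095.0  # 3 years at reference covariates
DECOYS_PER_PLANTED = 3
# Fraction of the signature program elevated in C1; the remainder is
# elevated in C2. A one-sided (all-up) shift would make the signature
# submatrix rank-1, which no two-metagene factorization can label; real
# subtype programs are bidirectional, and the 70/30 split keeps C1 the
# signature-high subtype so label orientation stays well defined.
C1_PROGRAM_FRACTION = 0.7
GRADE_PROBS = {"C1": (0.1, 0.3, 0.6), "C2": (0.4, 0.4, 0.2)}  # WHO II/III/IV


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the generative model; defaults are the study conditions."""

    n_samples: int = 200
    n_genes: int = 500
    n_signature_genes: int = 137
    signature_effect: float = 1.0  # log2 shift of signature genes in C1
    frac_c1: float = 0.5
    n_lr_pairs: int = 10
    lr_coupling: float = 0.9  # within-C1 correlation of a planted pair
    subtype_hazard_ratio: float = 5.583
    age_hazard_ratio_per_year: float = 1.070
    censor_rate: float = 0.3
    noise_sd: float = 1.0  # log2-scale residual SD
    seed: int = 0

    def __post_init__(self) -> None:
        def bad(fieldname, msg):
            raise ValueError(f"CohortConfig.{fieldname}: {msg}")

        for f in ("n_samples", "n_genes", "n_signature_genes"):
            if getattr(self, f) <= 0:
                bad(f, "must be > 0")
        if self.n_lr_pairs < 0:
            bad("n_lr_pairs", "must be >= 0")
        needed = (self.n_signature_genes
                  + (2 + DECOYS_PER_PLANTED) * self.n_lr_pairs)
        if self.n_genes < needed:
            bad("n_genes", f"must be >= {needed} to host signature, pairs and decoys")
        if not 0 < self.frac_c1 < 1:
            bad("frac_c1", "must be in (0,1)")
        if not 0 <= self.lr_coupling <= 1:
            bad("lr_coupling", "must be in [0,1]")
        if self.subtype_hazard_ratio <= 0:
            bad("subtype_hazard_ratio", "must be > 0")
        if self.age_hazard_ratio_per_year <= 0:
            bad("age_hazard_ratio_per_year", "must be > 0")
        if not 0 <= self.censor_rate < 1:
            bad("censor_rate", "must be in [0,1)")
        if self.noise_sd <= 0:
            bad("noise_sd", "must be > 0")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth_labels: pd.Series  # sample -> {C1, C2}
    signature: GeneSignature
    c1_program: list[str] = field(default_factory=list)  # signature genes up in C1
    c2_program: list[str] = field(default_factory=list)  # signature genes up in C2
    seed_genes: list[str] = field(default_factory=list)  # ligand/receptor network seeds
    interaction_catalog: pd.DataFrame = None  # gene_a, gene_b, source
    planted_edges: list[tuple[str, str]] = field(default_factory=list)
    config: CohortConfig = field(repr=False, default=None)


def _gene_names(cfg: CohortConfig):
    sig = [f"SIG{i + 1:04d}" for i in range(cfg.n_signature_genes)]
    lig = [f"LIG{i + 1:03d}" for i in range(cfg.n_lr_pairs)]
    rec = [f"REC{i + 1:03d}" for i in range(cfg.n_lr_pairs)]
    dec = [f"DEC{i + 1:03d}" for i in range(DECOYS_PER_PLANTED * cfg.n_lr_pairs)]
    n_fill = cfg.n_genes - len(sig) - len(lig) - len(rec) - len(dec)
    fill = [f"GEN{i + 1:04d}" for i in range(n_fill)]
    return sig, lig, rec, dec, fill


def _calibrate_censoring(event_times: np.ndarray, target: float) -> float:
    """Exponential censoring rate achieving an expected censored fraction."""

    def censored_frac(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * event_times)))

    lo, hi = 1e-12, 1e-12
    while censored_frac(hi) < target:
        hi *= 10
        if hi > 1e6:  # pragma: no cover - pathological event times
            raise RuntimeError("could not calibrate censoring rate")
    return brentq(lambda r: censored_frac(r) - target, lo, hi)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort from the generative model; reproducible from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sig, lig, rec, dec, fill = _gene_names(cfg)
    genes = sig + lig + rec + dec + fill
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]

    n_c1 = int(round(cfg.frac_c1 * cfg.n_samples))
    n_c1 = min(max(n_c1, 1), cfg.n_samples - 1)
    labels = np.array(["C2"] * cfg.n_samples, dtype=object)
    labels[rng.permutation(cfg.n_samples)[:n_c1]] = "C1"
    is_c1 = labels == "C1"

    log2x = BASELINE_LOG2_MEAN + cfg.noise_sd * rng.standard_normal((cfg.n_genes, cfg.n_samples))
    gene_row = {g: i for i, g in enumerate(genes)}

    # subtype program: most signature genes up in C1, the rest up in C2
    n_c1_prog = int(round(C1_PROGRAM_FRACTION * len(sig)))
    c1_program, c2_program = sig[:n_c1_prog], sig[n_c1_prog:]
    for g in c1_program:
        log2x[gene_row[g], is_c1] += cfg.signature_effect
    for g in c2_program:
        log2x[gene_row[g], ~is_c1] += cfg.signature_effect

    # planted ligand-receptor coupling: shared latent factor within C1
    rho = cfg.lr_coupling
    planted = list(zip(lig, rec))
    for a, b in planted:
        f = rng.standard_normal(int(is_c1.sum()))
        for g in (a, b):
            row = gene_row[g]
            resid = log2x[row, is_c1] - BASELINE_LOG2_MEAN
            log2x[row, is_c1] = BASELINE_LOG2_MEAN + cfg.noise_sd * (
                np.sqrt(rho) * f + np.sqrt(1 - rho) * resid / cfg.noise_sd
            )

    expression = ExpressionMatrix(
        pd.DataFrame(np.exp2(log2x), index=genes, columns=samples), unit="tpm"
    )

    # decoy catalog entries reuse the ligand seeds with uncoupled partners,
    # so they survive the seed-endpoint candidate filter downstream
    catalog_rows = [(a, b, "planted") for a, b in planted]
    for k, ligand in enumerate(lig):
        for j in range(DECOYS_PER_PLANTED):
            catalog_rows.append((ligand, dec[DECOYS_PER_PLANTED * k + j], "decoy"))
    catalog = pd.DataFrame(catalog_rows, columns=["gene_a", "gene_b", "source"])

    # clinical covariates
    age = rng.uniform(20, 80, cfg.n_samples)
    grade = np.empty(cfg.n_samples, dtype=int)
    for i, lab in enumerate(labels):
        grade[i] = rng.choice([2, 3, 4], p=GRADE_PROBS[lab])

    # proportional-hazards survival with exponential baseline
    lp = (np.log(cfg.subtype_hazard_ratio) * is_c1.astype(float)
          + np.log(cfg.age_hazard_ratio_per_year) * (age - age.mean()))
    lam0 = np.log(2.0) / BASELINE_MEDIAN_SURVIVAL_DAYS
    event_t = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    if cfg.censor_rate > 0:
        cens_rate = _calibrate_censoring(event_t, cfg.censor_rate)
        cens_t = rng.exponential(1.0 / cens_rate, cfg.n_samples)
        os_time = np.minimum(event_t, cens_t)
        os_event = (event_t <= cens_t).astype(int)
    else:
        os_time, os_event = event_t, np.ones(cfg.n_samples, dtype=int)

    clinical = ClinicalTable(pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": age,
            "grade": grade,
            "subtype_true": labels,
        },
        index=pd.Index(samples, name="sample_id"),
    ))

    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        truth_labels=pd.Series(labels, index=samples, name="subtype_true"),
        signature=GeneSignature("synthetic_signature", sig),
        c1_program=c1_program,
        c2_program=c2_program,
        seed_genes=lig + rec,
        interaction_catalog=catalog,
        planted_edges=planted,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as TSVs plus a JSON manifest; returns the manifest."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    files = {
        "expression": "expression.tsv",
        "clinical": "clinical.tsv",
        "catalog": "catalog.tsv",
        "truth": "truth_labels.tsv",
        "signature": "signature.txt",
        "seed_genes": "seed_genes.txt",
    }
    try:
        cohort.expression.values.to_csv(directory / files["expression"], sep="\t",
                                        index_label="gene_id")
        cohort.clinical.table.to_csv(directory / files["clinical"], sep="\t",
                                     index_label="sample_id")
        cohort.interaction_catalog.to_csv(directory / files["catalog"], sep="\t", index=False)
        cohort.truth_labels.rename("subtype").to_csv(directory / files["truth"], sep="\t",
                                                     index_label="sample_id")
        (directory / files["signature"]).write_text("\n".join(cohort.signature.symbols) + "\n")
        (directory / files["seed_genes"]).write_text("\n".join(cohort.seed_genes) + "\n")
        manifest = {
            "config": dataclasses.asdict(cohort.config) if cohort.config else None,
            "files": files,
            "planted_edges": [list(e) for e in cohort.planted_edges],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Round-trip loader for :func:`write_cohort` output."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    f = manifest["files"]
    expr = pd.read_csv(directory / f["expression"], sep="\t", index_col=0)
    expr.index.name = None
    clin = pd.read_csv(directory / f["clinical"], sep="\t", index_col=0)
    clin.index.name = "sample_id"
    truth = pd.read_csv(directory / f["truth"], sep="\t", index_col=0)["subtype"]
    catalog = pd.read_csv(directory / f["catalog"], sep="\t")
    signature = [ln for ln in (directory / f["signature"]).read_text().splitlines() if ln]
    seeds = [ln for ln in (directory / f["seed_genes"]).read_text().splitlines() if ln]
    cfg = CohortConfig(**manifest["config"]) if manifest.get("config") else None
    n_c1_prog = int(round(C1_PROGRAM_FRACTION * len(signature)))
    return SyntheticCohort(
        expression=ExpressionMatrix(expr, "tpm"),
        clinical=ClinicalTable(clin),
        truth_labels=truth,
        signature=GeneSignature("synthetic_signature", signature),
        c1_program=signature[:n_c1_prog],
        c2_program=signature[n_c1_prog:],
        seed_genes=seeds,
        interaction_catalog=catalog,
        planted_edges=[tuple(e) for e in manifest["planted_edges"]],
        config=cfg,
    )
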
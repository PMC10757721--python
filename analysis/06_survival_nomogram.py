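"""Survival evaluation of the discovered subtypes: KM/log-rank, univariate
and multivariate Cox, a points-based nomogram, time-dependent AUC at 1/3
years and a calibration curve.

Reads scratch/analysis/cohort/ and subtype_labels.tsv; writes
survival_results.json under results/analysis/.
"""
import json
from pathlib import Path

import pandas as pd

from efferotype.datatypes import ClinicalTable
from efferotype.io import filter_short_survivors
from efferotype.survival import (
    build_nomogram,
    calibration_curve,
    cox_fit,
    design_matrix,
    km_logrank,
    time_dependent_auc,
)
from efferotype.synthetic import read_cohort

COHORT = Path("scratch/analysis/cohort")
OUT = Path("results/analysis")
HORIZONS = [365.0, 1095.0]


def main() -> None:
    cohort = read_cohort(COHORT)
    labels = pd.read_csv(OUT / "subtype_labels.tsv", sep="\t", index_col=0)["subtype"]
    clinical = filter_short_survivors(cohort.clinical, 30)
    table = clinical.table.drop(columns="subtype_true").copy()
    table["subtype"] = labels[table.index]
    clin = ClinicalTable(table)

    _, lr_stat, lr_p = km_logrank(clin, table["subtype"])
    print(f"log-rank C1 vs C2: chi2 {lr_stat:.1f}, p {lr_p:.3g}")

    uni = cox_fit(clin, ["subtype", "age", "grade"], mode="univariate")
    multi = cox_fit(clin, ["subtype", "age", "grade"], mode="multivariate")
    for term in multi.summary.index:
        hr, (lo, hi) = multi.hazard_ratio(term), multi.ci(term)
        print(f"  multivariate {term}: HR {hr:.3f} ({lo:.3f}-{hi:.3f})")

    horizons = [t for t in HORIZONS if t <= table["os_time"].max()]
    nomogram = build_nomogram(multi, horizons=horizons)
    design = design_matrix(clin, multi.variables)
    risk = nomogram.linear_predictor(design)
    aucs = {int(t): time_dependent_auc(risk, clin, t) for t in horizons}
    for t, a in aucs.items():
        print(f"  nomogram time-dependent AUC at {t} d: {a:.3f}")
    calib = {int(t): calibration_curve(nomogram, clin, t).to_dict("records")
             for t in horizons}

    out = {
        "logrank": {"statistic": lr_stat, "p": lr_p},
        "univariate": {v: f.summary.reset_index().to_dict("records") for v, f in uni.items()},
        "multivariate": multi.summary.reset_index().to_dict("records"),
        "time_dependent_auc": aucs,
        "calibration": calib,
    }
    (OUT / "survival_results.json").write_text(json.dumps(out, indent=2, default=float))
    print(f"results -> {OUT / 'survival_results.json'}")


if __name__ == "__main__":
    main()
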
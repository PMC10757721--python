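"""Subtype transfer: fit a nearest-shrunken-centroid classifier on a 70%
stratified training split of the discovered labels and evaluate ROC AUC on
the held-out 30%.

Reads scratch/analysis/cohort/ and subtype_labels.tsv; writes the model and
test metrics under results/analysis/.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from efferotype.classify import fit_centroid_classifier, predict_subtype, roc_auc
from efferotype.datatypes import ExpressionMatrix
from efferotype.io import stratified_split
from efferotype.synthetic import read_cohort

COHORT = Path("scratch/analysis/cohort")
OUT = Path("results/analysis")
SEED = 7


def main() -> None:
    cohort = read_cohort(COHORT)
    expr = ExpressionMatrix(np.log2(cohort.expression.values + 1.0), "log2tpm")
    labels = pd.read_csv(OUT / "subtype_labels.tsv", sep="\t", index_col=0)["subtype"]

    train, test = stratified_split(expr.sample_ids, labels[expr.sample_ids], 0.7, seed=SEED)
    model = fit_centroid_classifier(expr.subset_samples(train), labels[train], seed=SEED)
    pred, scores = predict_subtype(model, expr.subset_samples(test))
    auc = roc_auc(scores["C1"], (labels[test] == "C1").astype(int))
    accuracy = float((pred == labels[test]).mean())

    model.to_json(OUT / "centroid_model.json")
    metrics = {"test_auc": auc, "test_accuracy": accuracy, "delta": model.delta,
               "n_train": len(train), "n_test": len(test),
               "n_active_genes": len(model.active_genes)}
    (OUT / "classifier_metrics.json").write_text(json.dumps(metrics, indent=2))
    print(f"shrinkage delta: {model.delta:.3f} "
          f"({len(model.active_genes)} genes kept of {len(model.gene_ids)})")
    print(f"held-out accuracy: {accuracy:.3f}  AUC: {auc:.3f}")


if __name__ == "__main__":
    main()
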
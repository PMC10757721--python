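"""Subtype transfer via nearest shrunken centroids.

The classifier of the "prediction analysis for microarrays" family: per-gene
class-centroid deviations from the overall centroid are standardized by the
pooled within-class SD (plus a fudge constant), soft-thresholded by a
shrinkage amount delta, and samples are assigned to the class whose shrunken
centroid minimizes a diagonal-covariance discriminant score with a prior
term. Delta is tuned by stratified cross-validated accuracy.

A literal partitioning-around-medoids assignment (nearest training medoid
by Euclidean distance) is also provided, since the source study's naming is
ambiguous between the two methods of that acronym.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import ExpressionMatrix


@dataclass
class CentroidModel:
    gene_ids: list[str]
    classes: list[str]
    overall_centroid: np.ndarray  # genes
    shrunken_centroids: np.ndarray  # genes x classes
    s: np.ndarray  # pooled within-class SD per gene
    s0: float  # fudge (median of s)
    delta: float
    priors: np.ndarray  # per class
    unit: str = "log2tpm"
    cv_accuracy: dict = field(default_factory=dict)

    @property
    def active_genes(self) -> list[str]:
        """Genes whose shrunken deviation is nonzero for some class."""
        dev = self.shrunken_centroids - self.overall_centroid[:, None]
        return [g for g, keep in zip(self.gene_ids, (np.abs(dev) > 0).any(axis=1)) if keep]

    def to_json(self, path) -> None:
        obj = {
            "gene_ids": self.gene_ids,
            "classes": self.classes,
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunken_centroids": self.shrunken_centroids.tolist(),
            "s": self.s.tolist(),
            "s0": self.s0,
            "delta": self.delta,
            "priors": self.priors.tolist(),
            "unit": self.unit,
            "cv_accuracy": {str(k): v for k, v in self.cv_accuracy.items()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            gene_ids=obj["gene_ids"],
            classes=obj["classes"],
            overall_centroid=np.array(obj["overall_centroid"]),
            shrunken_centroids=np.array(obj["shrunken_centroids"]),
            s=np.array(obj["s"]),
            s0=obj["s0"],
            delta=obj["delta"],
            priors=np.array(obj["priors"]),
            unit=obj.get("unit", "log2tpm"),
            cv_accuracy={float(k): v for k, v in obj.get("cv_accuracy", {}).items()},
        )


def _shrink(X: np.ndarray, y: np.ndarray, classes, delta: float):
    """Return (overall centroid, shrunken class centroids, s, s0, priors)."""
    n, n_genes = len(y), X.shape[1]
    xbar = X.mean(axis=0)
    cents = np.stack([X[y == k].mean(axis=0) for k in classes], axis=1)  # genes x K
    nk = np.array([(y == k).sum() for k in classes])
    # pooled within-class SD
    ss = np.zeros(n_genes)
    for j, k in enumerate(classes):
        ss += ((X[y == k] - cents[:, j]) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    denom = (s + s0)[:, None] * mk[None, :]
    d = (cents - xbar[:, None]) / denom
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunken = xbar[:, None] + denom * d_shr
    priors = nk / n
    return xbar, shrunken, s, s0, priors


def _discriminant(X: np.ndarray, model: CentroidModel) -> np.ndarray:
    """delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i+s0)^2 - 2 log pi_k."""
    denom2 = (model.s + model.s0) ** 2
    scores = np.empty((X.shape[0], len(model.classes)))
    for j in range(len(model.classes)):
        diff = X - model.shrunken_centroids[:, j][None, :]
        scores[:, j] = (diff ** 2 / denom2[None, :]).sum(axis=1) - 2.0 * np.log(model.priors[j])
    return scores


def fit_centroid_classifier(expr: ExpressionMatrix, labels, delta_grid=None,
                            cv_folds: int = 5, seed: int = 0) -> CentroidModel:
    """Fit nearest shrunken centroids with cross-validated shrinkage.

    ``delta_grid`` defaults to 30 values spanning 0 to the largest absolute
    standardized deviation. Ties in CV accuracy resolve to the larger delta
    (the sparser model).
    """
    labels = pd.Series(labels, index=expr.sample_ids) if not isinstance(labels, pd.Series) else labels
    y = labels.loc[expr.sample_ids].astype(str).to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {k: int((y == k).sum()) for k in classes}
    small = [k for k, c in counts.items() if c < max(2, cv_folds)]
    if small:
        raise ValueError(f"classes with fewer than {max(2, cv_folds)} samples: {small}")
    X = expr.values.to_numpy(dtype=float).T  # samples x genes

    xbar, shrunken, s, s0, priors = _shrink(X, y, classes, 0.0)
    dmax = float(np.max(np.abs((shrunken - xbar[:, None]) / ((s + s0)[:, None]))))
    if delta_grid is None:
        delta_grid = np.linspace(0.0, dmax, 30)

    cv_acc: dict[float, float] = {}
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for delta in delta_grid:
        correct = 0
        for tr, te in folds:
            m = _fit_at_delta(X[tr], y[tr], classes, float(delta), expr.gene_ids, expr.unit)
            pred = np.array(classes)[np.argmin(_discriminant(X[te], m), axis=1)]
            correct += int((pred == y[te]).sum())
        cv_acc[float(delta)] = correct / len(y)
    best_acc = max(cv_acc.values())
    best_delta = max(d for d, a in cv_acc.items() if a == best_acc)

    model = _fit_at_delta(X, y, classes, best_delta, expr.gene_ids, expr.unit)
    model.cv_accuracy = cv_acc
    return model


def _fit_at_delta(X, y, classes, delta, gene_ids, unit) -> CentroidModel:
    xbar, shrunken, s, s0, priors = _shrink(X, y, classes, delta)
    return CentroidModel(
        gene_ids=list(gene_ids), classes=list(classes), overall_centroid=xbar,
        shrunken_centroids=shrunken, s=s, s0=s0, delta=delta, priors=priors, unit=unit,
    )


def predict_subtype(model: CentroidModel, expr: ExpressionMatrix):
    """Assign each sample to its nearest shrunken centroid.

    Returns ``(labels, scores)``: a Series of class names and a DataFrame of
    per-class softmax probabilities derived from the discriminant scores
    (the first class column serves as the continuous score for ROC).
    Equal discriminant scores break to the lexicographically first class
    with a warning.
    """
    missing = [g for g in model.active_genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"expression matrix lacks model genes: {missing[:20]}")
    if expr.unit != model.unit:
        raise ValueError(f"unit mismatch: model trained on {model.unit!r}, got {expr.unit!r}")
    # all model genes are needed for the discriminant; fully shrunk genes
    # contribute a class-independent constant so zero-fill any absent ones
    X = np.zeros((expr.n_samples, len(model.gene_ids)))
    present = [i for i, g in enumerate(model.gene_ids) if g in expr.values.index]
    sub = expr.values.reindex([model.gene_ids[i] for i in present]).to_numpy(dtype=float).T
    X[:, present] = sub
    delta_scores = _discriminant(X, model)
    ties = np.sum(delta_scores == delta_scores.min(axis=1, keepdims=True), axis=1) > 1
    if ties.any():
        warnings.warn(f"{int(ties.sum())} samples with tied discriminant scores; "
                      "assigned to the lexicographically first class")
    labels = pd.Series(np.array(model.classes)[np.argmin(delta_scores, axis=1)],
                       index=expr.sample_ids, name="subtype")
    # softmax of -delta/2 gives a monotone probability-like score
    z = -0.5 * (delta_scores - delta_scores.min(axis=1, keepdims=True))
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    scores = pd.DataFrame(p, index=expr.sample_ids, columns=model.classes)
    return labels, scores


def roc_auc(scores, truth_binary) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth_binary).astype(int)
    if len(np.unique(truth)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(truth, scores))


def fit_medoid_classifier(expr: ExpressionMatrix, labels) -> dict:
    """Literal partitioning-around-medoids flavour: per-class medoid
    (member minimizing summed Euclidean distance to its class)."""
    labels = pd.Series(labels, index=expr.sample_ids) if not isinstance(labels, pd.Series) else labels
    X = expr.values.to_numpy(dtype=float).T
    medoids = {}
    for k in sorted(labels.unique()):
        idx = np.flatnonzero((labels.loc[expr.sample_ids] == k).to_numpy())
        sub = X[idx]
        dist = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=2).sum(axis=1)
        medoids[str(k)] = sub[int(np.argmin(dist))]
    return {"gene_ids": expr.gene_ids, "medoids": medoids, "unit": expr.unit}


def predict_medoid(model: dict, expr: ExpressionMatrix) -> pd.Series:
    X = expr.values.reindex(model["gene_ids"]).fillna(0.0).to_numpy(dtype=float).T
    classes = sorted(model["medoids"])
    D = np.stack([np.linalg.norm(X - model["medoids"][k][None, :], axis=1) for k in classes], axis=1)
    return pd.Series(np.array(classes)[np.argmin(D, axis=1)], index=expr.sample_ids, name="subtype")
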
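"""Tabular I/O, TPM conversion, cohort filters and the train/test split.

All tables are plain TSV/CSV with a header row. Expression files have the
gene id in the first column and one column per sample; clinical files are
indexed by sample id. GMT files follow the Broad convention
(set name <tab> description <tab> member genes...).
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, FormatError, GeneSignature

log = logging.getLogger(__name__)

TPM_SCALE = 1e6


def _sep_for(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression(path, unit: str = "tpm") -> ExpressionMatrix:
    """Read a gene x sample expression table.

    Duplicate gene symbols are collapsed by taking the per-sample maximum
    (the usual probe-collapse convention) and a warning is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        bad = df.isna().stack()
        gene, sample = bad[bad].index[0]
        raise FormatError(f"{path}: missing value at gene {gene!r}, sample {sample!r}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        log.warning("%s: %d duplicate gene rows collapsed by max", path, n_dup)
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(df, unit)


def write_expression(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    expr.values.to_csv(path, sep=_sep_for(path), index_label="gene_id")


def read_clinical(path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    path = Path(path)
    clinical.table.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def read_gene_list(path, name: str | None = None) -> GeneSignature:
    """Plain-text gene list, one symbol per line; blank lines ignored."""
    path = Path(path)
    symbols = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    return GeneSignature(name or path.stem, symbols)


def write_gene_list(signature: GeneSignature, path) -> None:
    Path(path).write_text("\n".join(signature.symbols) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into {set name: member list}."""
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {ln[:80]!r}")
        name, members = parts[0], [g for g in parts[2:] if g]
        if not members:
            raise FormatError(f"GMT set {name!r} is empty")
        sets[name] = list(dict.fromkeys(members))
    return sets


def counts_to_tpm(expr: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to transcripts-per-million.

    Per sample: rate_g = count_g / length_g (length in bp); the rates are
    rescaled to sum to 1e6. Every output column therefore sums to 1e6 to
    within floating tolerance.
    """
    if expr.unit != "counts":
        raise ValueError(f"counts_to_tpm expects counts, got {expr.unit!r}")
    lengths = pd.Series(gene_lengths).astype(float)
    missing = [g for g in expr.gene_ids if g not in lengths.index]
    if missing:
        raise FormatError(f"gene lengths missing for: {missing[:20]}")
    lengths = lengths.loc[expr.gene_ids]
    if (lengths <= 0).any():
        raise FormatError(f"non-positive gene lengths for: {lengths.index[lengths <= 0].tolist()}")
    rates = expr.values.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise FormatError(f"samples with zero total rate (all-zero counts): {zero}")
    tpm = rates.div(totals, axis=1) * TPM_SCALE
    return ExpressionMatrix(tpm, "tpm")


def log2_tpm(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    if expr.unit != "tpm":
        raise ValueError(f"log2_tpm expects tpm, got {expr.unit!r}")
    return ExpressionMatrix(np.log2(expr.values + pseudocount), "log2tpm")


def filter_short_survivors(clinical: ClinicalTable, min_days: float = 30) -> ClinicalTable:
    """Drop samples that died or were censored before ``min_days``.

    Samples with os_time strictly below the threshold are removed, so a
    survival time of exactly ``min_days`` is retained.
    """
    keep = clinical.table["os_time"] >= min_days
    removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(f"no samples with os_time >= {min_days}; cohort unusable")
    if removed:
        log.info("filter_short_survivors: removed %d of %d samples (< %s days)",
                 removed, len(keep), min_days)
    return ClinicalTable(clinical.table.loc[keep])


def stratified_split(sample_ids, labels, train_frac: float = 0.7, seed: int = 0):
    """Split samples into train/test preserving label proportions.

    Returns ``(train_ids, test_ids)``, disjoint and exhaustive, with each
    label's train share within one sample of ``train_frac``. Reproducible
    from ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0,1), got {train_frac}")
    sample_ids = list(sample_ids)
    labels = pd.Series(list(labels), index=sample_ids)
    if len(labels) != len(sample_ids):
        raise ValueError("labels must cover every sample")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for lab in sorted(labels.unique()):
        members = [s for s in sample_ids if labels[s] == lab]
        if len(members) < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 samples; cannot stratify")
        perm = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[i] for i in perm[:n_train])
        test.extend(members[i] for i in perm[n_train:])
    # keep the original cohort order for determinism of downstream iteration
    order = {s: i for i, s in enumerate(sample_ids)}
    return sorted(train, key=order.get), sorted(test, key=order.get)
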
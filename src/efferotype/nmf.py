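"""Consensus NMF subtype discovery.

Non-negative matrix factorization with generalized Kullback-Leibler
divergence and Brunet-style multiplicative updates, repeated over random
restarts to form a sample x sample consensus (co-clustering) matrix.
Cluster-number stability is summarized by the cophenetic correlation of the
consensus dissimilarities and by a dispersion coefficient, and the rank is
chosen as the last rank before the cophenetic coefficient first decreases.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, GeneSignature

log = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class FactorPair:
    W: np.ndarray  # genes x rank
    H: np.ndarray  # rank x samples
    rank: int
    objective_trace: np.ndarray  # per-iteration generalized KL divergence


@dataclass
class ConsensusResult:
    rank: int
    consensus: np.ndarray  # samples x samples, symmetric, unit diagonal
    cophenetic: float
    dispersion: float
    labels: np.ndarray  # per-sample cluster ids in 1..rank
    sample_ids: list


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum V log(V/WH) - V + WH."""
    WH = np.maximum(WH, EPS)
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(np.sum(term - V + WH))


def nmf_factorize(V: np.ndarray, rank: int, seed: int = 0,
                  max_iter: int = 500, tol: float = 1e-5) -> FactorPair:
    """Multiplicative-update KL-NMF.

    Updates (Brunet et al. form)::

        H <- H * (W^T (V / WH)) / (W^T 1)
        W <- W * ((V / WH) H^T) / (1 H^T)

    which never increase the generalized KL objective. Iteration stops at
    ``max_iter`` or when the relative objective change drops below ``tol``.
    Factors are floored at a small epsilon to avoid division by zero.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ValueError("NMF input must be non-negative")
    n, m = V.shape
    if not 2 <= rank < min(n, m):
        raise ValueError(f"rank must satisfy 2 <= rank < min(dims)={min(n, m)}, got {rank}")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.1, 1.0, (n, rank)) * scale
    H = rng.uniform(0.1, 1.0, (rank, m)) * scale

    trace = [kl_divergence(V, W @ H)]
    for _ in range(max_iter):
        WH = np.maximum(W @ H, EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], EPS)
        H = np.maximum(H, EPS)
        WH = np.maximum(W @ H, EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], EPS)
        W = np.maximum(W, EPS)
        obj = kl_divergence(V, W @ H)
        prev = trace[-1]
        trace.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0):
            break
    return FactorPair(W=W, H=H, rank=rank, objective_trace=np.array(trace))


def connectivity_matrix(labels) -> np.ndarray:
    """Binary co-membership matrix: 1 iff two samples share a label."""
    lab = np.asarray(labels)
    return (lab[:, None] == lab[None, :]).astype(float)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus dissimilarity structure.

    Pearson correlation between the condensed dissimilarities 1 - consensus
    and the cophenetic distances of their average-linkage dendrogram. A
    constant consensus has no dispersion to correlate; 0 is returned with a
    warning.
    """
    d = squareform(1.0 - np.asarray(consensus, dtype=float), checks=False)
    Z = average(d)
    coph = cophenet(Z)
    if np.std(d) == 0 or np.std(coph) == 0:
        warnings.warn("degenerate (constant) consensus matrix; cophenetic coefficient set to 0")
        return 0.0
    return float(np.corrcoef(d, coph)[0, 1])


def dispersion_coefficient(consensus: np.ndarray) -> float:
    """(1/n^2) sum 4 (c_ij - 1/2)^2 in [0,1]; 1 iff consensus is binary."""
    c = np.asarray(consensus, dtype=float)
    n = c.shape[0]
    return float(np.sum(4.0 * (c - 0.5) ** 2) / (n * n))


def consensus_over_restarts(V: np.ndarray, rank: int, n_restarts: int = 30,
                            base_seed: int = 0, sample_ids=None,
                            max_iter: int = 500, tol: float = 1e-5) -> ConsensusResult:
    """Average restart connectivity matrices into a consensus and label it.

    Per-restart labels are the argmax over the rank coefficients of each
    sample (columns of H); consensus-level labels come from average-linkage
    clustering of 1 - consensus cut at ``rank`` clusters. Restarts whose
    labelling leaves a cluster empty are discarded with a warning.
    """
    if n_restarts < 2:
        raise ValueError("need at least 2 restarts for a consensus")
    V = np.asarray(V, dtype=float)
    m = V.shape[1]
    acc = np.zeros((m, m))
    used = 0
    for r in range(n_restarts):
        fit = nmf_factorize(V, rank, seed=base_seed + r, max_iter=max_iter, tol=tol)
        lab = np.argmax(fit.H, axis=0)
        if len(np.unique(lab)) < rank:
            log.warning("restart %d produced an empty cluster at rank %d; discarded", r, rank)
            continue
        acc += connectivity_matrix(lab)
        used += 1
    if used == 0:
        raise RuntimeError(f"all {n_restarts} restarts degenerate at rank {rank}")
    consensus = acc / used
    np.fill_diagonal(consensus, 1.0)

    d = squareform(1.0 - consensus, checks=False)
    Z = average(d)
    labels = fcluster(Z, t=rank, criterion="maxclust")
    return ConsensusResult(
        rank=rank,
        consensus=consensus,
        cophenetic=cophenetic_coefficient(consensus),
        dispersion=dispersion_coefficient(consensus),
        labels=labels,
        sample_ids=list(sample_ids) if sample_ids is not None else list(range(m)),
    )


def select_rank(cophenetic_by_rank: dict[int, float]) -> int:
    """Rank-selection rule: the last rank before the cophenetic coefficient
    first strictly decreases, scanning ranks in increasing order. If the
    coefficient never decreases, the largest rank is returned with a
    warning."""
    ranks = sorted(cophenetic_by_rank)
    if len(ranks) == 1:
        warnings.warn("only one rank evaluated; returning it")
        return ranks[0]
    for prev, cur in zip(ranks, ranks[1:]):
        if cophenetic_by_rank[cur] < cophenetic_by_rank[prev]:
            return prev
    warnings.warn("cophenetic coefficient never decreased; returning the largest rank")
    return ranks[-1]


def orient_labels(labels, expr: ExpressionMatrix, signature: GeneSignature,
                  sample_ids=None) -> pd.Series:
    """Name two clusters so C1 is the signature-high (efferocytosis-high) one.

    With more than two clusters the labels are returned as C1..Ck in
    decreasing mean signature expression, with a warning. Ties break on the
    first sample id for determinism.
    """
    sample_ids = list(sample_ids) if sample_ids is not None else expr.sample_ids
    lab = pd.Series(np.asarray(labels), index=sample_ids)
    sig_genes = [g for g in signature if g in expr.values.index]
    if not sig_genes:
        raise ValueError("no signature genes present in the expression matrix")
    mean_sig = expr.values.loc[sig_genes, sample_ids].mean(axis=0)
    uniq = sorted(lab.unique())
    if len(uniq) != 2:
        warnings.warn(f"expected 2 clusters, got {len(uniq)}; naming C1..C{len(uniq)}")
    order = sorted(
        uniq,
        key=lambda k: (-float(mean_sig[lab == k].mean()),
                       str(lab.index[lab == k][0])),
    )
    mapping = {k: f"C{i + 1}" for i, k in enumerate(order)}
    return lab.map(mapping)


def subtype_cohort(expr: ExpressionMatrix, signature: GeneSignature,
                   ranks=range(2, 7), n_restarts: int = 30, base_seed: int = 0,
                   max_iter: int = 500, tol: float = 1e-5):
    """End-to-end discovery: consensus per rank, rank selection, C1/C2 naming.

    The factorized matrix is the signature-gene submatrix, the program the
    subtypes are defined on. Returns ``(labels, results_by_rank, chosen_rank)``.
    """
    genes = [g for g in signature if g in expr.values.index]
    if len(genes) < 2:
        raise ValueError("signature has fewer than 2 genes present in the matrix")
    V = expr.values.loc[genes].to_numpy(dtype=float)
    keep = V.sum(axis=1) > 0
    if not keep.all():
        log.warning("dropping %d all-zero signature genes before NMF", int((~keep).sum()))
        V = V[keep]
    results = {}
    for rank in ranks:
        results[rank] = consensus_over_restarts(
            V, rank, n_restarts=n_restarts, base_seed=base_seed + 1000 * rank,
            sample_ids=expr.sample_ids, max_iter=max_iter, tol=tol)
    chosen = select_rank({r: res.cophenetic for r, res in results.items()})
    labels = orient_labels(results[chosen].labels, expr, signature)
    return labels, results, chosen
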
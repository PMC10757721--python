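"""Rank-based gene-set scoring.

Two statistics are provided:

* a per-sample single-sample enrichment score (the rank-weighted
  running-sum statistic): genes are ranked within each sample, and the
  score integrates the difference between the weighted in-set and uniform
  out-of-set empirical CDFs along the ranking;
* preranked two-group GSEA: the classic weighted Kolmogorov-Smirnov
  enrichment score on an externally supplied gene ranking, with gene-label
  permutation significance and sign-matched normalization (NES).

The per-sample statistic is used where the source study ran per-sample set
scoring; it is fully determined by ranks (no density estimation), so
method tags record it as ``ssgsea`` and scores are compared only within
method.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


@dataclass
class GseaResult:
    es: float
    nes: float
    p_value: float
    n_perm: int
    flagged: bool = False  # set when the gene set was too small to trust


def _running_score(order_stats: np.ndarray, in_set: np.ndarray, weight: float):
    """Signed maximal deviation of the weighted KS running sum.

    ``order_stats`` are the ranking statistics already sorted descending;
    ``in_set`` is the aligned boolean membership mask.
    """
    n = len(order_stats)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must be a non-empty proper subset of the ranked genes")
    w = np.abs(order_stats) ** weight
    w_hit = np.where(in_set, w, 0.0)
    denom_hit = w_hit.sum()
    if denom_hit == 0:
        # all in-set weights zero (e.g. zero stats): fall back to uniform
        w_hit = in_set.astype(float)
        denom_hit = w_hit.sum()
    p_hit = np.cumsum(w_hit) / denom_hit
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    dev = p_hit - p_miss
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]), dev


def ssgsea_score(expr: ExpressionMatrix, gene_set, alpha: float = 0.25) -> pd.Series:
    """Per-sample rank-weighted enrichment score for one gene set.

    Within each sample, genes are ranked by expression (descending); rank
    values N..1 raised to ``alpha`` weight the in-set ECDF. With alpha = 0
    the score depends on the within-sample ordering only.
    """
    genes = list(expr.gene_ids)
    in_set_all = pd.Index(genes).isin(set(gene_set))
    if not in_set_all.any():
        raise ValueError("gene set does not intersect the expression matrix")
    if in_set_all.all():
        raise ValueError("gene set covers every gene; out-of-set ECDF undefined")
    n = len(genes)
    scores = {}
    vals = expr.values.to_numpy(dtype=float)
    for j, sample in enumerate(expr.sample_ids):
        order = np.argsort(-vals[:, j], kind="stable")
        rank_value = np.arange(n, 0, -1, dtype=float)  # N for the top gene
        in_set = in_set_all[order]
        # integrate the full deviation profile (not its extremum, as in the
        # two-group ES): the per-sample statistic is the summed difference
        w = rank_value ** alpha
        w_hit = np.where(in_set, w, 0.0)
        p_hit = np.cumsum(w_hit) / w_hit.sum()
        p_miss = np.cumsum(~in_set) / (n - int(in_set.sum()))
        scores[sample] = float(np.sum(p_hit - p_miss))
    return pd.Series(scores, name="ssgsea")


def score_collection(expr: ExpressionMatrix, collection: dict[str, list[str]],
                     alpha: float = 0.25) -> pd.DataFrame:
    """ssGSEA scores for every set in a GMT-style collection (set x sample)."""
    rows = {}
    for name, members in collection.items():
        rows[name] = ssgsea_score(expr, members, alpha=alpha)
    return pd.DataFrame(rows).T


def preranked_gsea(ranked_stats: pd.Series, gene_set, n_perm: int = 1000,
                   seed: int = 0, weight_p: float = 1.0) -> GseaResult:
    """Classic preranked GSEA with gene-label permutation significance.

    ES is the signed maximal deviation of the weighted running sum over the
    ranking (descending by statistic). The null re-draws the set positions
    uniformly; NES = ES / mean(|null ES| of the same sign) and
    p = (1 + #{|null| >= |ES|, same sign}) / (1 + #same-sign nulls).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    stats_sorted = ranked_stats.sort_values(ascending=False, kind="stable")
    genes = stats_sorted.index
    in_set = genes.isin(set(gene_set)).astype(bool)
    n_hit = int(in_set.sum())
    flagged = False
    if n_hit < 2:
        warnings.warn("gene set has fewer than 2 members in the ranking; result flagged")
        flagged = True
    order_stats = stats_sorted.to_numpy(dtype=float)
    es, _ = _running_score(order_stats, np.asarray(in_set), weight_p)

    rng = np.random.default_rng(seed)
    n = len(genes)
    null = np.empty(n_perm)
    for b in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hit, replace=False)] = True
        null[b], _ = _running_score(order_stats, mask, weight_p)
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, dtype=bool)
    n_same = int(same_sign.sum())
    mean_same = float(np.mean(np.abs(null[same_sign]))) if n_same else np.nan
    nes = es / mean_same if (n_same and mean_same > 0) else 0.0
    p = (1 + int(np.sum(np.abs(null[same_sign]) >= abs(es)))) / (1 + n_same) if n_same else 1.0
    return GseaResult(es=es, nes=nes, p_value=p, n_perm=n_perm, flagged=flagged)


def compare_group_scores(scores: pd.DataFrame, labels, adjust: bool = False) -> pd.DataFrame:
    """Per-set two-group Wilcoxon rank-sum (or Kruskal-Wallis for >2 groups).

    ``scores`` is set x sample; ``labels`` maps samples to groups. Optional
    Benjamini-Hochberg adjustment across sets.
    """
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    members = {g: [s for s in scores.columns if labels.get(s) == g] for g in groups}
    empty = [g for g, m in members.items() if not m]
    if empty:
        raise ValueError(f"groups without samples: {empty}")
    rows = []
    for name, row in scores.iterrows():
        vecs = [row[m].to_numpy(dtype=float) for g, m in members.items()]
        flat = np.concatenate(vecs)
        if np.ptp(flat) == 0:  # identical scores everywhere: no evidence
            stat, p = 0.0, 1.0
        elif len(groups) == 2:
            stat, p = stats.mannwhitneyu(vecs[0], vecs[1], alternative="two-sided")
        else:
            stat, p = stats.kruskal(*vecs)
        rows.append({"set": name, "statistic": float(stat), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("set")
    if adjust:
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
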
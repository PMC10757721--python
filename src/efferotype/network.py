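"""Discretized-concordance immune regulation networks and hub detection.

Per-gene expression is discretized into low/mid/high tertiles; genes pass a
prevalence filter (at least 66% of samples mid-or-high); candidate catalog
pairs touching a ligand/receptor seed are scored with a concordance index

    CI = (n_HH + n_LL) / (n_LH + n_HL)

over the samples where neither gene is mid; edges with CI strictly above 1
enter the network and isolated nodes are pruned. Hubs are ranked by Maximal
Clique Centrality (sum over maximal cliques containing the node of
(|clique|-1)!) and by degree, and the two top-k lists are intersected.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

log = logging.getLogger(__name__)

LOW, MID, HIGH = "low", "mid", "high"


@dataclass
class DiscretizedMatrix:
    categories: pd.DataFrame  # genes x samples of {low, mid, high}
    boundaries: pd.DataFrame  # genes x (low_upper, high_lower) rank cutoffs

    @property
    def gene_ids(self):
        return list(self.categories.index)

    @property
    def sample_ids(self):
        return list(self.categories.columns)


@dataclass
class ImmuneNetwork:
    graph: nx.Graph  # edges carry n_hh, n_ll, n_lh, n_hl, ci
    subtype: str = ""

    @property
    def nodes(self):
        return set(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, **attrs}
            for a, b, attrs in self.graph.edges(data=True)
        ]
        cols = ["gene_a", "gene_b", "n_hh", "n_ll", "n_lh", "n_hl", "ci"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class HubResult:
    mcc: pd.Series  # node -> MCC score
    degree: pd.Series
    top_mcc: list = field(default_factory=list)
    top_degree: list = field(default_factory=list)
    intersection: list = field(default_factory=list)


def discretize_tertiles(expr: ExpressionMatrix, genes=None) -> DiscretizedMatrix:
    """Per-gene rank tertiles: lowest third low, middle mid, top third high.

    Ties break by stable sample order (earlier samples get the lower rank).
    A constant gene is assigned all-mid with a warning.
    """
    genes = list(genes) if genes is not None else expr.gene_ids
    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing[:20]}")
    n = expr.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 samples to form tertiles, got {n}")
    lo_cut = n // 3            # ranks [0, lo_cut) -> low
    hi_cut = n - (n // 3)      # ranks [hi_cut, n) -> high
    cats = {}
    bounds = {}
    for g in genes:
        vals = expr.values.loc[g].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            warnings.warn(f"constant gene {g!r}; all samples set to mid")
            cats[g] = np.array([MID] * n, dtype=object)
            bounds[g] = (np.nan, np.nan)
            continue
        order = np.argsort(vals, kind="stable")
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        cat = np.where(rank < lo_cut, LOW, np.where(rank >= hi_cut, HIGH, MID))
        cats[g] = cat.astype(object)
        bounds[g] = (float(vals[order[lo_cut - 1]]) if lo_cut else -np.inf,
                     float(vals[order[hi_cut]]) if hi_cut < n else np.inf)
    categories = pd.DataFrame(cats, index=expr.sample_ids).T
    boundaries = pd.DataFrame(bounds, index=["low_upper", "high_lower"]).T
    return DiscretizedMatrix(categories=categories, boundaries=boundaries)


def prevalence_filter(disc: DiscretizedMatrix, min_frac: float = 0.66) -> list[str]:
    """Genes where at least ``min_frac`` of samples are mid or high."""
    frac = (disc.categories != LOW).mean(axis=1)
    return [g for g, f in frac.items() if f >= min_frac]


def candidate_edges(catalog: pd.DataFrame, seed_genes, admitted,
                    allow_candidate_candidate: bool = False) -> list[tuple[str, str]]:
    """Catalog pairs with both endpoints admitted and (by default) at least
    one endpoint in the ligand/receptor seed list. Duplicate pairs
    (order-insensitive) and self-loops are rejected."""
    seeds = set(seed_genes)
    if not seeds:
        raise ValueError("seed gene list is empty")
    adm = set(admitted)
    pairs, seen = [], set()
    for a, b in zip(catalog["gene_a"], catalog["gene_b"]):
        if a == b:
            raise ValueError(f"self-loop in interaction catalog: {a}")
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate catalog pair: {a}-{b}")
        seen.add(key)
        if a not in adm or b not in adm:
            continue
        if not allow_candidate_candidate and not (a in seeds or b in seeds):
            continue
        pairs.append((a, b))
    if not pairs:
        warnings.warn("no candidate edges survive filtering; network will be empty")
    return pairs


def concordance_index(disc: DiscretizedMatrix, gene_a: str, gene_b: str,
                      sample_subset=None):
    """Concordance index and its counts for one gene pair.

    Samples where either gene is mid contribute to no count. A pair with
    concordant pairs but no discordant ones gets CI = +inf (strongest
    possible edge); a pair with no counted samples at all gets CI = 0 with
    a warning (dropped downstream).
    """
    for g in (gene_a, gene_b):
        if g not in disc.categories.index:
            raise KeyError(f"gene {g!r} not discretized")
    cols = list(sample_subset) if sample_subset is not None else disc.sample_ids
    if not cols:
        raise ValueError("empty sample subset")
    ca = disc.categories.loc[gene_a, cols].to_numpy()
    cb = disc.categories.loc[gene_b, cols].to_numpy()
    n_hh = int(np.sum((ca == HIGH) & (cb == HIGH)))
    n_ll = int(np.sum((ca == LOW) & (cb == LOW)))
    n_lh = int(np.sum((ca == LOW) & (cb == HIGH)))
    n_hl = int(np.sum((ca == HIGH) & (cb == LOW)))
    counts = {"n_hh": n_hh, "n_ll": n_ll, "n_lh": n_lh, "n_hl": n_hl}
    conc, disc_n = n_hh + n_ll, n_lh + n_hl
    if disc_n == 0:
        if conc == 0:
            warnings.warn(f"pair {gene_a}-{gene_b}: no high/low pairs at all; CI set to 0")
            return 0.0, counts
        return math.inf, counts
    return conc / disc_n, counts


def build_network(disc: DiscretizedMatrix, candidates, sample_subset=None,
                  ci_threshold: float = 1.0, subtype: str = "") -> ImmuneNetwork:
    """Score candidate pairs and keep edges with CI strictly above threshold;
    prune isolated nodes (every retained node keeps at least one edge)."""
    g = nx.Graph()
    for a, b in candidates:
        ci, counts = concordance_index(disc, a, b, sample_subset)
        if ci > ci_threshold:
            g.add_edge(a, b, ci=ci, **counts)
    if g.number_of_edges() == 0:
        log.info("empty network (subtype=%s): no edge exceeded CI > %s", subtype, ci_threshold)
    return ImmuneNetwork(graph=g, subtype=subtype)


def mcc_scores(network: ImmuneNetwork | nx.Graph, max_nodes: int = 2000) -> HubResult:
    """Maximal Clique Centrality and degree for every node.

    Maximal cliques are enumerated with Bron-Kerbosch with pivoting;
    MCC(v) = sum over maximal cliques C containing v of (|C|-1)!.
    """
    g = network.graph if isinstance(network, ImmuneNetwork) else network
    if g.number_of_nodes() > max_nodes:
        raise ValueError(
            f"graph has {g.number_of_nodes()} nodes > budget {max_nodes}; "
            "analyze subgraphs instead")
    mcc = {v: 0 for v in g.nodes}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    mcc = pd.Series(mcc, dtype=float).sort_index()
    degree = pd.Series(dict(g.degree()), dtype=float).sort_index()
    return HubResult(mcc=mcc, degree=degree)


def _top_with_ties(scores: pd.Series, k: int) -> list[str]:
    """Top-k nodes by score, expanding ties at the k-th rank; deterministic
    (score desc, then node id asc)."""
    if scores.empty:
        return []
    order = np.lexsort((scores.index.astype(str), -scores.to_numpy()))
    ordered = scores.iloc[order]
    if len(ordered) <= k:
        return list(ordered.index)
    cutoff = ordered.iloc[k - 1]
    return list(ordered.index[ordered.to_numpy() >= cutoff])


def hub_intersection(network: ImmuneNetwork | nx.Graph, top_k: int = 10) -> HubResult:
    """Intersect the top-k MCC and top-k degree rankings (ties expand)."""
    res = mcc_scores(network)
    res.top_mcc = _top_with_ties(res.mcc, top_k)
    res.top_degree = _top_with_ties(res.degree, top_k)
    inter = set(res.top_mcc) & set(res.top_degree)
    res.intersection = sorted(inter, key=lambda v: (-res.mcc[v], -res.degree[v], str(v)))
    return res


def subtype_network(expr: ExpressionMatrix, labels: pd.Series, subtype: str,
                    catalog: pd.DataFrame, seed_genes, min_frac: float = 0.66,
                    ci_threshold: float = 1.0,
                    allow_candidate_candidate: bool = False) -> ImmuneNetwork:
    """Build the immune network for one subtype on that subtype's samples;
    discretization and the prevalence filter are computed on the subset."""
    samples = [s for s in expr.sample_ids if labels.get(s) == subtype]
    if len(samples) < 3:
        raise ValueError(f"subtype {subtype!r} has fewer than 3 samples")
    sub = expr.subset_samples(samples)
    genes = sorted(set(catalog["gene_a"]) | set(catalog["gene_b"]))
    genes = [g for g in genes if g in sub.values.index]
    disc = discretize_tertiles(sub, genes)
    admitted = prevalence_filter(disc, min_frac)
    cands = candidate_edges(catalog, seed_genes, admitted,
                            allow_candidate_candidate=allow_candidate_candidate)
    return build_network(disc, cands, ci_threshold=ci_threshold, subtype=subtype)
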
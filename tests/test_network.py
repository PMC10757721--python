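import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efferotype.datatypes import ExpressionMatrix
from efferotype.network import (
    HIGH,
    LOW,
    MID,
    build_network,
    candidate_edges,
    concordance_index,
    discretize_tertiles,
    hub_intersection,
    mcc_scores,
    prevalence_filter,
    subtype_network,
)
from efferotype.synthetic import CohortConfig, generate_cohort


def _expr(rows: dict, samples=None):
    df = pd.DataFrame(rows).T
    if samples:
        df.columns = samples
    else:
        df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df.astype(float).clip(lower=0), "tpm")


class TestDiscretize:
    def test_nine_values_split_three_ways(self):
        disc = discretize_tertiles(_expr({"g": list(range(1, 10))}))
        cats = disc.categories.loc["g"]
        assert (cats == LOW).sum() == 3 and (cats == MID).sum() == 3 and (cats == HIGH).sum() == 3
        # ranks map in order: smallest third low, largest third high
        assert cats.iloc[0] == LOW and cats.iloc[-1] == HIGH

    def test_constant_gene_goes_all_mid_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            disc = discretize_tertiles(_expr({"g": [2.0] * 6}))
        assert (disc.categories.loc["g"] == MID).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_alphabet_and_balance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        disc = discretize_tertiles(_expr({"g": rng.uniform(0, 10, n).tolist()}))
        cats = disc.categories.loc["g"]
        assert set(cats.unique()) <= {LOW, MID, HIGH}
        assert (cats == LOW).sum() == n // 3
        assert (cats == HIGH).sum() == n // 3

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            discretize_tertiles(_expr({"g": [1.0, 2.0]}))


class TestPrevalence:
    @pytest.mark.parametrize(
        "n_low, n_total, admitted",
        [(3, 10, True), (4, 10, False), (34, 100, True)],  # 7/10, 6/10, 66/100 mid-or-high
    )
    def test_boundary_is_inclusive(self, n_low, n_total, admitted):
        cats = pd.DataFrame([[LOW] * n_low + [MID] * (n_total - n_low)], index=["g"],
                            columns=[f"s{i}" for i in range(n_total)])
        disc = type("D", (), {"categories": cats})()
        assert (["g"] == prevalence_filter(disc)) == admitted or \
               (prevalence_filter(disc) == [] and not admitted)


class TestCandidateEdges:
    def _catalog(self, pairs):
        return pd.DataFrame(pairs, columns=["gene_a", "gene_b"])

    def test_seed_and_admission_rules(self):
        cat = self._catalog([("L1", "X"), ("L1", "Y"), ("X", "Y")])
        out = candidate_edges(cat, seed_genes=["L1"], admitted=["L1", "X", "Y"])
        assert out == [("L1", "X"), ("L1", "Y")]  # X-Y has no seed endpoint

    def test_unadmitted_endpoint_drops_pair(self):
        cat = self._catalog([("L1", "X")])
        assert candidate_edges(cat, ["L1"], ["L1"]) == []

    def test_candidate_candidate_flag(self):
        cat = self._catalog([("X", "Y")])
        assert candidate_edges(cat, ["L1"], ["X", "Y"], allow_candidate_candidate=True) == [("X", "Y")]

    def test_duplicates_and_self_loops_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            candidate_edges(self._catalog([("A", "B"), ("B", "A")]), ["A"], ["A", "B"])
        with pytest.raises(ValueError, match="self-loop"):
            candidate_edges(self._catalog([("A", "A")]), ["A"], ["A"])


def _disc_from_cats(cats: dict):
    df = pd.DataFrame(cats).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return type("D", (), {"categories": df, "sample_ids": list(df.columns)})()


class TestConcordanceIndex:
    def test_direct_arithmetic(self):
        cats = {
            "a": [HIGH] * 15 + [LOW] * 15,
            "b": [HIGH] * 10 + [LOW] * 5 + [LOW] * 10 + [HIGH] * 5,
        }
        ci, counts = concordance_index(_disc_from_cats(cats), "a", "b")
        assert counts == {"n_hh": 10, "n_ll": 10, "n_lh": 5, "n_hl": 5}
        assert ci == 2.0

    def test_pure_discordance_gives_zero(self):
        cats = {"a": [LOW] * 3 + [HIGH] * 3, "b": [HIGH] * 3 + [LOW] * 3}
        ci, _ = concordance_index(_disc_from_cats(cats), "a", "b")
        assert ci == 0.0

    def test_no_discordant_pairs_gives_infinity(self):
        cats = {"a": [HIGH] * 4 + [MID] * 2, "b": [HIGH] * 4 + [MID] * 2}
        ci, counts = concordance_index(_disc_from_cats(cats), "a", "b")
        assert math.isinf(ci) and counts["n_hh"] == 4

    def test_all_mid_warns_and_returns_zero(self):
        cats = {"a": [MID] * 4, "b": [MID] * 4}
        with pytest.warns(UserWarning, match="no high/low"):
            ci, _ = concordance_index(_disc_from_cats(cats), "a", "b")
        assert ci == 0.0

    def test_symmetric_in_gene_order(self):
        rng = np.random.default_rng(4)
        cats = {g: rng.choice([LOW, MID, HIGH], 30).tolist() for g in ("a", "b")}
        d = _disc_from_cats(cats)
        assert concordance_index(d, "a", "b")[0] == concordance_index(d, "b", "a")[0]

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 100, 21)
        other = rng.uniform(1, 100, 21)
        e1 = _expr({"a": vals.tolist(), "b": other.tolist()})
        e2 = _expr({"a": np.log(vals).tolist(), "b": (other ** 3).tolist()})
        d1, d2 = discretize_tertiles(e1), discretize_tertiles(e2)
        assert concordance_index(d1, "a", "b") == concordance_index(d2, "a", "b")

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            concordance_index(_disc_from_cats({"a": [LOW] * 3}), "a", "nope")


class TestBuildNetwork:
    def test_planted_perfectly_coupled_pair_is_recovered(self):
        coh = generate_cohort(CohortConfig(n_samples=300, lr_coupling=1.0, seed=2))
        nw = subtype_network(coh.expression, coh.truth_labels, "C1",
                             coh.interaction_catalog, coh.seed_genes)
        found = {frozenset(e) for e in zip(nw.edges["gene_a"], nw.edges["gene_b"])}
        for pair in coh.planted_edges:
            assert frozenset(pair) in found

    def test_anti_concordant_pair_is_excluded_and_pruned(self):
        cats = {"L": [LOW] * 10 + [HIGH] * 10, "X": [HIGH] * 10 + [LOW] * 10}
        nw = build_network(_disc_from_cats(cats), [("L", "X")])
        assert nw.graph.number_of_edges() == 0
        assert nw.nodes == set()  # both endpoints pruned as isolated

    def test_every_retained_node_has_an_edge(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(8)]
        cats = {g: rng.choice([LOW, MID, HIGH], 40).tolist() for g in genes}
        pairs = list(itertools.combinations(genes, 2))
        nw = build_network(_disc_from_cats(cats), pairs)
        for node in nw.nodes:
            assert nw.graph.degree(node) >= 1


def _brute_force_mcc(g: nx.Graph) -> dict:
    """Exponential oracle: enumerate all maximal cliques by subset scan."""
    nodes = list(g.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(g.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    mcc = {v: 0 for v in nodes}
    for c in maximal:
        for v in c:
            mcc[v] += math.factorial(len(c) - 1)
    return mcc


class TestMcc:
    def test_triangle(self):
        g = nx.complete_graph(3)
        res = mcc_scores(g)
        assert (res.mcc == 2).all()

    def test_path(self):
        g = nx.path_graph(["a", "b", "c"])
        res = mcc_scores(g)
        assert res.mcc["b"] == 2 and res.mcc["a"] == 1 and res.mcc["c"] == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(0, 2**31)))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() == 0:
            pytest.skip("empty random graph")
        res = mcc_scores(g)
        assert res.mcc.to_dict() == {k: float(v) for k, v in _brute_force_mcc(g).items()}

    def test_budget_guard(self):
        g = nx.path_graph(5)
        with pytest.raises(ValueError, match="budget"):
            mcc_scores(g, max_nodes=3)


class TestHubs:
    def test_identical_rankings_intersect_fully(self):
        g = nx.complete_graph(4)  # all nodes tied on both scores
        res = hub_intersection(g, top_k=2)
        # ties at the cutoff expand the top set to all tied nodes
        assert set(res.top_mcc) == set(g.nodes)
        assert set(res.intersection) == set(g.nodes)

    def test_disjoint_top_sets_give_empty_intersection(self):
        # star hub h: degree 4, MCC 4 (four 2-cliques); K4 members: degree 3,
        # MCC (4-1)! = 6 -> degree leader and MCC leaders are disjoint
        g = nx.Graph()
        g.add_edges_from([("h", f"leaf{i}") for i in range(4)])
        g.add_edges_from(itertools.combinations(["t1", "t2", "t3", "t4"], 2))
        res = hub_intersection(g, top_k=1)
        assert res.top_degree == ["h"]
        assert set(res.top_mcc) == {"t1", "t2", "t3", "t4"}
        assert res.intersection == []

    def test_deterministic_ordering(self):
        g = nx.path_graph(["b", "a", "c", "d"])
        r1 = hub_intersection(g, top_k=10)
        r2 = hub_intersection(g, top_k=10)
        assert r1.intersection == r2.intersection
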
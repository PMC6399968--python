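import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import embryonet as en
from embryonet.networks import SeedSet, coexpression_network, infer_network, load_interactome


def exact_steiner_connectors(graph: nx.Graph, seeds: set) -> int:
    """Oracle: smallest number of non-seed nodes whose addition makes the
    seeds mutually connected, by exhaustive subset search."""
    others = sorted(set(graph.nodes) - seeds)
    for size in range(len(others) + 1):
        for extra in itertools.combinations(others, size):
            sub = graph.subgraph(seeds | set(extra))
            if all(s in sub for s in seeds) and sub.number_of_nodes() > 0:
                comps = list(nx.connected_components(sub))
                if any(seeds <= c for c in comps):
                    return size
    return len(others)


class TestLoadInteractome:
    def test_undirected_dedup_and_self_loops(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\nB\tA\nA\tA\nB\tC\n")
        g = load_interactome(p)
        assert set(map(frozenset, g.edges)) == {frozenset("AB"), frozenset("BC")}

    def test_path_fixture(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\nb\tc\nc\td\n")
        g = load_interactome(p)
        assert nx.is_connected(g)
        assert [g.degree(n) for n in ["A", "B", "C", "D"]] == [1, 2, 2, 1]

    def test_tab2_style_symbol_columns(self, tmp_path):
        p = tmp_path / "biogrid.tsv"
        row = ["-"] * 7 + ["TP53", "MDM2"] + ["-"] * 3
        row2 = ["-"] * 7 + ["mdm2", "TRIM28"] + ["-"] * 3
        p.write_text("\t".join(row) + "\n" + "\t".join(row2) + "\n")
        g = load_interactome(p, fmt="tab2-like", symbol_columns=(7, 8))
        assert set(map(frozenset, g.edges)) == {frozenset({"TP53", "MDM2"}),
                                                frozenset({"MDM2", "TRIM28"})}

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("\n")
        with pytest.raises(ValueError):
            load_interactome(p)


class TestInferNetwork:
    def test_unique_shortest_path_connector(self):
        g = nx.path_graph(["A", "B", "C"])
        model = infer_network(g, SeedSet(frozenset("AC")))
        assert model.connectors == {"B"}
        assert set(map(frozenset, model.graph.edges)) == {frozenset("AB"),
                                                          frozenset("BC")}

    def test_adjacent_seeds_need_no_connectors(self):
        g = nx.path_graph(["A", "B", "C"])
        model = infer_network(g, SeedSet(frozenset("AB")))
        assert model.connectors == set()

    def test_all_seeds_absent_raises(self):
        g = nx.path_graph(["A", "B"])
        with pytest.raises(ValueError):
            infer_network(g, SeedSet(frozenset({"X", "Y"})))

    def test_chained_merges_through_connectors(self):
        g = nx.path_graph(["A", "B", "C", "D", "E"])
        model = infer_network(g, SeedSet(frozenset({"A", "C", "E"})),
                              max_connector_path=2)
        assert model.connectors == {"B", "D"}
        assert model.unreachable_seeds == frozenset()

    def test_unreachable_seed_reported_not_dropped(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("D", "E"), ("E", "F"),
                      ("F", "G"), ("G", "H")])
        model = infer_network(g, SeedSet(frozenset({"A", "C", "H"})),
                              max_connector_path=2)
        assert model.unreachable_seeds == frozenset({"H"})
        assert "H" in model.graph  # kept as an isolated, auditable node
        assert model.connectors == {"B"}

    def test_greedy_matches_exact_steiner_on_small_graphs(self):
        equal = total = 0
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(6, 13))
            g = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            if g.number_of_edges() == 0:
                continue
            comp = max(nx.connected_components(g), key=len)
            if len(comp) < 4:
                continue
            seeds = set(rng.choice(sorted(comp), size=min(4, len(comp)),
                                   replace=False))
            model = infer_network(g, SeedSet(frozenset(seeds)),
                                  max_connector_path=n)
            greedy = len(model.connectors)
            exact = exact_steiner_connectors(g, seeds)
            assert greedy >= exact  # greedy can never beat the optimum
            total += 1
            equal += greedy == exact
        assert total >= 150
        assert equal / total >= 0.95

    def test_exact_on_trees(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            t = nx.random_labeled_tree(10, seed=int(rng.integers(1 << 30)))
            t = nx.relabel_nodes(t, {i: f"N{i}" for i in t.nodes})
            seeds = set(rng.choice(sorted(t.nodes), size=3, replace=False))
            model = infer_network(t, SeedSet(frozenset(seeds)),
                                  max_connector_path=10)
            assert len(model.connectors) == exact_steiner_connectors(t, seeds)

    def test_extra_edge_never_increases_connectors(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            g = nx.gnp_random_graph(9, 0.35, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            comp = max(nx.connected_components(g), key=len)
            if len(comp) < 4:
                continue
            seeds = frozenset(rng.choice(sorted(comp), size=3, replace=False))
            base = len(infer_network(g, SeedSet(seeds), max_connector_path=9).connectors)
            missing = [e for e in itertools.combinations(sorted(comp), 2)
                       if not g.has_edge(*e)]
            if not missing:
                continue
            a, b = missing[int(rng.integers(len(missing)))]
            g2 = g.copy()
            g2.add_edge(a, b)
            aug = len(infer_network(g2, SeedSet(seeds), max_connector_path=9).connectors)
            assert aug <= base


class TestCoexpression:
    def _matrix(self, vals):
        vals = pd.DataFrame(vals, index=[f"G{i}" for i in range(len(vals))],
                            columns=[f"s{i}" for i in range(len(vals[0]))])
        meta = pd.DataFrame({"stage": ["x"] * vals.shape[1]}, index=vals.columns)
        return en.ExpressionMatrix(vals, meta)

    def test_duplicated_and_anticorrelated_rows(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        m = self._matrix([base, base, [-v for v in base], [5, 1, 4, 2, 3]])
        g = coexpression_network(m, r_threshold=0.99)
        assert g.has_edge("G0", "G1")  # r = 1
        assert g.has_edge("G0", "G2")  # |r| = 1 via anti-correlation
        assert not g.has_edge("G0", "G3")

    def test_constant_genes_excluded(self):
        m = self._matrix([[1.0, 2.0, 3.0, 4.0], [2.0, 2.0, 2.0, 2.0]])
        g = coexpression_network(m, r_threshold=0.9)
        assert "G1" not in g

    def test_independent_noise_has_near_zero_density(self):
        densities = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            m = self._matrix(rng.normal(size=(40, 50)))
            g = coexpression_network(m, r_threshold=0.99)
            possible = 40 * 39 / 2
            densities.append(g.number_of_edges() / possible)
        assert max(densities) < 0.001
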
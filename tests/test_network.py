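import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netricci import (
    PositivityError,
    ValidationError,
    load_network,
    match_expression,
    stationary_distribution,
    transition_matrix,
    weighted_adjacency,
    make_random_pin,
)
from netricci.network import MatchedNetwork


class TestLoadNetwork:
    def test_duplicate_edges_collapse(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("A\tB\nB\tC\nA\tB\n")
        graph = load_network(path)
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2

    def test_self_loops_dropped(self, tmp_path, caplog):
        path = tmp_path / "net.tsv"
        path.write_text("X\tX\nX\tY\n")
        with caplog.at_level("INFO", logger="netricci.network"):
            graph = load_network(path)
        assert set(graph.edges) == {("X", "Y")}
        assert any("self-loop" in rec.message for rec in caplog.records)

    def test_graphml_matches_edgelist(self, tmp_path):
        import networkx as nx

        edges = [("A", "B"), ("B", "C"), ("C", "D")]
        el = tmp_path / "net.tsv"
        el.write_text("".join(f"{u}\t{v}\n" for u, v in edges))
        gml = tmp_path / "net.graphml"
        nx.write_graphml(nx.Graph(edges), gml)
        g1 = load_network(el)
        g2 = load_network(gml)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))

    def test_sif(self, tmp_path):
        path = tmp_path / "net.sif"
        path.write_text("A pp B C\nD pp A\n")
        graph = load_network(path)
        assert set(map(frozenset, graph.edges)) == {
            frozenset(p) for p in [("A", "B"), ("A", "C"), ("A", "D")]
        }

    def test_mtx_expression_roundtrip(self, tmp_path):
        import scipy.sparse as sp
        from scipy.io import mmwrite

        from netricci import load_expression

        mat = sp.csr_matrix(np.array([[1.0, 2.0], [3.0, 4.0]]))
        path = tmp_path / "expr.mtx"
        path.touch()
        mmwrite(path, mat)
        (tmp_path / "expr.rows.txt").write_text("g1 g2")
        (tmp_path / "expr.cols.txt").write_text("s1 s2")
        df = load_expression(path)
        assert df.loc["g2", "s2"] == 4.0

    def test_empty_graph_rejected(self, tmp_path):
        path = tmp_path / "net.tsv"
        path.write_text("")
        with pytest.raises(ValidationError):
            load_network(path)


class TestMatchExpression:
    def _triangle(self):
        import networkx as nx

        return nx.Graph([("P", "Q"), ("Q", "R"), ("R", "P")])

    def test_many_genes_one_protein_averaged(self):
        graph = self._triangle()
        expr = pd.Series({"g1": 2.0, "g2": 4.0, "gq": 1.0, "gr": 1.0})
        mapping = pd.DataFrame(
            {"gene": ["g1", "g2", "gq", "gr"], "protein": ["P", "P", "Q", "R"]}
        )
        net = match_expression(graph, expr, mapping)
        assert net.expression[net.index_of("P")] == pytest.approx(3.0)

    def test_largest_component_kept(self):
        import networkx as nx

        graph = nx.Graph([("A", "B"), ("B", "C")])
        graph.add_node("D")
        expr = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
        net = match_expression(graph, expr)
        assert net.n == 3
        assert "D" not in net.node_ids

    def test_unmatched_nodes_removed(self):
        import networkx as nx

        # E has no expression; the matched subgraph splits and only the
        # largest piece survives.
        graph = nx.Graph([("A", "B"), ("B", "C"), ("C", "E"), ("E", "F")])
        expr = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "F": 4.0})
        net = match_expression(graph, expr)
        assert sorted(net.node_ids) == ["A", "B", "C"]

    def test_idempotent(self):
        import networkx as nx

        graph = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D")])
        expr = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        net1 = match_expression(graph, expr)
        graph2 = nx.Graph(
            [(net1.node_ids[a], net1.node_ids[b]) for a, b in net1.edge_index]
        )
        net2 = match_expression(
            graph2, pd.Series(dict(zip(net1.node_ids, net1.expression)))
        )
        assert net1.node_ids == net2.node_ids
        np.testing.assert_array_equal(net1.expression, net2.expression)
        assert (net1.adjacency != net2.adjacency).nnz == 0

    def test_zero_expression_is_error_naming_node(self):
        graph = self._triangle()
        expr = pd.Series({"P": 0.0, "Q": 1.0, "R": 1.0})
        with pytest.raises(PositivityError, match="P"):
            match_expression(graph, expr)

    def test_pseudocount_rescues_zero(self):
        graph = self._triangle()
        expr = pd.Series({"P": 0.0, "Q": 1.0, "R": 1.0})
        net = match_expression(graph, expr, pseudocount=0.5)
        assert net.expression[net.index_of("P")] == pytest.approx(0.5)
        assert net.expression[net.index_of("Q")] == pytest.approx(1.5)

    def test_too_few_matches_rejected(self):
        graph = self._triangle()
        with pytest.raises(ValidationError):
            match_expression(graph, pd.Series({"P": 1.0, "Q": 1.0}))

    def test_star_fixture_through_matching(self, tmp_path, star):
        net = star(3, 2.0)
        el = tmp_path / "star.tsv"
        el.write_text(
            "".join(
                f"{net.node_ids[a]}\t{net.node_ids[b]}\n" for a, b in net.edge_index
            )
        )
        expr = pd.Series(dict(zip(net.node_ids, net.expression)))
        rebuilt = match_expression(load_network(el), expr)
        for name, want in [("l1", 1.0), ("l2", 1.0), ("i", 1.0), ("j", 2.0)]:
            assert rebuilt.expression[rebuilt.index_of(name)] == pytest.approx(want)


class TestOperators:
    def test_unit_expression_gives_unit_weights(self, star):
        w = weighted_adjacency(star(4, 1.0))
        np.testing.assert_allclose(w.values, 1.0)

    def test_star_weights(self, star):
        net = star(3, 2.0)
        w = weighted_adjacency(net)
        hub, j = net.index_of("i"), net.index_of("j")
        assert w.value(hub, j) == pytest.approx(2.0)
        assert w.value(hub, net.index_of("l1")) == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=25)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_weights_scale_quadratically(self, c):
        net = make_random_pin(20, 3.0, seed=5)
        scaled = MatchedNetwork(net.node_ids, net.adjacency, c * net.expression)
        np.testing.assert_allclose(
            weighted_adjacency(scaled).values,
            c**2 * weighted_adjacency(net).values,
            rtol=1e-12,
        )

    def test_star_transition_rows(self, star):
        net = star(3, 2.0)
        P = transition_matrix(net).toarray()
        hub = net.index_of("i")
        row = P[hub]
        assert row[net.index_of("j")] == pytest.approx(0.5)
        assert row[net.index_of("l1")] == pytest.approx(0.25)
        assert row[net.index_of("l2")] == pytest.approx(0.25)
        for leaf in ("l1", "l2", "j"):
            assert P[net.index_of(leaf), hub] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        net = make_random_pin(30, 4.0, seed=seed)
        P = transition_matrix(net)
        np.testing.assert_allclose(
            np.asarray(P.sum(axis=1)).ravel(), 1.0, atol=1e-15
        )

    def test_star_hub_stationary_half(self, star):
        for k, eps in [(2, 0.3), (5, 1.0), (9, 7.2)]:
            net = star(k, eps)
            pi = stationary_distribution(net)
            assert pi[net.index_of("i")] == pytest.approx(0.5, abs=1e-14)

    def test_regular_graph_uniform_x_uniform_pi(self):
        import networkx as nx

        graph = nx.cycle_graph(6)
        net = match_expression(
            nx.relabel_nodes(graph, str),
            pd.Series({str(v): 1.0 for v in graph}),
        )
        np.testing.assert_allclose(stationary_distribution(net), 1.0 / 6)

    @pytest.mark.parametrize("seed", range(50))
    def test_stationary_matches_left_eigenvector(self, seed):
        """Closed-form stationary distribution vs power iteration on P."""
        rng = np.random.default_rng(seed)
        net = make_random_pin(int(rng.integers(10, 50)), 4.0, seed=seed)
        P = transition_matrix(net).toarray()
        v = np.full(net.n, 1.0 / net.n)
        for _ in range(20_000):
            nxt = v @ P
            if np.max(np.abs(nxt - v)) < 1e-14:
                v = nxt
                break
            v = nxt
        pi = stationary_distribution(net)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pi, v / v.sum(), atol=1e-10)
        np.testing.assert_allclose(pi @ P, pi, atol=1e-10)
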
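"""Auto-Contractive Map training, the weight→distance transform, the
Kruskal MST against an exhaustive oracle, graph building and export."""

import itertools
import json

import numpy as np
import pytest

import folatenet as fn


def brute_force_mst(D, names):
    """Enumerate all spanning trees of the complete graph (≤ 6 nodes) and
    return the minimum total distance."""
    n = len(names)
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for combo in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(D[i, j] for i, j in combo))
    return best


@pytest.fixture(scope="module")
def example_graph():
    rng = np.random.default_rng(9)
    X = rng.random((40, 6))
    return fn.train_autocm(X, [f"N{i}" for i in range(6)], max_epochs=50).connectivity_graph()


class TestTraining:
    def test_weights_bounded_by_contraction_constant(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 6))
        res = fn.train_autocm(X, max_epochs=300)
        m = res.model
        assert np.all(m.W >= 0) and np.all(m.W < m.C)
        assert np.all(m.v >= 0) and np.all(m.v < m.C)

    def test_duplicated_columns_develop_maximal_weight(self):
        rng = np.random.default_rng(1)
        base = (rng.random(80) > 0.5).astype(float)
        X = np.column_stack([base, base, rng.integers(0, 2, 80).astype(float)])
        res = fn.train_autocm(X, ["X1", "X2", "X3"], max_epochs=100)
        W = res.model.W_sym
        off = [(0, 1), (0, 2), (1, 2)]
        assert max(off, key=lambda p: W[p]) == (0, 1)

    def test_all_zero_column_stays_at_zero_weight(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.random(30), np.zeros(30), rng.random(30)])
        res = fn.train_autocm(X, max_epochs=100)
        W = res.model.W_sym
        assert W[1, 0] == 0.0 and W[1, 2] == 0.0

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 5))
        r1 = fn.train_autocm(X, max_epochs=50)
        r2 = fn.train_autocm(X, max_epochs=50)
        assert np.array_equal(r1.model.W, r2.model.W)

    def test_inputs_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fn.train_autocm(np.array([[1.5, 0.0]]))


class TestDistances:
    def test_transform_endpoints_and_antimonotonicity(self):
        m = fn.AutoCMModel(C=4.0, v=np.zeros(3),
                           W=np.array([[0.0, 4.0, 1.0], [4.0, 0.0, 3.0], [1.0, 3.0, 0.0]]),
                           epochs_run=1, converged=True)
        D = fn.weights_to_distances(m)
        assert D[0, 1] == 0.0       # w = C -> distance 0
        assert D[0, 2] == 3.0       # w = 1 -> C - 1
        assert np.all(np.diag(D) == 0)
        # anti-monotone: larger weight, smaller distance
        assert m.W_sym[1, 2] > m.W_sym[0, 2] and D[1, 2] < D[0, 2]

    def test_strength_scaling_preserves_order(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 5))
        res = fn.train_autocm(X, max_epochs=50)
        g = res.connectivity_graph()
        W = res.model.W_sym
        strengths = np.array([s for _, _, s in g.edges])
        assert np.all(strengths >= 0) and np.all(strengths < 1)
        order_w = np.argsort([W[i, j] for i in range(5) for j in range(i + 1, 5)])
        names = res.node_names
        pair_s = {tuple(sorted((names[i], names[j]))): W[i, j] / res.model.C
                  for i in range(5) for j in range(i + 1, 5)}
        for u, v, s in g.edges:
            assert s == pytest.approx(pair_s[(u, v)], abs=1e-15)


class TestMST:
    def test_four_node_worked_example(self):
        names = ["A", "B", "C", "D"]
        D = np.zeros((4, 4))
        pairs = {("A", "B"): 1.0, ("A", "C"): 2.0, ("A", "D"): 3.0,
                 ("B", "C"): 2.5, ("B", "D"): 1.5, ("C", "D"): 2.2}
        for (u, v), d in pairs.items():
            i, j = names.index(u), names.index(v)
            D[i, j] = D[j, i] = d
        tree = fn.minimum_spanning_tree(D, names)
        assert {(u, v) for u, v, _ in tree} == {("A", "B"), ("B", "D"), ("A", "C")}
        assert sum(d for _, _, d in tree) == pytest.approx(4.5)

    def test_two_nodes(self):
        tree = fn.minimum_spanning_tree(np.array([[0.0, 2.0], [2.0, 0.0]]), ["P", "Q"])
        assert tree == [("P", "Q", 2.0)]

    def test_equidistant_triangle_tie_break(self):
        D = np.ones((3, 3)) - np.eye(3)
        tree = fn.minimum_spanning_tree(D, ["A", "B", "C"])
        assert [(u, v) for u, v, _ in tree] == [("A", "B"), ("A", "C")]

    def test_matches_exhaustive_enumeration(self):
        """Kruskal total equals brute-force over all spanning trees for
        random complete graphs with up to 6 nodes."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 7))
            D = np.round(rng.random((n, n)), 3)
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            names = [f"N{i}" for i in range(n)]
            tree = fn.minimum_spanning_tree(D, names)
            assert len(tree) == n - 1
            assert sum(d for _, _, d in tree) == pytest.approx(brute_force_mst(D, names))

    def test_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        n = 12
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        names = [f"N{i:02d}" for i in range(n)]
        tree = fn.minimum_spanning_tree(D, names)
        G = nx.Graph()
        for i in range(n):
            for j in range(i + 1, n):
                G.add_edge(names[i], names[j], weight=D[i, j])
        nx_total = sum(d["weight"] for _, _, d in
                       nx.minimum_spanning_tree(G).edges(data=True))
        assert sum(d for _, _, d in tree) == pytest.approx(nx_total)

    def test_nonfinite_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            fn.minimum_spanning_tree(D, ["A", "B"])


class TestGraph:
    def _graph_from_W(self, W, names, C):
        m = fn.AutoCMModel(C=C, v=np.zeros(len(names)), W=W, epochs_run=1, converged=True)
        return fn.build_connectivity_graph(m, names)

    def test_star_hub(self):
        names = ["HUB", "A", "B", "C"]
        W = np.full((4, 4), 0.5)
        W[0, 1:] = W[1:, 0] = 3.0
        np.fill_diagonal(W, 0)
        g = self._graph_from_W(W, names, C=4.0)
        assert g.hubs == ["HUB"]

    def test_path_interior_nodes_are_hubs(self):
        names = ["A", "B", "C", "D"]
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 3.0
        g = self._graph_from_W(W, names, C=4.0)
        assert g.hubs == ["B", "C"]

    def test_planted_hub_recovered_across_seeds(self):
        """A variable co-varying with three satellites (plus two
        independent distractors) is recovered as an MST hub in ≥ 9/10
        generator seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            h = rng.integers(0, 2, n).astype(float)
            cols = {"HUB": h}
            for k in range(3):
                flip = rng.random(n) < 0.25
                cols[f"SAT{k}"] = np.where(flip, 1 - h, h)
            for k in range(2):
                cols[f"IND{k}"] = rng.integers(0, 2, n).astype(float)
            names = list(cols)
            X = np.column_stack([cols[c] for c in names])
            g = fn.train_autocm(X, names).connectivity_graph()
            hits += "HUB" in g.hubs
        assert hits >= 9

    def test_ld_coupled_loci_adjacent_in_map(self, study_maps):
        """With the planted MTHFR 677/1298 haplotype coupling, the map
        places at least one 677 indicator adjacent to a 1298 indicator in
        ≥ 80% of generator seeds."""
        hits = 0
        for g in study_maps:
            m677 = [n for n in g.nodes if n.startswith("MTHFR677")]
            m1298 = [n for n in g.nodes if n.startswith("MTHFR1298")]
            hits += any(v in m1298 for u in m677 for v in g.mst_neighbors(u))
        assert hits >= 8

    def test_bnmn_closer_to_case_node_than_control(self, study_maps):
        """The micronucleus-frequency node sits fewer tree hops from the
        case-condition node than from the control node in ≥ 80% of
        generator seeds (it carries the dominant case signal)."""
        hits = sum(
            g.mst_path_hops("BNMN", "MDS") < g.mst_path_hops("BNMN", "control")
            for g in study_maps
        )
        assert hits >= 8


class TestExport:
    def test_json_round_trip_identical(self, example_graph, tmp_path):
        p = tmp_path / "g.json"
        fn.export_graph(example_graph, p, "json")
        assert fn.import_graph_json(p) == example_graph

    def test_dot_has_exactly_mst_edge_statements(self, example_graph, tmp_path):
        p = tmp_path / "g.dot"
        fn.export_graph(example_graph, p, "dot")
        text = p.read_text()
        assert text.count(" -- ") == len(example_graph.nodes) - 1

    def test_dot_strengths_parse_into_unit_interval(self, example_graph, tmp_path):
        import re

        p = tmp_path / "g.dot"
        fn.export_graph(example_graph, p, "dot")
        vals = [float(s) for s in re.findall(r'label="([0-9.]+)"', p.read_text())]
        assert vals and all(0.0 <= v <= 1.0 for v in vals)

    def test_graphml_readable_by_networkx(self, example_graph, tmp_path):
        import networkx as nx

        p = tmp_path / "g.graphml"
        fn.export_graph(example_graph, p, "graphml")
        G = nx.read_graphml(p)
        assert set(G.nodes) == set(example_graph.nodes)
        mst_count = sum(1 for _, _, d in G.edges(data=True) if d["in_mst"])
        assert mst_count == len(example_graph.nodes) - 1

    def test_unknown_format_rejected(self, example_graph, tmp_path):
        with pytest.raises(ValueError, match="unknown export format"):
            fn.export_graph(example_graph, tmp_path / "g.x", "svg")
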
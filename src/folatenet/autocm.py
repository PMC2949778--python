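"""Auto-Contractive Map and the semantic connectivity graph.

The Auto-CM is an unsupervised network over the encoded variables (plus
the two condition-label nodes, case and control). Each variable i carries
a mono-connection weight v(i) and each ordered pair (j, i) a pairwise
weight w(j, i), all bounded by the contraction constant C. Per record,
with input signal m_in in [0, 1]:

    m_s(i)   = m_in(i) * (1 - v(i)/C)
    Net(i)   = sum_j m_s(j) * (1 - w(j,i)/C)
    m_out(i) = m_s(i) * (1 - Net(i)/C)

    dv(i)    = alpha * (m_in(i) - m_s(i)) * (1 - v(i)/C)
    dw(j,i)  = alpha * (m_s(i) - m_out(i)) * (1 - w(j,i)/C) * m_s(j)

Weights grow with co-activation and stay below C by construction (the
(1 - w/C) factor contracts every update). After training, the
symmetrised pairwise weights are turned into distances d = C - w, the
minimum spanning tree of the distance matrix is kept as the connectivity
map, edge strengths are reported as w/C in [0, 1], and hubs are the
nodes of maximal tree degree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import EncodedMatrix


@dataclass
class AutoCMModel:
    """Trained mono- and pairwise weights of the map."""

    C: float
    v: np.ndarray
    W: np.ndarray
    epochs_run: int
    converged: bool

    @property
    def W_sym(self) -> np.ndarray:
        return 0.5 * (self.W + self.W.T)


class AutoContractiveMap:
    """Model object: an Auto-CM bound to a [0, 1] data matrix.

    Parameters
    ----------
    X01 : array (n_records, n_nodes) in [0, 1]
    node_names : variable names, one per column.
    C : contraction constant; defaults to the number of nodes.
    lr : learning rate alpha (default 0.1).
    tol : stop when the epoch-mean absolute pairwise-weight change falls
        below this (default 1e-6).
    max_epochs : hard epoch cap (default 1000).
    """

    def __init__(self, X01, node_names=None, C: float | None = None,
                 lr: float = 0.1, tol: float = 1e-6, max_epochs: int = 1000):
        X01 = np.asarray(X01, dtype=float)
        if X01.ndim != 2:
            raise ValueError("X01 must be 2-D")
        if X01.min(initial=0.0) < 0 or X01.max(initial=0.0) > 1:
            raise ValueError("Auto-CM inputs must lie in [0, 1]")
        self.X = X01
        n_nodes = X01.shape[1]
        self.node_names = list(node_names) if node_names is not None else [
            f"V{i}" for i in range(n_nodes)
        ]
        if len(self.node_names) != n_nodes:
            raise ValueError("node_names length must match column count")
        self.C = float(C) if C is not None else float(n_nodes)
        if self.C <= 0:
            raise ValueError("C must be > 0")
        self.lr = float(lr)
        self.tol = float(tol)
        self.max_epochs = int(max_epochs)

    def fit(self) -> "AutoCMResults":
        """Deterministic training: zero-initialised weights, fixed record
        order, stop on weight-change tolerance or the epoch cap."""
        X, C, lr = self.X, self.C, self.lr
        n, m = X.shape
        v = np.zeros(m)
        W = np.zeros((m, m))
        converged = False
        epochs = 0
        for epoch in range(self.max_epochs):
            total_change = 0.0
            for i in range(n):
                m_in = X[i]
                m_s = m_in * (1.0 - v / C)
                net = m_s @ (1.0 - W / C)
                m_out = m_s * (1.0 - net / C)
                dv = lr * (m_in - m_s) * (1.0 - v / C)
                dW = lr * np.outer(m_s, (m_s - m_out)) * (1.0 - W / C)
                v += dv
                W += dW
                total_change += np.abs(dW).sum()
            epochs = epoch + 1
            if total_change / (n * m * m) < self.tol:
                converged = True
                break
        model = AutoCMModel(C=C, v=v, W=W, epochs_run=epochs, converged=converged)
        return AutoCMResults(model=model, node_names=self.node_names)


def train_autocm(X01, node_names=None, C=None, lr=0.1, tol=1e-6, max_epochs=1000) -> "AutoCMResults":
    """Functional wrapper around :class:`AutoContractiveMap`."""
    return AutoContractiveMap(X01, node_names, C=C, lr=lr, tol=tol, max_epochs=max_epochs).fit()


def weights_to_distances(m: AutoCMModel) -> np.ndarray:
    """d = C - w on the symmetrised weights; zero diagonal; anti-monotone
    in w (strong associations become short distances)."""
    d = m.C - m.W_sym
    np.fill_diagonal(d, 0.0)
    return d


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def minimum_spanning_tree(D: np.ndarray, names: list[str]) -> list[tuple[str, str, float]]:
    """Kruskal MST of a symmetric distance matrix.

    Edges are sorted by (distance, smaller name, larger name), so ties
    break lexicographically and the tree is reproducible.
    """
    D = np.asarray(D, dtype=float)
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v = sorted((names[i], names[j]))
            edges.append((float(D[i, j]), u, v))
    edges.sort()
    uf = _UnionFind(names)
    tree = []
    for d, u, v in edges:
        if uf.union(u, v):
            tree.append((u, v, d))
            if len(tree) == n - 1:
                break
    return tree


@dataclass
class ConnectivityGraph:
    """All pairwise strengths plus the MST skeleton and its hubs."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (u, v, strength in [0, 1]), u < v
    mst_edges: list[tuple[str, str]]     # subset of (u, v) pairs
    hubs: list[str]

    def strength(self, u: str, v: str) -> float:
        u, v = sorted((u, v))
        for a, b, s in self.edges:
            if (a, b) == (u, v):
                return s
        raise KeyError((u, v))

    def mst_degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, v in self.mst_edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def mst_neighbors(self, node: str) -> list[str]:
        out = []
        for u, v in self.mst_edges:
            if u == node:
                out.append(v)
            elif v == node:
                out.append(u)
        return sorted(out)

    def mst_path_hops(self, src: str, dst: str) -> int:
        """Hop count along the unique tree path between two nodes."""
        from collections import deque

        q = deque([(src, 0)])
        seen = {src}
        while q:
            node, d = q.popleft()
            if node == dst:
                return d
            for nb in self.mst_neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    q.append((nb, d + 1))
        raise ValueError(f"{dst!r} not reachable from {src!r} (tree disconnected?)")


@dataclass
class AutoCMResults:
    """Trained map plus graph-building and export methods."""

    model: AutoCMModel
    node_names: list[str]

    def distances(self) -> np.ndarray:
        return weights_to_distances(self.model)

    def connectivity_graph(self) -> ConnectivityGraph:
        return build_connectivity_graph(self.model, self.node_names)

    def summary(self) -> str:
        g = self.connectivity_graph()
        deg = g.mst_degree()
        lines = [
            "Auto-Contractive Map results",
            "============================",
            f"nodes               : {len(self.node_names)}",
            f"contraction C       : {self.model.C:g}",
            f"epochs run          : {self.model.epochs_run}"
            + (" (converged)" if self.model.converged else " (epoch cap)"),
            f"max pairwise weight : {self.model.W_sym.max():.4f}",
            f"hubs (max MST degree {max(deg.values())}): " + ", ".join(g.hubs),
        ]
        return "\n".join(lines)


def build_connectivity_graph(m: AutoCMModel, node_names: list[str]) -> ConnectivityGraph:
    """Scale weights to [0, 1] strengths, keep the MST, find the hubs."""
    W = m.W_sym
    n = len(node_names)
    if W.shape != (n, n):
        raise ValueError("node_names length must match the weight matrix")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            u, v = sorted((node_names[i], node_names[j]))
            edges.append((u, v, float(W[i, j] / m.C)))
    tree = minimum_spanning_tree(weights_to_distances(m), node_names)
    mst_edges = sorted((u, v) for u, v, _ in tree)
    deg: dict[str, int] = {name: 0 for name in node_names}
    for u, v in mst_edges:
        deg[u] += 1
        deg[v] += 1
    dmax = max(deg.values()) if deg else 0
    hubs = sorted([name for name, d in deg.items() if d == dmax])
    return ConnectivityGraph(sorted(node_names), sorted(edges), mst_edges, hubs)


def condition_labelled_matrix(em: EncodedMatrix) -> tuple[np.ndarray, list[str]]:
    """Append the two condition-label nodes (case and control indicators)
    to the encoded features, as they appear in the map as graph nodes."""
    X = np.column_stack([em.X, em.y, 1.0 - em.y])
    names = list(em.feature_names) + ["MDS", "control"]
    return X, names


def export_graph(g: ConnectivityGraph, path, fmt: str) -> None:
    """Write the graph as DOT, GraphML or a JSON edge list.

    DOT contains exactly the MST edges (the rendered map); GraphML and
    JSON carry every pairwise edge with an ``in_mst`` flag. Strengths are
    printed with 2 decimals in DOT.
    """
    fmt = fmt.lower()
    if fmt == "dot":
        mst = set(g.mst_edges)
        lines = ["graph connectivity {", "  node [shape=box];"]
        for n in g.nodes:
            extra = ' style=filled fillcolor="lightblue"' if n in g.hubs else ""
            lines.append(f'  "{n}" [label="{n}"{extra}];')
        for u, v in g.mst_edges:
            s = g.strength(u, v)
            lines.append(f'  "{u}" -- "{v}" [label="{s:.2f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    elif fmt == "graphml":
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(g.nodes)
        mst = set(g.mst_edges)
        for u, v, s in g.edges:
            G.add_edge(u, v, strength=s, in_mst=(u, v) in mst)
        nx.write_graphml(G, path)
    elif fmt == "json":
        mst = set(g.mst_edges)
        payload = {
            "nodes": g.nodes,
            "hubs": g.hubs,
            "edges": [
                {"source": u, "target": v, "strength": s, "in_mst": (u, v) in mst}
                for u, v, s in g.edges
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected dot, graphml or json)")


def import_graph_json(path) -> ConnectivityGraph:
    """Re-read a JSON edge list written by :func:`export_graph`."""
    with open(path) as fh:
        payload = json.load(fh)
    edges = [(e["source"], e["target"], e["strength"]) for e in payload["edges"]]
    mst_edges = [(e["source"], e["target"]) for e in payload["edges"] if e["in_mst"]]
    return ConnectivityGraph(payload["nodes"], edges, mst_edges, payload["hubs"])
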
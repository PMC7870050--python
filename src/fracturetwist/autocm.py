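"""Auto-Contractive Map training and semantic connectivity graphs.

The Auto-CM is a three-layer network (input → hidden → output, one node per
variable in each layer) whose weights grow where variables co-activate:

* hidden signal       m^h_i   = m^in_i · (1 − v_i / C)
* input-weight update Δv_i    = (m^in_i − m^h_i) · (1 − v_i / C)
* net input           Net_j   = Σ_i m^h_i · (1 − W_ij / C)
* output signal       m^out_j = m^h_j · (1 − Net_j / C)
* lateral update      ΔW_ij   = (m^h_j − m^out_j) · (1 − W_ij / C) · m^h_i

with a single contraction parameter C and no learning rate; the (1 − ·/C)
factors self-limit the updates, so every weight stays in [0, C].  After
training, the lateral matrix W is read as a variable–variable similarity
matrix; its complement to the strongest similarity is a distance matrix on
which a minimum spanning tree gives the backbone of the semantic map, and a
"maximally regular graph" augmentation adds the strongest non-tree edges
that keep node degrees homogeneous, exposing densely interconnected loops.

A second similarity source — the prior-probability concordance index
c/(c+d) over fuzzy agreement — is provided as a drop-in alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .preprocessing import AugmentedMatrix, OUTCOME_HIGH, OUTCOME_LOW

__all__ = [
    "AutoCMWeights", "SimilarityMatrix", "ConnectivityGraph",
    "train_autocm", "pp_similarity", "autocm_similarity",
    "similarity_to_distance", "minimum_spanning_tree",
    "maximally_regular_graph", "map_report", "build_map",
]


@dataclass
class AutoCMWeights:
    C: float
    v: np.ndarray                  # (n_nodes,) input -> hidden
    W: np.ndarray                  # (n_nodes, n_nodes) hidden -> output
    node_names: list[str]
    epochs_run: int
    converged: bool


@dataclass
class SimilarityMatrix:
    node_names: list[str]
    values: np.ndarray             # symmetric
    source: str                    # "autocm" | "prior_probability"

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")


@dataclass
class ConnectivityGraph:
    """MST backbone plus optional maximally-regular augmentation."""

    graph: nx.Graph                # nodes flagged, edges flagged tree/extra
    tree_edges: list[tuple[str, str]]
    extra_edges: list[tuple[str, str]]
    regularity_trace: list[tuple[int, float]] = field(default_factory=list)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_dict(self) -> dict:
        return {
            "nodes": [{"name": n, **self.graph.nodes[n]} for n in sorted(self.graph)],
            "edges": [
                {"u": u, "v": v, "weight": d["weight"], "kind": d["kind"]}
                for u, v, d in sorted(self.graph.edges(data=True))
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _matrix_of(matrix: AugmentedMatrix | pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    frame = matrix.values if isinstance(matrix, AugmentedMatrix) else matrix
    m = frame.to_numpy(dtype=float)
    if m.size == 0:
        raise ValueError("empty matrix")
    if m.min() < -1e-9 or m.max() > 1 + 1e-9:
        raise ValueError("matrix values must lie in [0, 1]")
    return np.clip(m, 0.0, 1.0), list(frame.columns)


def train_autocm(matrix: AugmentedMatrix | pd.DataFrame, C: float | None = None,
                 epochs: int = 50, tol: float = 1e-4) -> AutoCMWeights:
    """Train the contractive map on records in [0, 1].

    ``C`` defaults to ⌈√(record count)⌉.  Weights start at a small positive
    constant (exactly zero is a fixed point of the first-layer update, which
    would disable the contraction mechanism that freezes the lateral weights
    before saturation) and records are presented in fixed order, so training
    is fully deterministic.  The first layer contracts until the hidden
    signals vanish, at which point the lateral matrix W stops changing with
    its entries differentiated by co-activation; ``converged`` is set when
    the largest epoch-to-epoch weight change drops below ``tol``.
    """
    m, names = _matrix_of(matrix)
    n_rec, n_nodes = m.shape
    if C is None:
        C = float(np.ceil(np.sqrt(n_rec)))
    if C <= 0:
        raise ValueError("contraction parameter C must be > 0")

    v = np.full(n_nodes, 1e-3)
    W = np.full((n_nodes, n_nodes), 1e-3)
    converged = False
    epochs_run = 0
    for epoch in range(epochs):
        W_prev = W.copy()
        for rec in m:
            m_h = rec * (1.0 - v / C)
            v = v + (rec - m_h) * (1.0 - v / C)
            net = m_h @ (1.0 - W / C)                       # Net_j
            m_out = m_h * (1.0 - net / C)
            # ΔW_ij = (m^h_j − m^out_j) · (1 − W_ij / C) · m^h_i
            W = W + np.outer(m_h, m_h - m_out) * (1.0 - W / C)
        if not np.isfinite(W).all() or not np.isfinite(v).all():
            raise RuntimeError(f"non-finite Auto-CM update at epoch {epoch}")
        if W.min() < -1e-9 or W.max() > C + 1e-9 or v.min() < -1e-9 or v.max() > C + 1e-9:
            raise RuntimeError(f"Auto-CM weights left [0, C] at epoch {epoch}")
        epochs_run = epoch + 1
        if np.max(np.abs(W - W_prev)) < tol:
            converged = True
            break
    return AutoCMWeights(C=C, v=v, W=W, node_names=names,
                         epochs_run=epochs_run, converged=converged)


def autocm_similarity(weights: AutoCMWeights) -> SimilarityMatrix:
    """Symmetrised trained lateral weights, read as similarities."""
    s = (weights.W + weights.W.T) / 2.0
    return SimilarityMatrix(node_names=list(weights.node_names), values=s,
                            source="autocm")


def pp_similarity(matrix: AugmentedMatrix | pd.DataFrame) -> SimilarityMatrix:
    """Prior-probability concordance index between column pairs.

    For columns u, x over records r (values in [0, 1]):
    concordance c = Σ_r u·x + (1−u)(1−x), discordance d = Σ_r u(1−x) + (1−u)x,
    similarity = c / (c + d) ∈ [0, 1].  Identical binary columns score 1,
    complementary ones 0.
    """
    m, names = _matrix_of(matrix)
    n_rec = m.shape[0]
    c = m.T @ m + (1 - m).T @ (1 - m)
    d = m.T @ (1 - m) + (1 - m).T @ m
    s = c / (c + d)      # c + d = n_rec exactly
    s = (s + s.T) / 2.0  # symmetric up to float error; enforce exactly
    return SimilarityMatrix(node_names=names, values=s, source="prior_probability")


def similarity_to_distance(S: SimilarityMatrix) -> np.ndarray:
    """d_ij = s_max − s_ij with s_max the largest off-diagonal similarity."""
    s = S.values
    off = s[~np.eye(len(s), dtype=bool)]
    s_max = float(off.max())
    d = s_max - s
    np.fill_diagonal(d, 0.0)
    return d


def minimum_spanning_tree(distance: np.ndarray,
                          node_names: list[str] | None = None) -> list[tuple[str, str]]:
    """Exact MST (Kruskal) with lexicographic node-pair tie-breaking.

    Edges are inserted in lexicographic node order; Kruskal's stable sort by
    weight then breaks ties by insertion order, so the result is
    byte-reproducible.
    """
    distance = np.asarray(distance, dtype=float)
    n = distance.shape[0]
    if n < 2:
        raise ValueError("MST requires at least 2 nodes")
    if not np.isfinite(distance).all():
        raise ValueError("distance matrix contains non-finite entries")
    names = node_names if node_names is not None else [str(i) for i in range(n)]
    idx = {nm: i for i, nm in enumerate(names)}
    g = nx.Graph()
    g.add_nodes_from(sorted(names))
    for u in sorted(names):
        for v_ in sorted(names):
            if u < v_:
                g.add_edge(u, v_, weight=float(distance[idx[u], idx[v_]]))
    tree = nx.minimum_spanning_edges(g, algorithm="kruskal", data=False)
    return sorted(tuple(sorted(e)) for e in tree)


def _degree_cv(g: nx.Graph) -> float:
    deg = np.array([d for _, d in g.degree()], dtype=float)
    return float(deg.std() / deg.mean())


def maximally_regular_graph(tree_edges: list[tuple[str, str]], S: SimilarityMatrix,
                            max_extra: int = 6) -> ConnectivityGraph:
    """Augment the MST with the strongest edges that keep degrees regular.

    Candidate non-tree edges are ranked by descending similarity (ties by
    lexicographic node pair).  For k = 0 … max_extra, the graph G_k = MST +
    top-k candidates is scored by H(G_k) = (1 − CV(degree)) · (mean
    similarity of the k added edges), H(G_0) = 0; the highest-H graph wins.
    Every (k, H) evaluation is kept in ``regularity_trace``.
    """
    names = S.node_names
    idx = {nm: i for i, nm in enumerate(names)}
    tree_set = {tuple(sorted(e)) for e in tree_edges}
    if {n for e in tree_set for n in e} != set(names):
        raise ValueError("tree must span all similarity-matrix nodes")

    candidates = []
    for i, u in enumerate(names):
        for v_ in names[i + 1:]:
            e = tuple(sorted((u, v_)))
            if e not in tree_set:
                candidates.append((-S.values[idx[e[0]], idx[e[1]]], e))
    candidates.sort()
    ranked = [e for _, e in candidates]

    base = nx.Graph()
    base.add_nodes_from(names)
    base.add_edges_from(tree_set)
    trace = [(0, 0.0)]
    best_k, best_h = 0, 0.0
    g = base.copy()
    sims = []
    for k, e in enumerate(ranked[:max_extra], start=1):
        g.add_edge(*e)
        sims.append(S.values[idx[e[0]], idx[e[1]]])
        h = (1.0 - _degree_cv(g)) * float(np.mean(sims))
        trace.append((k, h))
        if h > best_h:
            best_k, best_h = k, h

    extra = sorted(ranked[:best_k],
                   key=lambda e: (-S.values[idx[e[0]], idx[e[1]]], e))
    out = nx.Graph()
    for nm in names:
        role = ("outcome" if nm in (OUTCOME_HIGH, OUTCOME_LOW)
                else "variable-high" if nm.endswith(" high")
                else "variable-low" if nm.endswith(" low")
                else "variable")
        out.add_node(nm, role=role)
    for e in sorted(tree_set):
        out.add_edge(*e, weight=float(S.values[idx[e[0]], idx[e[1]]]), kind="tree")
    for e in extra:
        out.add_edge(*e, weight=float(S.values[idx[e[0]], idx[e[1]]]), kind="extra")
    return ConnectivityGraph(graph=out, tree_edges=sorted(tree_set),
                             extra_edges=extra, regularity_trace=trace)


def map_report(graph: ConnectivityGraph) -> dict:
    """Direct neighbours of each outcome node, strongest connection first."""
    g = graph.graph
    for node in (OUTCOME_HIGH, OUTCOME_LOW):
        if node not in g:
            raise ValueError(f"graph is missing outcome node {node!r}")
    report = {}
    for node in (OUTCOME_HIGH, OUTCOME_LOW):
        nbrs = [
            {"node": nbr, "weight": g[node][nbr]["weight"], "kind": g[node][nbr]["kind"]}
            for nbr in g.neighbors(node)
        ]
        nbrs.sort(key=lambda r: (-r["weight"], r["node"]))
        report[node] = nbrs
    return report


def build_map(matrix: AugmentedMatrix, similarity: str = "autocm",
              C: float | None = None, epochs: int = 50,
              max_extra: int = 6) -> tuple[SimilarityMatrix, ConnectivityGraph]:
    """Full map pipeline: similarity → distance → MST → MRG."""
    if similarity == "autocm":
        S = autocm_similarity(train_autocm(matrix, C=C, epochs=epochs))
    elif similarity == "prior_probability":
        S = pp_similarity(matrix)
    else:
        raise ValueError("similarity must be 'autocm' or 'prior_probability'")
    d = similarity_to_distance(S)
    tree = minimum_spanning_tree(d, S.node_names)
    return S, maximally_regular_graph(tree, S, max_extra=max_extra)


def plot_map(graph: ConnectivityGraph, path) -> None:
    """Render the map as a static figure (spring layout, seeded)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = graph.graph
    pos = nx.spring_layout(g, seed=0, weight="weight")
    colors = {"outcome": "#d62728", "variable-high": "#1f77b4",
              "variable-low": "#aec7e8", "variable": "#7f7f7f"}
    node_colors = [colors[g.nodes[n]["role"]] for n in g]
    fig, ax = plt.subplots(figsize=(10, 8))
    nx.draw_networkx_edges(g, pos, edgelist=graph.tree_edges, ax=ax, edge_color="black")
    nx.draw_networkx_edges(g, pos, edgelist=graph.extra_edges, ax=ax,
                           edge_color="red", style="dashed")
    nx.draw_networkx_nodes(g, pos, node_color=node_colors, node_size=350, ax=ax)
    nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
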
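"""Kernels over subjects: RBF on region features, WL subtree on graphs.

The region-feature view uses a Gaussian RBF kernel on the selected
clustering-coefficient columns.  The subgraph view converts each subject
into an ordinary labeled graph — the clique expansion of the subject's
hyper-edges that match a selected pattern, over the fixed ROI node set
with ROI-identity node labels — and compares subjects with the
Weisfeiler-Lehman subtree kernel: node labels are iteratively refined to
a compressed code of (own label, sorted multiset of neighbor labels) and
the kernel is the sum over refinement rounds of label-histogram dot
products.  Both kernels are cosine-normalized to unit diagonal before
being combined as the convex combination alpha*K_region +
(1-alpha)*K_subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from hyperbrain.hypernet import HyperNetwork
from hyperbrain.subgraphs import SubgraphCatalog

__all__ = [
    "LabeledGraph",
    "KernelBundle",
    "rbf_kernel",
    "default_gamma",
    "subject_graph",
    "wl_kernel",
    "normalize_kernel",
    "combine_kernels",
]


@dataclass
class LabeledGraph:
    """Simple undirected graph with total categorical node labels."""

    n_nodes: int
    edges: set[tuple[int, int]]
    labels: tuple

    def __post_init__(self) -> None:
        norm = set()
        for u, v in self.edges:
            if u == v:
                raise ValueError("self-loops are not allowed")
            norm.add((min(u, v), max(u, v)))
        self.edges = norm
        if len(self.labels) != self.n_nodes:
            raise ValueError("every node must carry a label")

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj


@dataclass
class KernelBundle:
    """Normalized per-view kernels and their convex combination."""

    subject_order: list[str]
    k_region: np.ndarray | None
    k_subgraph: np.ndarray | None
    alpha: float
    k_combined: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.k_combined = combine_kernels(self.k_region, self.k_subgraph,
                                          self.alpha)


def default_gamma(features: np.ndarray) -> float:
    """Bandwidth heuristic 1 / (p * median column variance)."""
    features = np.asarray(features, dtype=float)
    p = features.shape[1]
    med_var = float(np.median(features.var(axis=0)))
    if med_var <= 0:
        return 1.0 / p
    return 1.0 / (p * med_var)


def rbf_kernel(features: np.ndarray, gamma: float | None = None) -> np.ndarray:
    """K(i, j) = exp(-gamma * ||x_i - x_j||^2) with an exactly unit diagonal."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 1:
        raise ValueError(
            "no region features to build an RBF kernel from; "
            "fall back to the subgraph kernel alone (alpha=0)")
    if gamma is None:
        gamma = default_gamma(features)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    sq = squareform(pdist(features, "sqeuclidean"))
    k = np.exp(-gamma * sq)
    np.fill_diagonal(k, 1.0)
    return k


def subject_graph(network: HyperNetwork, selected: SubgraphCatalog | None,
                  roi_labels: tuple | None = None) -> LabeledGraph:
    """Clique expansion of the subject's pattern-matching hyper-edges.

    Nodes are all ROIs with ROI-identity labels; a subject matching no
    selected pattern yields an edgeless graph.  ``selected=None`` expands
    every hyper-edge (whole-network clique expansion).
    """
    m = network.n_nodes
    if roi_labels is None:
        roi_labels = tuple(range(m))
    if selected is None:
        keep = [e.nodes for e in network.edges]
    else:
        wanted = {p.nodes for p in selected.selected_patterns}
        keep = [e.nodes for e in network.edges
                if tuple(sorted(e.nodes)) in wanted]
    edges: set[tuple[int, int]] = set()
    for nodes in keep:
        for u, v in combinations(sorted(nodes), 2):
            edges.add((u, v))
    return LabeledGraph(n_nodes=m, edges=edges, labels=roi_labels)


def _wl_histograms(graphs: list[LabeledGraph], h: int) -> list[dict[int, int]]:
    """Per-graph sparse histograms of compressed labels over rounds 0..h.

    A single global dictionary maps every (label, sorted neighbor labels)
    signature to a fresh integer code, so equal signatures across graphs
    and rounds of the same depth always collide exactly and distinct ones
    never do.
    """
    adjs = [g.adjacency_lists() for g in graphs]
    codebook: dict = {}

    def code(sig) -> int:
        c = codebook.get(sig)
        if c is None:
            c = len(codebook)
            codebook[sig] = c
        return c

    current = [[code(("init", lab)) for lab in g.labels] for g in graphs]
    hists: list[dict[int, int]] = [dict() for _ in graphs]
    for it in range(h + 1):
        for gi, labs in enumerate(current):
            hist = hists[gi]
            for c in labs:
                hist[c] = hist.get(c, 0) + 1
        if it == h:
            break
        nxt = []
        for gi, labs in enumerate(current):
            adj = adjs[gi]
            nxt.append([
                code((labs[v], tuple(sorted(labs[u] for u in adj[v]))))
                for v in range(len(labs))
            ])
        current = nxt
    return hists


def wl_kernel(graphs: list[LabeledGraph], h: int = 3) -> np.ndarray:
    """Weisfeiler-Lehman subtree kernel matrix over a list of graphs."""
    if h < 0:
        raise ValueError("h must be >= 0")
    counts = {g.n_nodes for g in graphs}
    if len(counts) > 1:
        raise ValueError(f"graphs disagree on node count: {sorted(counts)}")
    hists = _wl_histograms(graphs, h)
    n_labels = 1 + max((max(hist) for hist in hists if hist), default=0)
    phi = np.zeros((len(graphs), n_labels))
    for i, hist in enumerate(hists):
        for label, count in hist.items():
            phi[i, label] = count
    return phi @ phi.T


def normalize_kernel(k: np.ndarray) -> np.ndarray:
    """Cosine normalization K(i,j) / sqrt(K(i,i) K(j,j)) to unit diagonal."""
    k = np.asarray(k, dtype=float)
    diag = np.diag(k)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        raise ValueError(
            f"kernel has non-positive self-similarity at subject index {bad[0]}; "
            "cannot normalize")
    scale = np.sqrt(diag)
    out = k / np.outer(scale, scale)
    np.fill_diagonal(out, 1.0)
    return out


def combine_kernels(k_region: np.ndarray | None, k_subgraph: np.ndarray | None,
                    alpha: float) -> np.ndarray:
    """Convex combination alpha*K_region + (1-alpha)*K_subgraph."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    if k_region is None and k_subgraph is None:
        raise ValueError("at least one kernel view is required")
    if k_region is None:
        if alpha != 0:
            raise ValueError("alpha must be 0 when the region kernel is absent")
        return np.asarray(k_subgraph, dtype=float)
    if k_subgraph is None:
        if alpha != 1:
            raise ValueError("alpha must be 1 when the subgraph kernel is absent")
        return np.asarray(k_region, dtype=float)
    k_region = np.asarray(k_region, dtype=float)
    k_subgraph = np.asarray(k_subgraph, dtype=float)
    if k_region.shape != k_subgraph.shape:
        raise ValueError(
            f"kernel shapes differ: {k_region.shape} vs {k_subgraph.shape}")
    return alpha * k_region + (1 - alpha) * k_subgraph
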
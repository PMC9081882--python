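"""Weighted graph metrics on the positive connectivity-strength network.

All metrics follow the weighted-undirected conventions of the Brain
Connectivity Toolbox and operate on the symmetric non-negative Fisher-z
weight matrix of a condition network:

- nodal degree  k_i  = number of incident edges (W_ij > 0),
- nodal strength s_i = sum of incident weights,
- clustering (Onnela): with w-hat = W / max(W),
      C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w-hat_ij w-hat_ih w-hat_jh)^(1/3)
  and C_i = 0 for k_i < 2,
- global efficiency: edge lengths L_ij = 1 / W_ij, all-pairs shortest-path
  distances d_ij, and E = mean over ordered pairs of 1 / d_ij with
  unreachable pairs contributing zero.

Regional metrics normalized to the network maximum, ranked in descending
order, identify the network hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "WeightedGraph",
    "MetricReport",
    "nodal_degree",
    "nodal_strength",
    "clustering_weighted",
    "global_efficiency",
    "summarize_network",
]


@dataclass
class WeightedGraph:
    """Symmetric non-negative weight matrix with named nodes."""

    nodes: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.nodes)
        if self.W.shape != (n, n):
            raise ValueError(f"weight matrix shape {self.W.shape} != ({n}, {n})")
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(self.W < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")

    @classmethod
    def from_network(cls, net) -> "WeightedGraph":
        """Positive-z weighted graph of a :class:`~cfosnet.network.FunctionalNetwork`."""
        return cls(nodes=list(net.atlas.codes), W=net.z_weights.copy())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def nodal_degree(G: WeightedGraph) -> np.ndarray:
    """Number of incident edges per node: k_i = #{j : W_ij > 0}."""
    return (G.W > 0).sum(axis=1).astype(int)


def nodal_strength(G: WeightedGraph) -> np.ndarray:
    """Sum of incident edge weights per node: s_i = sum_j W_ij."""
    return G.W.sum(axis=1)


def clustering_weighted(G: WeightedGraph) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering coefficient per node, and its mean.

    Weights are normalized by the global maximum before taking cube roots,
    so the coefficient is scale invariant and reaches 1 only for triangles
    of maximum-weight edges.  Nodes with fewer than two neighbours have
    C_i = 0; an all-zero graph yields all zeros.

    Returns
    -------
    (C, average) : ndarray, float
        Per-node coefficients and their mean over all nodes.
    """
    W = G.W
    k = nodal_degree(G)
    C = np.zeros(G.n_nodes)
    wmax = W.max()
    if wmax > 0:
        what = (W / wmax) ** (1.0 / 3.0)
        triangles = np.diag(what @ what @ what)  # 2 * sum of triangle intensities
        mask = k >= 2
        C[mask] = triangles[mask] / (k[mask] * (k[mask] - 1))
    return C, float(C.mean()) if G.n_nodes else 0.0


def global_efficiency(G: WeightedGraph) -> float:
    """Average inverse shortest-path distance over all ordered node pairs.

    Each positive weight maps to a length L_ij = 1/W_ij; distances are
    shortest paths over these lengths; unreachable pairs contribute zero
    efficiency (they stay in the average's denominator N(N-1)).
    """
    n = G.n_nodes
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(G.W > 0, 1.0 / G.W, 0.0)
    dist = shortest_path(csr_matrix(lengths), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(dist)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


@dataclass
class MetricReport:
    """Global and regional weighted metrics plus hub rankings."""

    nodes: list[str] = field(repr=False)
    global_efficiency: float
    average_clustering: float
    average_strength: float
    average_degree: float
    nodal_strength: np.ndarray = field(repr=False)
    nodal_degree: np.ndarray = field(repr=False)
    normalized_nodal_strength: np.ndarray = field(repr=False)
    normalized_nodal_degree: np.ndarray = field(repr=False)
    hub_order: list[str] = field(repr=False)
    hub_order_by_degree: list[str] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "global": {
                "global_efficiency": self.global_efficiency,
                "average_clustering": self.average_clustering,
                "average_strength": self.average_strength,
                "average_degree": self.average_degree,
            },
            "nodal": {
                node: {
                    "strength": float(self.nodal_strength[i]),
                    "degree": int(self.nodal_degree[i]),
                    "normalized_strength": float(self.normalized_nodal_strength[i]),
                    "normalized_degree": float(self.normalized_nodal_degree[i]),
                }
                for i, node in enumerate(self.nodes)
            },
            "hub_order": self.hub_order,
            "hub_order_by_degree": self.hub_order_by_degree,
        }


def _normalize(v: np.ndarray) -> np.ndarray:
    m = v.max()
    return v / m if m > 0 else np.zeros_like(v, dtype=float)


def summarize_network(G: WeightedGraph) -> MetricReport:
    """Full metric report: four global metrics, nodal vectors, hub ranking.

    Regional vectors are normalized to their network maximum; hubs are the
    nodes ranked by descending normalized strength (ties broken by
    normalized degree, then node order).  A second ranking keyed on degree
    is reported alongside, since both orderings identify hubs.
    """
    s = nodal_strength(G)
    k = nodal_degree(G)
    _, avg_clust = clustering_weighted(G)
    ns = _normalize(s)
    nk = _normalize(k.astype(float))
    order_strength = sorted(range(G.n_nodes), key=lambda i: (-ns[i], -nk[i], i))
    order_degree = sorted(range(G.n_nodes), key=lambda i: (-nk[i], -ns[i], i))
    return MetricReport(
        nodes=list(G.nodes),
        global_efficiency=global_efficiency(G),
        average_clustering=avg_clust,
        average_strength=float(s.mean()),
        average_degree=float(k.mean()),
        nodal_strength=s,
        nodal_degree=k,
        normalized_nodal_strength=ns,
        normalized_nodal_degree=nk,
        hub_order=[G.nodes[i] for i in order_strength],
        hub_order_by_degree=[G.nodes[i] for i in order_degree],
    )
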
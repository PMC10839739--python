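"""Multiplex-network cartography of the selected functional networks.

The significant connections of each frequency band form one layer of a
binary multiplex graph over the cortical parcels: same node set, five
layers. Six structural measures summarize how the layers relate
(Battiston-style multiplex conventions):

* overlapping degree ``o_i = sum_a k_i^a`` and its normalization by
  ``M (N - 1)`` (maximum possible degree summed over the M layers);
* multiplex participation coefficient
  ``P_i = M / (M - 1) * (1 - sum_a (k_i^a / o_i)^2)`` — 1 when a node's
  edges spread uniformly over layers, 0 when they sit in a single layer;
* pairwise multiplexity ``m_ab``: fraction of nodes active (degree >= 1)
  in both layers a and b;
* Hamming distance ``H_ab``: size of the edge symmetric difference over
  the number of reliable (unmasked) pairs;
* total overlap ratio: fraction of union edges present in >= 2 layers;
* edge intersection index: |intersection of all layers| / |union|.

Degenerate cases (isolated node, empty union) return 0 so that group
averaging stays well defined when a band yields no significant network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .selection import SelectionResult, compare_group_scores

__all__ = [
    "MultiplexNetwork",
    "fold_to_adjacency",
    "unfold_adjacency",
    "build_multiplex",
    "layer_degrees",
    "overlapping_degree",
    "participation_coefficient",
    "pairwise_multiplexity",
    "hamming_distance",
    "total_overlap_ratio",
    "edge_intersection_index",
    "multiplex_metrics",
    "cartography_summary",
    "write_graphml",
]


@dataclass
class MultiplexNetwork:
    """Binary node x node x layer adjacency stack (parcels x parcels x bands)."""

    adjacency: np.ndarray  # (N, N, M), uint8, symmetric layers, zero diagonal
    layer_names: list[str]
    mask: np.ndarray  # reliability mask over canonical pairs (for Hamming's K)
    node_labels: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_layers(self) -> int:
        return self.adjacency.shape[2]


def fold_to_adjacency(values: np.ndarray, mask: np.ndarray, n_parcels: int) -> np.ndarray:
    """Fold a reliable-pair vector into a symmetric parcel matrix.

    Values go back to their canonical upper-triangle positions, zeros are
    inserted for masked (unreliable) pairs, and the upper triangle is
    mirrored; the diagonal stays zero.
    """
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values)
    if mask.size != n_parcels * (n_parcels - 1) // 2:
        raise ValueError("mask length does not match the parcel pair count")
    if values.size != mask.sum():
        raise ValueError(
            f"expected {int(mask.sum())} reliable values, got {values.size}"
        )
    full = np.zeros(mask.size, dtype=float)
    full[mask] = values
    M = np.zeros((n_parcels, n_parcels))
    iu = np.triu_indices(n_parcels, k=1)
    M[iu] = full
    return M + M.T


def unfold_adjacency(matrix: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fold_to_adjacency`: reliable upper-triangle values."""
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu][np.asarray(mask, dtype=bool)]


def build_multiplex(
    results: list[SelectionResult],
    mask: np.ndarray,
    n_parcels: int,
    layer_names: list[str] | None = None,
) -> MultiplexNetwork:
    """One layer per band from the significant sets of SelectionResults.

    An edge is present in layer b iff the corresponding connection is in
    the significant set of that band's result; empty-flagged results give
    empty layers.
    """
    mask = np.asarray(mask, dtype=bool)
    M = len(results)
    adj = np.zeros((n_parcels, n_parcels, M), dtype=np.uint8)
    for b, res in enumerate(results):
        vec = np.zeros(int(mask.sum()))
        if not res.empty and res.significant.size:
            vec[res.significant] = 1.0
        adj[:, :, b] = fold_to_adjacency(vec, mask, n_parcels).astype(np.uint8)
    names = layer_names or [f"layer{b}" for b in range(M)]
    return MultiplexNetwork(adjacency=adj, layer_names=names, mask=mask)


def layer_degrees(net: MultiplexNetwork) -> np.ndarray:
    """Node degree per layer, shape (N, M)."""
    return net.adjacency.sum(axis=1)


def overlapping_degree(net: MultiplexNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Per-node overlapping degree and its normalization by M (N - 1)."""
    o = layer_degrees(net).sum(axis=1).astype(float)
    norm = o / (net.n_layers * (net.n_nodes - 1))
    return o, norm


def participation_coefficient(net: MultiplexNetwork) -> np.ndarray:
    """Multiplex participation coefficient, 0 for isolated nodes."""
    k = layer_degrees(net).astype(float)
    o = k.sum(axis=1)
    M = net.n_layers
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = k / o[:, None]
        P = (M / (M - 1)) * (1.0 - (frac**2).sum(axis=1))
    P = np.where(o > 0, P, 0.0)
    return np.clip(P, 0.0, 1.0)


def pairwise_multiplexity(net: MultiplexNetwork, a: int, b: int) -> float:
    """Fraction of nodes active (degree >= 1) in both layers a and b."""
    if a == b:
        raise ValueError("layers must differ")
    k = layer_degrees(net)
    active = k > 0
    return float((active[:, a] & active[:, b]).sum() / net.n_nodes)


def hamming_distance(net: MultiplexNetwork, a: int, b: int) -> float:
    """Normalized edge symmetric difference between layers a and b.

    Normalization is by the number of reliable (unmasked) pairs, i.e. the
    maximum number of edges either layer could carry.
    """
    if a == b:
        raise ValueError("layers must differ")
    K = int(np.asarray(net.mask, dtype=bool).sum())
    if K == 0:
        raise ValueError("mask admits no reliable pairs")
    iu = np.triu_indices(net.n_nodes, k=1)
    ea = net.adjacency[:, :, a][iu].astype(bool)
    eb = net.adjacency[:, :, b][iu].astype(bool)
    return float((ea ^ eb).sum() / K)


def _edge_layer_counts(net: MultiplexNetwork) -> np.ndarray:
    """For each upper-triangle pair, the number of layers containing it."""
    iu = np.triu_indices(net.n_nodes, k=1)
    return net.adjacency[iu[0], iu[1], :].astype(bool).sum(axis=1)


def total_overlap_ratio(net: MultiplexNetwork) -> float:
    """Fraction of union edges present in at least two layers (0 if empty)."""
    counts = _edge_layer_counts(net)
    union = (counts >= 1).sum()
    if union == 0:
        return 0.0
    return float((counts >= 2).sum() / union)


def edge_intersection_index(net: MultiplexNetwork) -> float:
    """|edges in every layer| / |edges in any layer| (0 if the union is empty)."""
    counts = _edge_layer_counts(net)
    union = (counts >= 1).sum()
    if union == 0:
        return 0.0
    return float((counts == net.n_layers).sum() / union)


def multiplex_metrics(net: MultiplexNetwork) -> dict:
    """All six structural measures for one multiplex network."""
    o, o_norm = overlapping_degree(net)
    M = net.n_layers
    pm = np.full((M, M), np.nan)
    hd = np.full((M, M), np.nan)
    for a in range(M):
        for b in range(M):
            if a != b:
                pm[a, b] = pairwise_multiplexity(net, a, b)
                hd[a, b] = hamming_distance(net, a, b)
    return {
        "overlapping_degree": o,
        "normalized_overlapping_degree": o_norm,
        "participation_coefficient": participation_coefficient(net),
        "pairwise_multiplexity": pm,
        "hamming_distance": hd,
        "total_overlap_ratio": total_overlap_ratio(net),
        "edge_intersection_index": edge_intersection_index(net),
    }


def cartography_summary(metrics_list: list[dict]) -> dict:
    """Mean, SD and skewness of each measure across analyses.

    Node- and layer-pair-valued measures are flattened before pooling;
    scalar measures pool directly. Used to average the cartography across
    scores and correlation directions.
    """
    if not metrics_list:
        raise ValueError("need at least one analysis")
    out = {}
    keys = metrics_list[0].keys()
    for key in keys:
        pooled = np.concatenate(
            [np.atleast_1d(np.asarray(m[key], dtype=float)).ravel() for m in metrics_list]
        )
        pooled = pooled[~np.isnan(pooled)]
        out[key] = {
            "mean": float(pooled.mean()) if pooled.size else 0.0,
            "sd": float(pooled.std(ddof=0)) if pooled.size else 0.0,
            "skewness": float(stats.skew(pooled))
            if pooled.size > 2 and pooled.std() > 0
            else 0.0,
        }
    return out


def compare_cartographies(metrics_a: list[dict], metrics_b: list[dict], key: str):
    """Rank-sum comparison of one pooled measure between two groups."""
    pool = lambda ms: np.concatenate(
        [np.atleast_1d(np.asarray(m[key], dtype=float)).ravel() for m in ms]
    )
    a, b = pool(metrics_a), pool(metrics_b)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    return compare_group_scores(a, b)


def write_graphml(path, net: MultiplexNetwork) -> None:
    """One networkx graph per layer, shared node ids, in a single GraphML file."""
    G = nx.Graph()
    labels = net.node_labels or [f"parcel{k}" for k in range(net.n_nodes)]
    G.add_nodes_from(labels)
    for b, name in enumerate(net.layer_names):
        iu = np.triu_indices(net.n_nodes, k=1)
        for i, j in zip(*iu):
            if net.adjacency[i, j, b]:
                if G.has_edge(labels[i], labels[j]):
                    G[labels[i]][labels[j]]["layers"] += f",{name}"
                else:
                    G.add_edge(labels[i], labels[j], layers=name)
    nx.write_graphml(G, path)
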
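"""MDS-GEO baseline: shortest-path distances + classical multidimensional
scaling.

The baseline takes the geometric assumption literally: hop counts on the
graph stand in for metric distances, and classical (Torgerson) MDS — the
spectral decomposition of the double-centered squared-distance matrix —
places the nodes in d dimensions.  Unlike t-LSE it preserves a predefined
metric rather than learning one, and shortest paths are notoriously
sensitive to inserted false edges, which is what the robustness
experiments probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.csgraph import shortest_path

from .graph_io import Network
from .model import Embedding

__all__ = ["DistanceMatrix", "shortest_path_matrix", "classical_mds",
           "fit_mdsgeo"]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of hop counts, zero diagonal."""

    D: np.ndarray
    node_order: list[str]


def shortest_path_matrix(net: Network) -> DistanceMatrix:
    """All-pairs BFS hop distances; requires a connected network."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    D = shortest_path(net.adjacency_matrix(), method="D", unweighted=True)
    if np.any(np.isinf(D)):
        raise ValueError(
            "network is disconnected; embed each connected component separately"
        )
    return DistanceMatrix(D=D, node_order=list(net.nodes))


def classical_mds(dm: DistanceMatrix, d: int) -> Embedding:
    """Torgerson MDS: eigendecompose B = -1/2 J (D*D) J.

    Coordinates are the top-d eigenvectors scaled by sqrt(eigenvalue);
    only positive eigenvalues are used (zero-filled if fewer than d).
    Eigenvector signs are fixed so the largest-magnitude entry is
    positive, making the output deterministic.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    D = dm.D
    n = D.shape[0]
    D2 = D * D
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = 0.5 * (B + B.T)  # symmetrize against round-off
    k = min(d, n)
    vals, vecs = eigh(B, subset_by_index=[n - k, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = np.zeros((n, d))
    for j in range(k):
        if vals[j] <= 0:
            break
        v = vecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, j] = np.sqrt(vals[j]) * v
    return Embedding(coords=coords, bias=0.0, t=1.0, node_order=list(dm.node_order))


def _youden_bias(emb: Embedding, net: Network) -> float:
    """Squared-distance cutoff maximizing Youden's J (sens + spec - 1)
    on the training edges vs all (or sampled) non-edges."""
    from .graph_io import _non_edge_pool, sample_non_edge_indices

    pos = net.edge_array()
    if net.n_nodes <= 2000:
        neg = _non_edge_pool(net)
    else:
        rng = np.random.default_rng(0)
        neg = sample_non_edge_indices(net, min(10 * net.n_edges,
                                               net.n_non_edges()), rng)
    sp = np.sort(emb.distances(pos) ** 2)
    sn = np.sort(emb.distances(neg) ** 2)
    if len(sp) == 0:
        return 0.0
    cuts = np.unique(np.concatenate([sp, sn]))
    sens = np.searchsorted(sp, cuts, side="right") / len(sp)
    spec = 1.0 - np.searchsorted(sn, cuts, side="right") / max(len(sn), 1)
    return float(cuts[np.argmax(sens + spec)])


def fit_mdsgeo(net: Network, d: int) -> Embedding:
    """Embed a connected network: BFS hop matrix -> classical MDS.

    The bias is set to the squared-distance threshold maximizing Youden's
    J on the training edges, so the embedding scores/classifies pairs the
    same way a t-LSE embedding does.
    """
    dm = shortest_path_matrix(net)
    emb = classical_mds(dm, d)
    bias = _youden_bias(emb, net)
    emb.bias = bias
    return emb


def fit_mdsgeo_components(net: Network, d: int) -> Embedding:
    """MDS-GEO for a possibly disconnected network.

    Each connected component is embedded independently (hop distances are
    only defined within a component) and the components are laid out along
    the first axis with gaps exceeding the largest component extent, so
    cross-component pairs score as distant non-interactions.  The bias is
    then set by Youden's J on the full edge set.
    """
    from .graph_io import connected_components

    comps = connected_components(net)
    if len(comps) == 1:
        return fit_mdsgeo(net, d)
    pieces = []
    for comp in comps:
        if comp.n_nodes == 1:
            pieces.append((comp, np.zeros((1, d))))
        else:
            dm = shortest_path_matrix(comp)
            pieces.append((comp, classical_mds(dm, d).coords))
    extents = [c[:, 0].max() - c[:, 0].min() if len(c) else 0.0
               for _, c in pieces]
    gap = max(extents) + 1.0
    coords = np.zeros((net.n_nodes, d))
    cursor = 0.0
    for (comp, sub), ext in zip(pieces, extents):
        shift = cursor - sub[:, 0].min()
        sub = sub.copy()
        sub[:, 0] += shift
        for v, row in zip(comp.nodes, sub):
            coords[net.index_of(v)] = row
        cursor += ext + gap
    emb = Embedding(coords=coords, bias=0.0, t=1.0, node_order=list(net.nodes))
    emb.bias = _youden_bias(emb, net)
    return emb
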
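"""The t-LSE probability model over node pairs and its MLE objective.

Each node i carries a d-dimensional coordinate z_i; a global scalar bias b
acts as the squared-distance cutoff of the geometric assumption.  The
margin of a pair is

    xi_ij = b - ||z_i - z_j||^2,

and the probability that the pair interacts is F_t(xi_ij), with
F_t(-xi_ij) the complementary non-interaction probability.  Training
minimizes the negative log-likelihood

    L(Z, b) = sum_{(i,j) in E} l_t(xi_ij)
            + w_neg * sum_{(i,j) in sampled non-edges} l_t(-xi_ij),

where ``w_neg`` reweights a uniform sample of non-edges so the sum is an
unbiased estimate of the full objective over all non-adjacent pairs.

The gradient has a weighted-average (graph Laplacian) structure: with
per-pair mixing coefficients W_ij = -2 * y_ij * l_t'(y_ij * xi_ij)
(positive for attracting edges, negative for repelling non-edges),

    dL/dz_i = sum_j W_ij (z_i - z_j),

so at a stationary point each embedded point is the W-weighted average of
its partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .graph_io import Network, sample_non_edge_indices
from .tmath import check_t, link_eval

__all__ = ["Embedding", "PairSet", "PairWeights", "build_pairset",
           "pair_margin", "objective", "gradient"]


@dataclass
class Embedding:
    """Per-node coordinates plus the bias and loss parameter."""

    coords: np.ndarray  # (n, d)
    bias: float
    t: float
    node_order: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be (n, d) with d >= 1")
        if self.coords.shape[0] != len(self.node_order):
            raise ValueError("coords rows must match node_order")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        check_t(self.t)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def distances(self, pairs: np.ndarray) -> np.ndarray:
        """Euclidean distances for an (m, 2) index-pair array."""
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        diff = self.coords[pairs[:, 0]] - self.coords[pairs[:, 1]]
        return np.sqrt(np.einsum("ij,ij->i", diff, diff))

    def to_frame(self):
        import pandas as pd

        cols = {f"x{k}": self.coords[:, k] for k in range(self.dim)}
        return pd.DataFrame({"node": self.node_order, **cols})


@dataclass
class PairSet:
    """Indexed positive (y=+1) and negative (y=-1) training pairs.

    ``neg_weight`` multiplies each negative term so that a sampled
    negative set estimates the full sum over non-edges unbiasedly.
    """

    pos_pairs: np.ndarray  # (P, 2) int
    neg_pairs: np.ndarray  # (N, 2) int
    neg_weight: float = 1.0

    def __post_init__(self) -> None:
        self.pos_pairs = np.asarray(self.pos_pairs, dtype=np.int64).reshape(-1, 2)
        self.neg_pairs = np.asarray(self.neg_pairs, dtype=np.int64).reshape(-1, 2)
        if self.neg_weight < 0:
            raise ValueError("neg_weight must be >= 0")

    def all_pairs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Concatenated pairs, labels y in {+1,-1}, and per-pair weights."""
        pairs = np.concatenate([self.pos_pairs, self.neg_pairs], axis=0)
        y = np.concatenate(
            [np.ones(len(self.pos_pairs)), -np.ones(len(self.neg_pairs))]
        )
        w = np.concatenate(
            [np.ones(len(self.pos_pairs)),
             np.full(len(self.neg_pairs), self.neg_weight)]
        )
        return pairs, y, w


@dataclass
class PairWeights:
    """Sparse symmetric mixing-coefficient matrix W and its row sums."""

    W: csr_matrix
    rowsum: np.ndarray


def build_pairset(
    net: Network,
    neg_ratio: float = 5.0,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> PairSet:
    """Positive pairs = edges; negatives = all non-edges (``exact``) or a
    uniform sample of ``round(neg_ratio * |E|)`` of them, reweighted by
    (#non-edges / #sampled) to keep the objective unbiased."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = net.edge_array()
    n_non = net.n_non_edges()
    if exact or n_non == 0:
        from .graph_io import _non_edge_pool

        neg = _non_edge_pool(net)
        return PairSet(pos_pairs=pos, neg_pairs=neg, neg_weight=1.0)
    count = min(int(round(neg_ratio * max(net.n_edges, 1))), n_non)
    count = max(count, 1)
    neg = sample_non_edge_indices(net, count, rng)
    return PairSet(pos_pairs=pos, neg_pairs=neg, neg_weight=n_non / count)


def _margins(emb: Embedding, pairs: np.ndarray) -> np.ndarray:
    diff = emb.coords[pairs[:, 0]] - emb.coords[pairs[:, 1]]
    return emb.bias - np.einsum("ij,ij->i", diff, diff)


def pair_margin(emb: Embedding, i: int, j: int) -> float:
    """xi_ij = b - ||z_i - z_j||^2 (symmetric in i, j)."""
    if i == j:
        raise ValueError("pair_margin requires i != j")
    return float(_margins(emb, np.array([[i, j]]))[0])


def objective(emb: Embedding, pairs: PairSet) -> float:
    """Negative log-likelihood of the pair labels under the t-link."""
    idx, y, w = pairs.all_pairs()
    if len(idx) == 0:
        return 0.0
    u = y * _margins(emb, idx)
    le = link_eval(u, emb.t)
    return float(np.sum(w * le.loss))


class PairEvaluator:
    """Cached pair arrays for repeated objective/gradient evaluation.

    Used by the optimizer's inner loops, where the pair set is fixed and
    only (Z, b) change; avoids re-concatenating index/label/weight arrays
    and re-assembling sparse matrices on every function evaluation.
    """

    def __init__(self, pairs: PairSet, t: float, n: int):
        self.idx, self.y, self.w = pairs.all_pairs()
        self.t = check_t(t)
        self.n = n
        self.wy = self.w * self.y

    def sq_dists(self, Z: np.ndarray) -> np.ndarray:
        diff = Z[self.idx[:, 0]] - Z[self.idx[:, 1]]
        return np.einsum("ij,ij->i", diff, diff)

    def objective_from_d2(self, d2: np.ndarray, b: float) -> float:
        le = link_eval(self.y * (b - d2), self.t)
        return float(np.sum(self.w * le.loss))

    def db_from_d2(self, d2: np.ndarray, b: float) -> float:
        le = link_eval(self.y * (b - d2), self.t)
        return float(np.sum(self.wy * le.dloss_du))

    def objective(self, Z: np.ndarray, b: float) -> float:
        return self.objective_from_d2(self.sq_dists(Z), b)

    def gradient(
        self, Z: np.ndarray, b: float
    ) -> tuple[np.ndarray, float, PairWeights]:
        le = link_eval(self.y * (b - self.sq_dists(Z)), self.t)
        wvals = -2.0 * self.wy * le.dloss_du
        i, j = self.idx[:, 0], self.idx[:, 1]
        W = coo_matrix(
            (np.concatenate([wvals, wvals]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n, self.n),
        ).tocsr()
        rowsum = np.asarray(W.sum(axis=1)).ravel()
        dZ = rowsum[:, None] * Z - W @ Z
        db = float(np.sum(self.wy * le.dloss_du))
        return dZ, db, PairWeights(W=W, rowsum=rowsum)


def gradient(
    emb: Embedding, pairs: PairSet
) -> tuple[np.ndarray, float, PairWeights]:
    """Gradient of :func:`objective` in (Z, b).

    Returns ``(dZ, db, weights)`` where ``dZ[i] = sum_j W_ij (z_i - z_j)``
    with mixing coefficients ``W_ij = -2 y l'(u) w`` (attractive > 0 on
    edges, repulsive < 0 on non-edges) and ``db = sum w y l'(u)``.
    """
    n, d = emb.coords.shape
    idx, y, w = pairs.all_pairs()
    if len(idx) == 0:
        return np.zeros((n, d)), 0.0, PairWeights(
            W=csr_matrix((n, n)), rowsum=np.zeros(n)
        )
    u = y * _margins(emb, idx)
    le = link_eval(u, emb.t)
    wvals = -2.0 * y * le.dloss_du * w  # mixing coefficients
    i, j = idx[:, 0], idx[:, 1]
    W = coo_matrix(
        (np.concatenate([wvals, wvals]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    dZ = rowsum[:, None] * emb.coords - W @ emb.coords
    db = float(np.sum(w * y * le.dloss_du))
    return dZ, db, PairWeights(W=W, rowsum=rowsum)
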
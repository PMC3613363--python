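"""Random-graph null models and the noise-perturbation operator.

The generators mirror the standard comparison set for PPI network
modeling:

* ER — Erdos-Renyi with an exact edge count (uses only n and m);
* ER-DD — degree-distribution-matched random graph via the stubs method;
* SF — Barabasi-Albert preferential attachment, with fractional
  attachment counts so the expected edge count matches a target;
* Sticky — stickiness-index model: node i gets theta_i proportional to
  its degree, pair (i, j) is an edge with probability theta_i * theta_j;
* GEO — geometric random graph: uniform points in the unit cube, the
  m closest pairs become edges.  This is the synthetic ground truth for
  the recovery and robustness experiments, since it makes the geometric
  assumption exact and returns the generating coordinates.

``perturb`` simulates noisy interaction data by deleting a fraction of
edges and inserting an equal number of false ones.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial.distance import pdist

from .graph_io import Network, sample_non_edge_indices

logger = logging.getLogger(__name__)

__all__ = ["gen_er", "gen_erdd", "gen_sf", "gen_sticky", "gen_geometric",
           "perturb"]


def _labels(n: int) -> list[str]:
    return [f"v{i}" for i in range(n)]


def _pairs_from_lin(lin: np.ndarray, n: int) -> list[tuple[str, str]]:
    i, j = np.divmod(lin, n)
    return [(f"v{a}", f"v{b}") for a, b in zip(i, j)]


def gen_er(n: int, m: int, seed: int) -> Network:
    """Erdos-Renyi G(n, m): exactly m distinct uniform edges."""
    total = n * (n - 1) // 2
    if m > total:
        raise ValueError(f"m={m} exceeds the {total} possible edges")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(total, size=m, replace=False)
    edges = [(f"v{iu[p]}", f"v{ju[p]}") for p in np.sort(pick)]
    return Network.from_edges(edges, nodes=_labels(n))


def gen_erdd(reference: Network, seed: int,
             max_rejects_factor: int = 1000, retries: int = 10) -> Network:
    """Degree-matched random graph by the stubs method.

    Each node receives as many stubs as its reference degree; random stub
    pairs are joined unless the join would create a self-loop or duplicate
    edge.  A run can deadlock (the remaining stubs admit no legal join,
    detected after ``max_rejects_factor * |E|`` consecutive rejections);
    the matching is then restarted from scratch, up to ``retries`` times.
    If every attempt deadlocks, the last attempt's unplaceable stubs are
    discarded (logged) and the output degree sequence falls short of the
    reference by that residue.
    """
    if reference.n_nodes == 0:
        raise ValueError("reference network is empty")
    root = np.random.default_rng(seed)
    best: Network | None = None
    for _ in range(max(retries, 1)):
        net, leftover = _erdd_attempt(reference, root, max_rejects_factor)
        if leftover == 0:
            return net
        if best is None or net.n_edges > best.n_edges:
            best = net
    logger.info("stubs method: degree sequence incomplete after retries")
    return best


def _erdd_attempt(
    reference: Network, rng: np.random.Generator, max_rejects_factor: int
) -> tuple[Network, int]:
    deg = reference.degrees()
    stubs: list[int] = []
    for v, k in enumerate(deg):
        stubs.extend([v] * int(k))
    edges: set[tuple[int, int]] = set()
    max_rejects = max_rejects_factor * max(reference.n_edges, 1)
    rejects = 0
    while len(stubs) >= 2 and rejects < max_rejects:
        a_pos = int(rng.integers(len(stubs)))
        b_pos = int(rng.integers(len(stubs)))
        if a_pos == b_pos:
            rejects += 1
            continue
        a, b = stubs[a_pos], stubs[b_pos]
        if a == b or (min(a, b), max(a, b)) in edges:
            rejects += 1
            continue
        edges.add((min(a, b), max(a, b)))
        for pos in sorted((a_pos, b_pos), reverse=True):
            stubs[pos] = stubs[-1]
            stubs.pop()
        rejects = 0
    if stubs:
        logger.info("stubs method: %d unplaceable stub(s) discarded", len(stubs))
    labels = reference.nodes
    net = Network.from_edges(
        [(labels[a], labels[b]) for a, b in sorted(edges)], nodes=labels
    )
    return net, len(stubs)


def gen_sf(n: int, m_total: int, seed: int) -> Network:
    """Barabasi-Albert scale-free graph with expected m_total edges.

    Growth starts from a path on m0 nodes; each arriving node attaches to
    k existing nodes chosen preferentially (probability proportional to
    degree, without replacement), where k is floor(mf) or ceil(mf) with
    the fractional part as Bernoulli probability and mf chosen so the
    expected final edge count equals ``m_total``.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if m_total > n * (n - 1) // 2:
        raise ValueError("m_total exceeds the possible edge count")
    rng = np.random.default_rng(seed)
    mbar = m_total / n
    m0 = max(2, math.ceil(mbar) + 1)
    m0 = min(m0, n - 1)
    seed_edges = [(i, i + 1) for i in range(m0 - 1)]
    mf = (m_total - (m0 - 1)) / (n - m0)
    if mf < 0:
        mf = 0.0
    edges = list(seed_edges)
    # repeated-endpoint list makes degree-proportional sampling O(1)
    endpoint_pool: list[int] = [v for e in seed_edges for v in e]
    for new in range(m0, n):
        k = int(mf) + (1 if rng.random() < mf - int(mf) else 0)
        k = min(k, new)
        targets: set[int] = set()
        guard = 0
        while len(targets) < k and guard < 100 * (k + 1):
            guard += 1
            if endpoint_pool:
                cand = endpoint_pool[int(rng.integers(len(endpoint_pool)))]
            else:
                cand = int(rng.integers(new))
            if cand != new:
                targets.add(cand)
        for tgt in sorted(targets):
            edges.append((tgt, new))
            endpoint_pool.extend((tgt, new))
    return Network.from_edges(
        [(f"v{a}", f"v{b}") for a, b in edges], nodes=_labels(n)
    )


def gen_sticky(reference: Network, seed: int) -> Network:
    """Stickiness-index model: theta_i = deg_i / sqrt(sum_k deg_k);
    each pair is an edge independently with probability
    min(1, theta_i * theta_j)."""
    if reference.n_edges < 1:
        raise ValueError("reference must have at least one edge")
    rng = np.random.default_rng(seed)
    deg = reference.degrees().astype(float)
    theta = deg / np.sqrt(deg.sum())
    n = reference.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    p = theta[iu] * theta[ju]
    clipped = int(np.sum(p > 1.0))
    if clipped:
        logger.info("sticky model: %d pair probability(ies) clipped at 1", clipped)
    p = np.minimum(p, 1.0)
    keep = rng.random(len(p)) < p
    labels = reference.nodes
    return Network.from_edges(
        [(labels[a], labels[b]) for a, b in zip(iu[keep], ju[keep])],
        nodes=labels,
    )


def gen_geometric(
    n: int, d_true: int, m_target: int, seed: int
) -> tuple[Network, np.ndarray]:
    """Geometric random graph: n uniform points in the unit d_true-cube,
    edges = the m_target closest pairs (radius set by the m_target-th
    smallest distance; ties broken by pair index).  Returns the network
    and the generating coordinates — with them, true distances separate
    edges from non-edges perfectly."""
    total = n * (n - 1) // 2
    if m_target > total:
        raise ValueError("m_target exceeds the possible edge count")
    rng = np.random.default_rng(seed)
    coords = rng.random((n, d_true))
    dists = pdist(coords)
    order = np.argsort(dists, kind="stable")[:m_target]
    iu, ju = np.triu_indices(n, k=1)
    edges = [(f"v{iu[p]}", f"v{ju[p]}") for p in np.sort(order)]
    return Network.from_edges(edges, nodes=_labels(n)), coords


def perturb(net: Network, frac: float, seed: int) -> Network:
    """Noise operator: remove floor(frac * |E|) uniformly chosen edges and
    insert the same number of uniformly chosen non-edges.  The edge count
    and node set are conserved."""
    if not (0 <= frac < 1):
        raise ValueError("frac must be in [0, 1)")
    k = int(frac * net.n_edges)
    if k == 0:
        return Network.from_edges(net.edge_labels(), nodes=net.nodes)
    rng = np.random.default_rng(seed)
    drop = set(rng.choice(net.n_edges, size=k, replace=False).tolist())
    kept = [e for idx, e in enumerate(net.edges) if idx not in drop]
    inserted = sample_non_edge_indices(net, k, rng)
    labels = net.nodes
    new_edges = [(labels[i], labels[j]) for i, j in kept]
    new_edges += [(labels[i], labels[j]) for i, j in inserted]
    return Network.from_edges(new_edges, nodes=labels)
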
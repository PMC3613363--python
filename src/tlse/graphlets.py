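"""Graphlet orbit counting and GDD agreement.

Graphlets are small connected induced subgraphs (2-5 nodes); an orbit is
an automorphism-equivalence class of node positions within a graphlet.
The graphlet degree of a node counts how often it touches each orbit; the
graphlet degree distribution (GDD) of a network is, per orbit j, the
distribution over k of the number of nodes touching orbit j exactly k
times.  The GDD agreement between two networks compares their scaled,
normalized GDDs orbit by orbit and averages; it lies in [0, 1], with 1
meaning identical distributions.

Orbits for graphlets up to 4 nodes (ids 0-14) follow the standard
numbering (0 = edge, 1/2 = path end/middle, 3 = triangle, ...); it is
reproduced constructively by ordering canonical graphs by (size, edge
count, max degree) and orbit classes within a graphlet by degree.  Orbits
of 5-node graphlets (ids 15-72) are assigned by the same deterministic
canonical order.

Counting enumerates every connected induced subgraph exactly once (the
ESU algorithm) and resolves its orbits through a cached canonical-form
table; with at most 2^10 distinct local adjacency patterns the table is
tiny.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["GDDProfile", "orbit_counts", "gdd_profile", "gdd_agreement",
           "n_orbits"]

_PAIRS = {k: list(itertools.combinations(range(k), 2)) for k in range(2, 6)}
_PAIR_BIT = {
    k: {p: b for b, p in enumerate(pairs)} for k, pairs in _PAIRS.items()
}


def _apply_perm(mask: int, k: int, perm: tuple[int, ...]) -> int:
    out = 0
    for bit, (a, b) in enumerate(_PAIRS[k]):
        if mask >> bit & 1:
            pa, pb = perm[a], perm[b]
            out |= 1 << _PAIR_BIT[k][(min(pa, pb), max(pa, pb))]
    return out


def _degrees(mask: int, k: int) -> list[int]:
    deg = [0] * k
    for bit, (a, b) in enumerate(_PAIRS[k]):
        if mask >> bit & 1:
            deg[a] += 1
            deg[b] += 1
    return deg


def _is_connected(mask: int, k: int) -> bool:
    adj = [set() for _ in range(k)]
    for bit, (a, b) in enumerate(_PAIRS[k]):
        if mask >> bit & 1:
            adj[a].add(b)
            adj[b].add(a)
    seen = {0}
    stack = [0]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == k


class _OrbitRegistry:
    """Canonical graphlets of sizes 2..max_size and their global orbit ids."""

    def __init__(self, max_size: int):
        if max_size not in (4, 5):
            raise ValueError("max_graphlet_size must be 4 or 5")
        self.max_size = max_size
        self.n_orbits = 0
        # (k, canonical mask) -> list of orbit ids per canonical position
        self._canon_orbits: dict[tuple[int, int], list[int]] = {}
        # (k, raw mask) -> tuple of orbit ids per raw position (lazy)
        self._raw_cache: dict[tuple[int, int], tuple[int, ...]] = {}
        for k in range(2, max_size + 1):
            self._register_size(k)

    def _register_size(self, k: int) -> None:
        perms = list(itertools.permutations(range(k)))
        canon_seen: dict[int, None] = {}
        infos = []
        for mask in range(1, 1 << len(_PAIRS[k])):
            if not _is_connected(mask, k):
                continue
            canon = min(_apply_perm(mask, k, p) for p in perms)
            if canon in canon_seen:
                continue
            canon_seen[canon] = None
            deg = _degrees(canon, k)
            infos.append(
                (bin(canon).count("1"), max(deg), tuple(sorted(deg)), canon)
            )
        infos.sort()
        for _, _, _, canon in infos:
            autos = [p for p in perms if _apply_perm(canon, k, p) == canon]
            # orbit classes = automorphism equivalence of positions
            reps = list(range(k))
            for p in autos:
                for i in range(k):
                    j = p[i]
                    ri, rj = _find(reps, i), _find(reps, j)
                    if ri != rj:
                        reps[max(ri, rj)] = min(ri, rj)
            classes: dict[int, list[int]] = {}
            for i in range(k):
                classes.setdefault(_find(reps, i), []).append(i)
            deg = _degrees(canon, k)
            adj = [[] for _ in range(k)]
            for bit, (a, b) in enumerate(_PAIRS[k]):
                if canon >> bit & 1:
                    adj[a].append(b)
                    adj[b].append(a)

            def class_key(members):
                i = members[0]
                return (deg[i], tuple(sorted(deg[w] for w in adj[i])), min(members))

            ordered = sorted(classes.values(), key=class_key)
            pos_orbit = [0] * k
            for cls in ordered:
                for i in cls:
                    pos_orbit[i] = self.n_orbits
                self.n_orbits += 1
            self._canon_orbits[(k, canon)] = pos_orbit

    def orbits_of(self, mask: int, k: int) -> tuple[int, ...]:
        """Orbit ids per local position for a raw adjacency mask."""
        key = (k, mask)
        hit = self._raw_cache.get(key)
        if hit is not None:
            return hit
        best = None
        best_perm = None
        for p in itertools.permutations(range(k)):
            pm = _apply_perm(mask, k, p)
            if best is None or pm < best:
                best, best_perm = pm, p
        pos_orbit = self._canon_orbits[(k, best)]
        out = tuple(pos_orbit[best_perm[i]] for i in range(k))
        self._raw_cache[key] = out
        return out


def _find(reps: list[int], i: int) -> int:
    while reps[i] != i:
        reps[i] = reps[reps[i]]
        i = reps[i]
    return i


@lru_cache(maxsize=None)
def _registry(max_size: int) -> _OrbitRegistry:
    return _OrbitRegistry(max_size)


def n_orbits(max_graphlet_size: int) -> int:
    """15 orbits for graphlets up to 4 nodes, 73 up to 5."""
    return _registry(max_graphlet_size).n_orbits


def _esu_subsets(adj: list[set[int]], k: int):
    """Enumerate each connected induced k-subset exactly once (ESU)."""
    n = len(adj)

    def extend(sub: list[int], ext: set[int], v: int, nbr_sub: set[int]):
        if len(sub) == k:
            yield tuple(sub)
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            excl = {u for u in adj[w] if u > v and u not in sub and u not in nbr_sub}
            yield from extend(sub + [w], ext | excl, v, nbr_sub | adj[w])
        return

    for v in range(n):
        yield from extend([v], {u for u in adj[v] if u > v}, v, set(adj[v]))


def orbit_counts(net, max_graphlet_size: int = 4) -> np.ndarray:
    """Per-node, per-orbit touch counts as an (n, n_orbits) int array.

    Counts every connected induced subgraph on 2..max_graphlet_size nodes
    by exhaustive enumeration.
    """
    reg = _registry(max_graphlet_size)
    n = net.n_nodes
    counts = np.zeros((n, reg.n_orbits), dtype=np.int64)
    adj = [set(a) for a in net.adjacency_lists()]
    for i, j in net.edges:  # size-2 graphlet: the edge, orbit 0
        counts[i, 0] += 1
        counts[j, 0] += 1
    edge_set = {(i, j) for i, j in net.edges}
    for k in range(3, max_graphlet_size + 1):
        pair_bits = _PAIRS[k]
        for sub in _esu_subsets(adj, k):
            nodes = sorted(sub)
            mask = 0
            for bit, (a, b) in enumerate(pair_bits):
                if (nodes[a], nodes[b]) in edge_set:
                    mask |= 1 << bit
            orbits = reg.orbits_of(mask, k)
            for local, node in enumerate(nodes):
                counts[node, orbits[local]] += 1
    return counts


@dataclass
class GDDProfile:
    """Normalized graphlet degree distributions, one per orbit.

    ``orbits[j]`` maps k (>= 1) to the scaled (1/k), per-orbit-normalized
    mass N_j(k); orbits with no touching node are empty dicts.
    """

    orbits: dict[int, dict[int, float]]
    max_graphlet_size: int


def gdd_profile(counts: np.ndarray, max_graphlet_size: int = 4) -> GDDProfile:
    """Histogram node counts per orbit, scale each bin k by 1/k and
    normalize to unit total per orbit."""
    counts = np.asarray(counts)
    profiles: dict[int, dict[int, float]] = {}
    for j in range(counts.shape[1]):
        col = counts[:, j]
        ks, freq = np.unique(col[col >= 1], return_counts=True)
        scaled = {int(k): f / k for k, f in zip(ks, freq)}
        total = sum(scaled.values())
        profiles[j] = (
            {k: v / total for k, v in scaled.items()} if total > 0 else {}
        )
    return GDDProfile(orbits=profiles, max_graphlet_size=max_graphlet_size)


def _orbit_agreement(a: dict[int, float], b: dict[int, float]) -> float:
    support = set(a) | set(b)
    sq = sum((a.get(k, 0.0) - b.get(k, 0.0)) ** 2 for k in support)
    return 1.0 - np.sqrt(sq) / np.sqrt(2.0)


def gdd_agreement(
    netA,
    netB,
    max_graphlet_size: int = 4,
    mean: str = "arithmetic",
    return_per_orbit: bool = False,
):
    """GDD agreement between two networks, in [0, 1].

    Per orbit j: A_j = 1 - ||N_j^A - N_j^B||_2 / sqrt(2); the overall
    agreement is the arithmetic (default) or geometric mean over orbits
    where at least one network has mass (both-empty orbits are skipped).
    """
    if mean not in ("arithmetic", "geometric"):
        raise ValueError("mean must be 'arithmetic' or 'geometric'")
    if netA.n_nodes == 0 or netB.n_nodes == 0:
        raise ValueError("both networks must be nonempty")
    pa = gdd_profile(orbit_counts(netA, max_graphlet_size), max_graphlet_size)
    pb = gdd_profile(orbit_counts(netB, max_graphlet_size), max_graphlet_size)
    per_orbit: dict[int, float] = {}
    for j in pa.orbits:
        a, b = pa.orbits[j], pb.orbits[j]
        if not a and not b:
            continue
        per_orbit[j] = _orbit_agreement(a, b)
    vals = np.array(list(per_orbit.values()))
    if len(vals) == 0:
        raise ValueError("no orbit with mass in either network")
    agg = float(vals.mean()) if mean == "arithmetic" else float(
        np.exp(np.mean(np.log(np.maximum(vals, 1e-300))))
    )
    if return_per_orbit:
        return agg, per_orbit
    return agg
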
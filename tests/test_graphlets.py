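"""Graphlet orbit counts (vs brute-force oracle) and GDD agreement."""

import itertools

import networkx as nx
import numpy as np
import pytest

from tlse.graph_io import Network
from tlse.graphlets import gdd_agreement, gdd_profile, n_orbits, orbit_counts
from tlse.nullmodels import gen_er

# Reference graphlet/orbit table for sizes 2-4 (standard numbering):
# for each graphlet an edge list on 0..k-1 and the orbit of each node.
REFERENCE_GRAPHLETS = [
    ([(0, 1)], {0: 0, 1: 0}),                                  # G0 edge
    ([(0, 1), (1, 2)], {0: 1, 1: 2, 2: 1}),                    # G1 path P3
    ([(0, 1), (1, 2), (0, 2)], {0: 3, 1: 3, 2: 3}),            # G2 triangle
    ([(0, 1), (1, 2), (2, 3)], {0: 4, 1: 5, 2: 5, 3: 4}),      # G3 path P4
    ([(0, 1), (0, 2), (0, 3)], {0: 7, 1: 6, 2: 6, 3: 6}),      # G4 claw
    ([(0, 1), (1, 2), (2, 3), (3, 0)], {i: 8 for i in range(4)}),  # G5 C4
    ([(0, 1), (1, 2), (0, 2), (2, 3)],
     {0: 10, 1: 10, 2: 11, 3: 9}),                             # G6 paw
    ([(0, 1), (1, 2), (0, 2), (0, 3), (1, 3)],
     {0: 13, 1: 13, 2: 12, 3: 12}),                            # G7 diamond
    ([(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
     {i: 14 for i in range(4)}),                               # G8 K4
]


def oracle_orbit_counts(net: Network) -> np.ndarray:
    """Independent brute force: enumerate all node subsets of size 2-4,
    keep connected induced subgraphs, and identify each node's orbit by an
    explicit isomorphism onto the reference table."""
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    g.add_edges_from(net.edges)
    counts = np.zeros((net.n_nodes, 15), dtype=int)
    refs = [(nx.Graph(e), orb) for e, orb in REFERENCE_GRAPHLETS]
    for k in (2, 3, 4):
        for sub in itertools.combinations(range(net.n_nodes), k):
            h = g.subgraph(sub)
            if h.number_of_edges() == 0 or not nx.is_connected(h):
                continue
            for ref, orb in refs:
                if ref.number_of_nodes() != k:
                    continue
                gm = nx.isomorphism.GraphMatcher(h, ref)
                if gm.is_isomorphic():
                    for node, ref_node in gm.mapping.items():
                        counts[node, orb[ref_node]] += 1
                    break
            else:  # pragma: no cover
                raise AssertionError("unmatched connected subgraph")
    return counts


class TestOrbitCounts:
    def test_orbit_inventory(self):
        assert n_orbits(4) == 15
        assert n_orbits(5) == 73

    def test_triangle_by_hand(self):
        tri = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        c = orbit_counts(tri, 4)
        # every node touches 2 edges (orbit 0) and 1 triangle (orbit 3)
        assert np.all(c[:, 0] == 2)
        assert np.all(c[:, 3] == 1)
        assert c[:, [1, 2]].sum() == 0  # no induced P3 in K3

    def test_p3_by_hand(self):
        p3 = Network.from_edges([("a", "b"), ("b", "c")])
        c = orbit_counts(p3, 4)
        ia, ib, ic = 0, 1, 2
        assert c[ia, 1] == 1 and c[ic, 1] == 1  # path ends
        assert c[ib, 2] == 1  # path middle
        assert c[ib, 0] == 2 and c[ia, 0] == 1

    def test_edgeless(self):
        net = Network.from_edges([], nodes=["a", "b", "c"])
        assert orbit_counts(net, 4).sum() == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 8))
        m = int(rng.integers(n - 1, n * (n - 1) // 2 + 1))
        net = gen_er(n, m, seed=seed + 100)
        np.testing.assert_array_equal(
            orbit_counts(net, 4), oracle_orbit_counts(net)
        )

    def test_matches_oracle_on_all_four_node_graphs(self):
        """Exhaustive: every simple graph on 4 nodes."""
        for mask in range(1 << 6):
            pairs = list(itertools.combinations(range(4), 2))
            edges = [(f"n{a}", f"n{b}") for bit, (a, b) in enumerate(pairs)
                     if mask >> bit & 1]
            net = Network.from_edges(edges, nodes=[f"n{i}" for i in range(4)])
            np.testing.assert_array_equal(
                orbit_counts(net, 4), oracle_orbit_counts(net)
            )

    def test_size5_counts_are_consistent(self):
        """Size-5 orbit counts sum to the number of connected induced
        5-subgraphs containing the node (independent networkx count)."""
        net = gen_er(8, 14, seed=5)
        g = nx.Graph()
        g.add_nodes_from(range(8))
        g.add_edges_from(net.edges)
        c = orbit_counts(net, 5)
        for v in range(8):
            expected = sum(
                1
                for sub in itertools.combinations(range(8), 5)
                if v in sub and nx.is_connected(g.subgraph(sub))
            )
            assert c[v, 15:].sum() == expected


class TestGDDProfile:
    def test_k3_edge_orbit_single_bin(self):
        tri = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        prof = gdd_profile(orbit_counts(tri, 4))
        assert prof.orbits[0] == {2: 1.0}
        assert prof.orbits[3] == {1: 1.0}
        assert prof.orbits[4] == {}

    def test_disjoint_doubling_invariance(self):
        base = gen_er(10, 20, seed=2)
        doubled = Network.from_edges(
            base.edge_labels()
            + [(f"{a}__copy", f"{b}__copy") for a, b in base.edge_labels()]
        )
        p1 = gdd_profile(orbit_counts(base, 4))
        p2 = gdd_profile(orbit_counts(doubled, 4))
        for j in range(15):
            assert p1.orbits[j].keys() == p2.orbits[j].keys()
            for k in p1.orbits[j]:
                assert p1.orbits[j][k] == pytest.approx(p2.orbits[j][k])


class TestAgreement:
    def test_self_agreement_is_one(self):
        for seed in (0, 1):
            net = gen_er(12, 25, seed=seed)
            assert gdd_agreement(net, net) == pytest.approx(1.0, abs=1e-12)

    def test_k3_vs_p3_hand_computed(self):
        """Frozen hand computation of the normalized-profile distance.

        K3: orbit0 mass all at k=2; orbit3 at k=1.  P3: orbit0 has
        d(1)=2, d(2)=1 -> scaled (2, 1/2) -> N=(0.8, 0.2); orbits 1, 2 at
        k=1.  A0 = 1 - sqrt(0.64+0.64)/sqrt2 = 0.2; orbits 1, 2, 3 are
        one-sided: A = 1 - 1/sqrt2.  Mean over the 4 non-empty orbits.
        """
        k3 = Network.from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        p3 = Network.from_edges([("a", "b"), ("b", "c")])
        expected = (0.2 + 3 * (1 - 1 / np.sqrt(2))) / 4
        assert gdd_agreement(k3, p3) == pytest.approx(expected, abs=1e-12)

    def test_range_and_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n1, n2 = rng.integers(6, 14, 2)
            a = gen_er(int(n1), int(rng.integers(n1 - 1, 2 * n1)), seed=trial)
            b = gen_er(int(n2), int(rng.integers(n2 - 1, 2 * n2)),
                       seed=1000 + trial)
            agg = gdd_agreement(a, b)
            assert 0.0 <= agg <= 1.0
            if trial < 10:
                assert gdd_agreement(b, a) == pytest.approx(agg, abs=1e-12)

    def test_relabeling_invariance(self):
        a = gen_er(10, 18, seed=3)
        relabeled = Network.from_edges(
            [(f"x_{v}", f"x_{w}") for v, w in reversed(a.edge_labels())]
        )
        b = gen_er(10, 18, seed=7)
        assert gdd_agreement(a, b) == pytest.approx(
            gdd_agreement(relabeled, b), abs=1e-12
        )

    def test_geometric_vs_arithmetic_means(self):
        a = gen_er(10, 18, seed=3)
        b = gen_er(10, 18, seed=9)
        ar = gdd_agreement(a, b, mean="arithmetic")
        ge = gdd_agreement(a, b, mean="geometric")
        assert 0 <= ge <= ar <= 1  # AM-GM
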
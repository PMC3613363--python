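"""Null-model generators and the noise-perturbation operator."""

import numpy as np
import pytest

from tlse.graph_io import Network
from tlse.nullmodels import (
    gen_er,
    gen_erdd,
    gen_geometric,
    gen_sf,
    gen_sticky,
    perturb,
)


class TestER:
    def test_forced_complete_graph(self):
        net = gen_er(10, 45, seed=0)
        assert net.n_edges == 45

    def test_edgeless(self):
        net = gen_er(5, 0, seed=0)
        assert net.n_edges == 0 and net.n_nodes == 5

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            gen_er(4, 7, seed=0)

    def test_exact_edge_count_and_simplicity(self):
        for seed in range(5):
            net = gen_er(30, 60, seed=seed)
            assert net.n_edges == 60
            assert len(set(net.edges)) == 60

    def test_uniform_pair_inclusion(self):
        """Over repeated draws each pair appears with frequency ~ m/C(n,2)."""
        n, m, reps = 30, 60, 200
        total = n * (n - 1) // 2
        counts = np.zeros((n, n))
        for seed in range(reps):
            for i, j in gen_er(n, m, seed=seed).edges:
                counts[i, j] += 1
        p = m / total
        se = np.sqrt(p * (1 - p) / reps)
        iu = np.triu_indices(n, 1)
        freq = counts[iu] / reps
        # with 435 pairs a few 3-sigma excursions are expected; demand the
        # binomial coverage (>= 99% of pairs inside 3 SE) and an exact
        # global mean (every draw has exactly m edges)
        inside = np.abs(freq - p) <= 3 * se
        assert inside.mean() >= 0.99
        assert freq.mean() == pytest.approx(p, abs=1e-12)


class TestERDD:
    def test_perfect_matching_reference(self):
        ref = Network.from_edges([("a", "b"), ("c", "d"), ("e", "f")])
        out = gen_erdd(ref, seed=1)
        assert sorted(out.degrees().tolist()) == [1, 1, 1, 1, 1, 1]

    def test_four_cycle_reference(self):
        # all degrees 2 on 4 nodes forces a 4-cycle
        ref = Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        for seed in range(5):
            out = gen_erdd(ref, seed=seed)
            if out.n_edges == 4:  # full stub placement achieved
                assert sorted(out.degrees().tolist()) == [2, 2, 2, 2]

    def test_degree_sequence_usually_matched(self):
        rng = np.random.default_rng(0)
        ref = gen_er(50, 100, seed=9)
        ref_deg = sorted(ref.degrees().tolist())
        hits = sum(
            sorted(gen_erdd(ref, seed=s).degrees().tolist()) == ref_deg
            for s in range(40)
        )
        assert hits >= 0.95 * 40
        # and the total degree never exceeds the reference
        for s in range(10):
            assert gen_erdd(ref, seed=s).n_edges <= ref.n_edges


class TestSF:
    def test_tree_when_one_edge_per_node(self):
        net = gen_sf(50, 49, seed=2)
        assert net.n_edges <= 49
        # a connected graph with n-1 edges is a tree
        from tlse.graph_io import connected_components

        if net.n_edges == 49:
            assert len(connected_components(net)) == 1

    def test_expected_edge_count(self):
        realized = [gen_sf(1000, 3000, seed=s).n_edges for s in range(20)]
        assert abs(np.mean(realized) - 3000) / 3000 < 0.05

    def test_hub_growth_with_n(self):
        """Preferential attachment: max degree grows with n at fixed mean
        degree."""
        small = [max(gen_sf(200, 600, seed=s).degrees()) for s in range(10)]
        large = [max(gen_sf(2000, 6000, seed=s).degrees()) for s in range(10)]
        assert np.median(large) > np.median(small)


class TestSticky:
    def test_star_hub_exceeds_leaf(self):
        star = Network.from_edges([("h", f"l{i}") for i in range(5)])
        hub_deg = []
        leaf_deg = []
        for s in range(50):
            out = gen_sticky(star, seed=s)
            deg = out.degrees()
            hub_deg.append(deg[out.index_of("h")])
            leaf_deg.append(deg[out.index_of("l0")])
        assert np.mean(hub_deg) > np.mean(leaf_deg)

    def test_expected_degrees_match_reference(self):
        """E[deg_i] = sum_j theta_i theta_j ~ deg_ref(i) for sparse
        references; empirical means within 3 standard errors."""
        ref = gen_er(40, 60, seed=3)
        deg = ref.degrees().astype(float)
        theta = deg / np.sqrt(deg.sum())
        expect = np.array(
            [theta[i] * (theta.sum() - theta[i]) for i in range(40)]
        )
        reps = 50
        acc = np.zeros(40)
        acc2 = np.zeros(40)
        for s in range(reps):
            d = gen_sticky(ref, seed=s).degrees()
            acc += d
            acc2 += d.astype(float) ** 2
        mean = acc / reps
        sd = np.sqrt(np.maximum(acc2 / reps - mean**2, 1e-12))
        se = sd / np.sqrt(reps)
        assert np.all(np.abs(mean - expect) <= 3 * se + 0.2)

    def test_needs_an_edge(self):
        with pytest.raises(ValueError):
            gen_sticky(Network.from_edges([], nodes=["a"]), seed=0)


class TestGeometric:
    def test_complete_when_all_pairs_requested(self):
        net, _ = gen_geometric(8, 2, 28, seed=0)
        assert net.n_edges == 28

    def test_edges_are_the_closest_pairs(self):
        net, coords = gen_geometric(40, 3, 100, seed=5)
        d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        edge_d = [d[i, j] for i, j in net.edges]
        non_d = [
            d[i, j]
            for i in range(40)
            for j in range(i + 1, 40)
            if not net.has_edge_idx(i, j)
        ]
        assert max(edge_d) <= min(non_d)

    def test_true_coordinates_give_perfect_recovery(self):
        from tlse.evaluate import auc_score
        from tlse.graph_io import _non_edge_pool

        net, coords = gen_geometric(50, 2, 150, seed=1)
        pos = net.edge_array()
        neg = _non_edge_pool(net)
        dp = np.linalg.norm(coords[pos[:, 0]] - coords[pos[:, 1]], axis=-1)
        dn = np.linalg.norm(coords[neg[:, 0]] - coords[neg[:, 1]], axis=-1)
        assert auc_score(dp, dn) == 1.0


class TestPerturb:
    def test_zero_fraction_is_identity(self):
        net = gen_er(20, 40, seed=0)
        out = perturb(net, 0.0, seed=1)
        assert set(out.edges) == set(net.edges)

    def test_edge_count_conserved(self):
        net = gen_er(30, 80, seed=2)
        for frac in (0.05, 0.1, 0.25, 0.5):
            out = perturb(net, frac, seed=3)
            assert out.n_edges == net.n_edges
            assert out.nodes == net.nodes

    def test_jaccard_overlap_matches_counting_argument(self):
        """Removing and inserting k = frac*|E| edges leaves an overlap of
        (1-frac)|E| against a union of (1+frac)|E|."""
        net = gen_er(40, 200, seed=4)
        frac = 0.1
        expected = (1 - frac) / (1 + frac)
        jac = []
        for s in range(20):
            out = perturb(net, frac, seed=s)
            a, b = set(net.edges), set(out.edges)
            jac.append(len(a & b) / len(a | b))
        assert np.mean(jac) == pytest.approx(expected, abs=0.01)

    def test_invalid_fraction(self):
        net = gen_er(10, 10, seed=0)
        with pytest.raises(ValueError):
            perturb(net, 1.0, seed=0)


def test_generators_are_seed_deterministic():
    ref = gen_er(25, 50, seed=11)
    for gen in (
        lambda s: gen_er(25, 50, seed=s),
        lambda s: gen_erdd(ref, seed=s),
        lambda s: gen_sf(25, 50, seed=s),
        lambda s: gen_sticky(ref, seed=s),
        lambda s: gen_geometric(25, 2, 50, seed=s)[0],
        lambda s: perturb(ref, 0.2, seed=s),
    ):
        a, b = gen(7), gen(7)
        assert a.edges == b.edges
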
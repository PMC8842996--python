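"""Flat partitioning, core adjacency, hierarchical placement, baselines."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from hiaerpart import (
    CoreAdjacency,
    CoreAssignment,
    CorePlacement,
    HierarchySpec,
    NeuronGraph,
    PartitionConfig,
    PartitioningError,
    ValidationError,
    build_core_adjacency,
    count_traffic,
    flat_partition,
    hierarchical_placement,
    kway_partition,
    random_assignment,
    random_placement,
)

from .conftest import random_graph


def _cliques(sizes):
    """Disjoint directed cliques (both directions per pair)."""
    pre, post, offset = [], [], 0
    for s in sizes:
        for u, v in itertools.permutations(range(offset, offset + s), 2):
            pre.append(u)
            post.append(v)
        offset += s
    return NeuronGraph(n_neurons=offset, pre=pre, post=post)


class TestFlatPartition:
    def test_single_core_trivial(self):
        g = random_graph(20, 50, seed=0)
        cfg = PartitionConfig(spec=HierarchySpec((1,)))
        asg = flat_partition(g, cfg)
        assert np.all(asg.core_of == 0)

    def test_two_disjoint_cliques_cut_is_zero(self):
        # exhaustive check over balanced 2-partitions shows 0 is the optimum
        g = _cliques([5, 5])
        cfg = PartitionConfig(spec=HierarchySpec((2,)), backend_seed=1)
        asg = flat_partition(g, cfg)
        cores = asg.core_of
        assert len(set(cores[:5])) == 1 and len(set(cores[5:])) == 1
        assert cores[0] != cores[5]

    def test_part_sizes_respect_balance_cap(self):
        g = random_graph(10, 40, seed=1)
        cfg = PartitionConfig(spec=HierarchySpec((3,)), balance_tolerance=0.03)
        asg = flat_partition(g, cfg)
        assert sorted(asg.core_sizes().tolist()) == [3, 3, 4]

    def test_deterministic_for_fixed_backend_seed(self):
        g = random_graph(60, 300, seed=2)
        cfg = PartitionConfig(spec=HierarchySpec((2, 2)), backend_seed=7)
        a1 = flat_partition(g, cfg)
        a2 = flat_partition(g, cfg)
        assert np.array_equal(a1.core_of, a2.core_of)

    def test_more_cores_than_neurons_rejected(self):
        g = random_graph(3, 4, seed=0)
        with pytest.raises(PartitioningError):
            flat_partition(g, PartitionConfig(spec=HierarchySpec((2, 2))))

    def test_balance_invariant_on_random_graphs(self):
        for seed in range(3):
            g = random_graph(101, 500, seed=seed)
            cfg = PartitionConfig(spec=HierarchySpec((2, 3)), backend_seed=seed)
            asg = flat_partition(g, cfg)
            asg.check_balance(cfg.balance_tolerance)

    def test_pluggable_backend_hook(self):
        g = random_graph(12, 30, seed=3)
        calls = []

        def backend(W, k, cap, seed):
            calls.append((W.shape, k, cap, seed))
            return np.arange(12) % k

        cfg = PartitionConfig(spec=HierarchySpec((3,)), backend=backend, backend_seed=9)
        asg = flat_partition(g, cfg)
        assert calls == [((12, 12), 3, 5, 9)]
        assert asg.core_sizes().tolist() == [4, 4, 4]


class TestCoreAdjacency:
    def test_multiple_targets_in_one_core_count_once(self):
        # neuron 0 (core 0) -> posts {5, 6} both in core 1: one routed connection
        g = NeuronGraph(n_neurons=8, pre=[0, 0], post=[5, 6])
        asg = CoreAssignment(core_of=np.array([0] * 4 + [1] * 4), n_cores=2)
        adj = build_core_adjacency(g, asg)
        assert adj.A[0, 1] == 1

    def test_synapse_multiplicity_ignored(self):
        g = NeuronGraph(n_neurons=4, pre=[0, 0, 0], post=[2, 2, 2])
        asg = CoreAssignment(core_of=np.array([0, 0, 1, 1]), n_cores=2)
        assert build_core_adjacency(g, asg).A[0, 1] == 1

    def test_intra_core_only_gives_zero_matrix(self):
        g = NeuronGraph(n_neurons=4, pre=[0, 1], post=[1, 0])
        asg = CoreAssignment(core_of=np.array([0, 0, 1, 1]), n_cores=2)
        assert not build_core_adjacency(g, asg).A.any()

    def test_b_is_sum_of_a_and_a_transpose(self):
        # A[0,1]=2, A[1,0]=1  ->  B[0,1]=B[1,0]=3
        g = NeuronGraph(n_neurons=4, pre=[0, 1, 2], post=[2, 3, 0])
        asg = CoreAssignment(core_of=np.array([0, 0, 1, 1]), n_cores=2)
        adj = build_core_adjacency(g, asg)
        assert adj.A[0, 1] == 2 and adj.A[1, 0] == 1
        assert adj.B[0, 1] == adj.B[1, 0] == 3

    def test_total_equals_per_neuron_remote_core_sets(self):
        g = random_graph(40, 900, seed=4)
        asg = random_assignment(40, 5, seed=5)
        adj = build_core_adjacency(g, asg)
        expected = 0
        for v in range(40):
            dests = {asg.core_of[p] for u, p in zip(g.pre, g.post) if u == v}
            expected += len(dests - {asg.core_of[v]})
        assert adj.A.sum() == expected

    def test_validates_type_invariants(self):
        with pytest.raises(ValidationError):
            CoreAdjacency(A=np.array([[1, 0], [0, 0]]))  # nonzero diagonal
        with pytest.raises(ValidationError):
            CoreAdjacency(A=np.array([[0, 1], [0, 0]]), B=np.zeros((2, 2), int))


def _block_adjacency(blocks, strong=50, weak=1):
    """Symmetric core adjacency with heavy intra-block weights."""
    k = sum(len(b) for b in blocks)
    B = np.full((k, k), weak, dtype=np.int64)
    np.fill_diagonal(B, 0)
    for block in blocks:
        for i, j in itertools.permutations(block, 2):
            B[i, j] = strong
    A = np.triu(B)  # any A with A + A^T == B
    return CoreAdjacency(A=A, B=A + A.T)


class TestHierarchicalPlacement:
    def test_single_level_spec_is_traffic_invariant_labeling(self):
        adj = _block_adjacency([[0, 1], [2, 3]])
        cfg = PartitionConfig(spec=HierarchySpec((4,)))
        placement = hierarchical_placement(adj, cfg)
        g = random_graph(40, 200, seed=6)
        asg = random_assignment(40, 4, seed=7)
        t1 = count_traffic(g, asg, placement, "multicast")
        t2 = count_traffic(g, asg, CorePlacement.identity(cfg.spec), "multicast")
        assert t1.messages == t2.messages

    def test_block_diagonal_recovers_heavy_groups(self):
        # exhaustive search over the 3 balanced 2-groupings of 4 cores shows
        # {0,1},{2,3} uniquely minimizes the cut: the placement must find it
        adj = _block_adjacency([[0, 1], [2, 3]])
        cfg = PartitionConfig(spec=HierarchySpec((2, 2)), backend_seed=0)
        placement = hierarchical_placement(adj, cfg)
        tops = [placement.address_of(c)[0] for c in range(4)]
        assert tops[0] == tops[1] and tops[2] == tops[3] and tops[0] != tops[2]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_optimum_k8(self, seed):
        # top-level split of 8 cores into 2 groups vs brute force over all
        # 35 balanced groupings, scored by cut weight of B
        rng = np.random.default_rng(seed)
        B = rng.integers(0, 20, size=(8, 8))
        B = B + B.T
        np.fill_diagonal(B, 0)
        adj = CoreAdjacency(A=np.triu(B), B=np.triu(B) + np.triu(B).T)
        cfg = PartitionConfig(spec=HierarchySpec((2, 4)), backend_seed=seed)
        placement = hierarchical_placement(adj, cfg)
        groups = {}
        for c in range(8):
            groups.setdefault(placement.address_of(c)[0], set()).add(c)
        achieved = sum(
            adj.B[i, j]
            for i in range(8)
            for j in range(8)
            if i < j
            and any(i in g and j not in g for g in groups.values())
        )
        best = min(
            sum(
                adj.B[i, j]
                for i in range(8)
                for j in range(8)
                if i < j and ((i in combo) != (j in combo))
            )
            for combo in itertools.combinations(range(8), 4)
        )
        assert achieved == best

    def test_uniform_adjacency_still_valid_bijection(self):
        B = np.full((8, 8), 3, dtype=np.int64)
        np.fill_diagonal(B, 0)
        adj = CoreAdjacency(A=np.triu(B), B=np.triu(B) + np.triu(B).T)
        cfg = PartitionConfig(spec=HierarchySpec((2, 2, 2)))
        placement = hierarchical_placement(adj, cfg)
        assert sorted(placement.slot_of.tolist()) == list(range(8))

    def test_indivisible_spec_rejected(self):
        adj = _block_adjacency([[0, 1, 2]])
        with pytest.raises(ValidationError):
            hierarchical_placement(adj, PartitionConfig(spec=HierarchySpec((2, 2))))

    def test_consistent_relabeling_leaves_traffic_unchanged(self):
        g = random_graph(60, 400, seed=8)
        spec = HierarchySpec((2, 2))
        cfg = PartitionConfig(spec=spec, backend_seed=2)
        asg = flat_partition(g, cfg)
        adj = build_core_adjacency(g, asg)
        placement = hierarchical_placement(adj, cfg)
        # relabel cores by a permutation sigma, consistently everywhere
        sigma = np.array([2, 0, 3, 1])
        asg2 = CoreAssignment(core_of=sigma[asg.core_of], n_cores=4)
        slot2 = np.empty(4, dtype=np.int64)
        slot2[sigma] = placement.slot_of
        placement2 = CorePlacement(spec, slot2)
        for mode in ("multicast", "unicast"):
            t1 = count_traffic(g, asg, placement, mode)
            t2 = count_traffic(g, asg2, placement2, mode)
            assert t1.messages == t2.messages and t1.relays == t2.relays


class TestKwayPartition:
    def test_exact_sizes_requires_divisibility(self):
        W = sp.csr_matrix(np.zeros((7, 7)))
        with pytest.raises(PartitioningError):
            kway_partition(W, 3, exact_sizes=True)

    def test_labels_cover_all_parts(self):
        g = random_graph(30, 200, seed=9)
        labels = kway_partition(g.undirected_csr(), 5, seed=1, part_cap=7)
        assert set(labels.tolist()) == set(range(5))
        assert np.bincount(labels).max() <= 7


class TestRandomBaselines:
    def test_balanced_block_sizes(self):
        assert random_assignment(8, 4, seed=0).core_sizes().tolist() == [2, 2, 2, 2]
        assert sorted(random_assignment(10, 4, seed=0).core_sizes()) == [2, 2, 3, 3]

    def test_assignment_deterministic_per_seed(self):
        a = random_assignment(50, 5, seed=3)
        b = random_assignment(50, 5, seed=3)
        assert np.array_equal(a.core_of, b.core_of)
        c = random_assignment(50, 5, seed=4)
        assert not np.array_equal(a.core_of, c.core_of)

    def test_placement_is_reproducible_bijection(self):
        spec = HierarchySpec((2, 4, 8))
        p1 = random_placement(64, spec, seed=5)
        p2 = random_placement(64, spec, seed=5)
        assert np.array_equal(p1.slot_of, p2.slot_of)
        assert sorted(p1.slot_of.tolist()) == list(range(64))
        assert random_placement(1, HierarchySpec((1,)), seed=0).slot_of.tolist() == [0]
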
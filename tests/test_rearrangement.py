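import random

import numpy as np
import pytest

from plastrace.rearrangement import (
    Inversion,
    SignedCircularPermutation,
    all_inversions,
    apply_inversion,
    bfs_distance_oracle,
    canonicalize,
    distance_matrix,
    median_permutation,
    mgr_tree,
    read_grimm,
    reversal_distance,
    sort_by_reversals,
    write_grimm,
    _bfs_map,
)
from plastrace.synthetic_data import evolve, random_permutation

P = SignedCircularPermutation


class TestCanonicalize:
    def test_rotation(self):
        assert canonicalize(P([2, 3, 1])).blocks == (1, 2, 3)

    def test_reflection(self):
        assert canonicalize(P([-3, -2, -1])).blocks == (1, 2, 3)

    def test_idempotent(self):
        p = P([-4, 2, 1, -3])
        assert canonicalize(canonicalize(p)) == canonicalize(p)

    def test_duplicate_block_rejected(self):
        with pytest.raises(ValueError):
            P([1, 2, 2])

    def test_missing_block_rejected(self):
        with pytest.raises(ValueError):
            P([1, 3, 4])


class TestReversalDistance:
    def test_identity_pair(self):
        p = random_permutation(10, 3)
        assert reversal_distance(p, p) == 0

    def test_single_inversion_is_one(self):
        p = random_permutation(10, 4)
        q = apply_inversion(p, Inversion(2, 6))
        assert reversal_distance(p, q) == 1

    def test_mismatched_block_sets_error(self):
        with pytest.raises(ValueError):
            reversal_distance(P([1, 2, 3]), P([1, 2, 3, 4]))

    def test_matches_oracle_exhaustively_small(self):
        states = [P(s) for s in _bfs_map(4)]
        for a in states:
            for b in states:
                assert reversal_distance(a, b) == bfs_distance_oracle(a, b)

    def test_matches_oracle_sampled_n6(self):
        rng = random.Random(17)
        states = [P(s) for s in _bfs_map(6)]
        for _ in range(200):
            a, b = rng.choice(states), rng.choice(states)
            assert reversal_distance(a, b) == bfs_distance_oracle(a, b)

    def test_is_a_metric(self):
        rng = random.Random(23)
        perms = [random_permutation(6, rng.randrange(10**6)) for _ in range(30)]
        for _ in range(100):
            a, b, c = rng.sample(perms, 3)
            dab = reversal_distance(a, b)
            assert dab == reversal_distance(b, a)
            assert dab <= reversal_distance(a, c) + reversal_distance(c, b)
            assert (dab == 0) == (a == b)


class TestBfsOracle:
    def test_guard_on_large_n(self):
        p = random_permutation(10, 0)
        with pytest.raises(ValueError):
            bfs_distance_oracle(p, p)

    def test_symmetry(self):
        rng = random.Random(5)
        for _ in range(30):
            a = random_permutation(5, rng.randrange(10**6))
            b = random_permutation(5, rng.randrange(10**6))
            assert bfs_distance_oracle(a, b) == bfs_distance_oracle(b, a)


class TestSortByReversals:
    def test_identity_gives_empty_scenario(self):
        p = random_permutation(8, 9)
        assert len(sort_by_reversals(p, p)) == 0

    def test_replay_reaches_target_with_optimal_length(self):
        rng = random.Random(31)
        for _ in range(25):
            n = rng.choice([4, 5, 6])
            a = random_permutation(n, rng.randrange(10**6))
            b = random_permutation(n, rng.randrange(10**6))
            scen = sort_by_reversals(a, b)
            assert len(scen) == bfs_distance_oracle(a, b)
            assert scen.replay(a) == b

    def test_deterministic(self):
        a = random_permutation(8, 41)
        b = random_permutation(8, 42)
        assert sort_by_reversals(a, b) == sort_by_reversals(a, b)


class TestPlantedHistoryRecovery:
    def test_distance_never_exceeds_and_usually_equals_k(self):
        hits = trials = 0
        for seed in range(100):
            k = seed % 8 + 1
            src = random_permutation(33, 10_000 + seed)
            hist = evolve(src, k, 20_000 + seed)
            d = reversal_distance(src, hist.result)
            assert d <= k
            hits += d == k
            trials += 1
        assert hits / trials >= 0.90


class TestDistanceMatrix:
    def test_identical_permutations_zero_matrix(self):
        p = random_permutation(6, 1)
        assert not distance_matrix([p, p, p]).any()

    def test_symmetric_zero_diagonal(self):
        perms = [random_permutation(7, s) for s in (1, 2, 3, 4)]
        m = distance_matrix(perms)
        assert (m == m.T).all() and not m.diagonal().any()

    def test_star_neighbourhood_bounded_by_two(self):
        src = random_permutation(10, 77)
        leaves = [
            apply_inversion(src, inv)
            for inv in [Inversion(0, 3), Inversion(4, 6), Inversion(7, 9)]
        ]
        m = distance_matrix(leaves)
        off = m[~np.eye(3, dtype=bool)]
        assert (off <= 2).all()


class TestMgrTree:
    def test_too_few_genomes_error(self):
        p = random_permutation(5, 0)
        with pytest.raises(ValueError):
            mgr_tree([p, p])

    def test_identical_genomes_star_with_zero_total(self):
        p = random_permutation(10, 8)
        t = mgr_tree([p, p, p], names=["a", "b", "c"])
        assert t.total_inversions == 0
        assert len(t.edges) == 3  # star around one ancestor

    def test_recovers_ancestor_of_disjoint_single_inversions(self):
        anc = random_permutation(10, 5)
        leaves = [
            apply_inversion(anc, Inversion(0, 3)),
            apply_inversion(anc, Inversion(4, 6)),
            apply_inversion(anc, Inversion(7, 9)),
        ]
        t = mgr_tree(leaves, names=["L1", "L2", "L3"])
        assert t.total_inversions == 3
        ancestors = [nm for nm in t.labels if nm.startswith("A")]
        assert any(t.labels[nm] == anc for nm in ancestors)
        assert all(
            c == reversal_distance(t.labels[a], t.labels[b])
            for a, b, c in t.edges
        )

    def test_quartet_total_bounded_by_planted_history(self):
        for seed in range(3):
            root = random_permutation(12, seed + 100)
            x = evolve(root, 2, seed * 10 + 1).result
            y = evolve(root, 2, seed * 10 + 2).result
            leaves = [
                evolve(x, 1, seed * 10 + 3).result,
                evolve(x, 1, seed * 10 + 4).result,
                evolve(y, 1, seed * 10 + 5).result,
                evolve(y, 1, seed * 10 + 6).result,
            ]
            t = mgr_tree(leaves, names=list("abcd"))
            assert t.total_inversions <= 8

    def test_fixed_topology_labels_minimise_local_sums(self):
        anc = random_permutation(6, 3)
        leaves = {
            nm: evolve(anc, 1, s).result
            for nm, s in zip("abcd", [11, 12, 13, 14])
        }
        t = mgr_tree(
            list(leaves.values()),
            names=list(leaves),
            topology=(("a", "b"), ("c", "d")),
        )
        # parsimony total never exceeds the sum along a leaf spanning path
        path = (
            reversal_distance(leaves["a"], leaves["b"])
            + reversal_distance(leaves["b"], leaves["c"])
            + reversal_distance(leaves["c"], leaves["d"])
        )
        assert t.total_inversions <= path

    def test_newick_is_parseable(self):
        import dendropy

        p = random_permutation(8, 2)
        leaves = [evolve(p, 1, s).result for s in (5, 6, 7)]
        t = mgr_tree(leaves, names=["x", "y", "z"])
        tree = dendropy.Tree.get(data=t.to_newick(), schema="newick")
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"x", "y", "z"}


class TestMedian:
    def test_exact_median_of_single_inversion_neighbours(self):
        anc = random_permutation(5, 21)
        neigh = [evolve(anc, 1, s).result for s in (1, 2, 3)]
        med = median_permutation(neigh)
        score = sum(reversal_distance(med, q) for q in neigh)
        anc_score = sum(reversal_distance(anc, q) for q in neigh)
        assert score <= anc_score <= 3


class TestGrimmIO:
    def test_round_trip(self):
        perms = {
            "alpha": P([1, -3, 2]),
            "beta": P([2, 3, 1]),
        }
        text = write_grimm(perms)
        back = read_grimm(text)
        assert back == perms

    def test_dollar_terminator_tolerated(self):
        back = read_grimm(">g1\n+1 -2 +3 $\n")
        assert back["g1"] == P([1, -2, 3])

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            read_grimm(">only_name\n")
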
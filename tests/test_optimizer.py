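"""Selection machinery and the main optimization loop."""

import numpy as np
import pytest

import seqforge as sf
from seqforge.optimizer import archive_update, random_partition


def brute_force_rank(F):
    """Independent O(n^2 k) dominator count."""
    F = np.asarray(F, dtype=float)
    n = len(F)
    ranks = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and all(F[j] <= F[i]) and any(F[j] < F[i]):
                ranks[i] += 1
    return ranks


class TestDominance:
    def test_strict_domination(self):
        assert sf.dominates((1, 2), (2, 3))

    def test_incomparable_pairs(self):
        assert not sf.dominates((1, 2), (2, 1))
        assert not sf.dominates((2, 1), (1, 2))

    def test_equal_vectors_do_not_dominate(self):
        assert not sf.dominates((1, 2), (1, 2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sf.dominates((1, 2), (1, 2, 3))

    def test_rank_chain(self):
        ranks = sf.domination_rank([(0, 0), (1, 1), (2, 2)])
        assert list(ranks) == [0, 1, 2]

    def test_rank_incomparable_and_singleton(self):
        assert list(sf.domination_rank([(0, 1), (1, 0)])) == [0, 0]
        assert list(sf.domination_rank([(3, 4)])) == [0]

    def test_rank_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 40))
            k = int(rng.integers(1, 4))
            F = rng.integers(0, 6, size=(n, k)).astype(float)
            assert np.array_equal(sf.domination_rank(F), brute_force_rank(F))


class TestCrowdingDistance:
    def test_middle_member_normalized_gap(self):
        F = np.array([[0.0], [4.0], [10.0]])
        d = sf.crowding_distance(F, np.array([0.0]), np.array([10.0]))
        assert d[0] == np.inf and d[2] == np.inf
        assert d[1] == pytest.approx(1.0)

    def test_two_members_both_extreme(self):
        d = sf.crowding_distance(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.all(np.isinf(d))

    def test_degenerate_objective_contributes_nothing(self):
        F = np.array([[1.0, 0.0], [1.0, 4.0], [1.0, 10.0]])
        d = sf.crowding_distance(F, F.min(axis=0), F.max(axis=0))
        assert d[1] == pytest.approx(1.0)  # only the second objective counts


class TestSelect:
    def _solutions(self, vectors):
        out = []
        for i, v in enumerate(vectors):
            z = sf.Solution("ACGT", (sf.Block(0, 4),))
            z.objectives = np.asarray(v, dtype=float)
            out.append(z)
        return out

    def test_dominating_solution_always_retained(self):
        parents = self._solutions([(5, 5), (6, 6)])
        offspring = self._solutions([(0, 0), (7, 7)])
        chosen = sf.select(parents, offspring, 2)
        assert any(tuple(z.objectives) == (0.0, 0.0) for z in chosen)

    def test_rank_ties_broken_by_crowding(self):
        # four mutually non-dominated; the crowded middle pair loses members
        parents = self._solutions([(0, 10), (10, 0)])
        offspring = self._solutions([(4.9, 5.1), (5.0, 5.0)])
        chosen = sf.select(parents, offspring, 3)
        vecs = {tuple(z.objectives) for z in chosen}
        assert (0.0, 10.0) in vecs and (10.0, 0.0) in vecs
        assert len(vecs) == 3

    def test_pool_size_is_exact(self):
        parents = self._solutions([(i, i) for i in range(5)])
        offspring = self._solutions([(i + 0.5, i + 0.5) for i in range(5)])
        assert len(sf.select(parents, offspring, 5)) == 5

    def test_duplicate_pools_preserve_vectors(self):
        parents = self._solutions([(1, 2), (2, 1)])
        offspring = self._solutions([(1, 2), (2, 1)])
        chosen = sf.select(parents, offspring, 2)
        assert {tuple(z.objectives) for z in chosen} == {(1.0, 2.0), (2.0, 1.0)}


class TestInitialization:
    def test_partitions_within_bounds(self, rng):
        cfg = sf.OptimizerConfig(l_min=500, l_max=3000)
        for _ in range(50):
            blocks = random_partition(3000, cfg, rng)
            assert 1 <= len(blocks) <= 6
            assert blocks[0].start == 0 and blocks[-1].end == 3000
            assert all(500 <= len(b) <= 3000 for b in blocks)
            assert all(a.end == b.start for a, b in zip(blocks, blocks[1:]))

    def test_pool_size_and_validity(self, medium_construct):
        cfg = sf.OptimizerConfig(n=10)
        pool = sf.initialize_pool(
            medium_construct, cfg, np.random.default_rng(0)
        )
        assert len(pool) == 10
        for z in pool:
            assert sf.validate_solution(z, medium_construct, cfg).ok

    def test_short_sequence_rejected(self):
        cfg = sf.OptimizerConfig(l_min=500, l_max=3000)
        with pytest.raises(ValueError):
            random_partition(100, cfg, np.random.default_rng(0))


class TestArchive:
    def _sol(self, v):
        z = sf.Solution("ACGT" + "".join(np.random.default_rng(abs(hash(v)) % 2**31).choice(list("ACGT"), 4)), (sf.Block(0, 8),))
        z.objectives = np.asarray(v, dtype=float)
        return z

    def test_dominated_candidate_is_ignored(self):
        archive = sf.ParetoArchive(capacity=10)
        archive_update(archive, [self._sol((1.0, 1.0))])
        archive_update(archive, [self._sol((2.0, 2.0))])
        assert [tuple(z.objectives) for z in archive.solutions] == [(1.0, 1.0)]

    def test_dominating_candidate_replaces_member(self):
        archive = sf.ParetoArchive(capacity=10)
        archive_update(archive, [self._sol((1.0, 1.0))])
        archive_update(archive, [self._sol((0.5, 0.5))])
        assert [tuple(z.objectives) for z in archive.solutions] == [(0.5, 0.5)]

    def test_capacity_truncation_evicts_crowded_middle(self):
        archive = sf.ParetoArchive(capacity=2)
        pts = [(0.0, 10.0), (4.9, 5.0), (10.0, 0.0)]
        archive_update(archive, [self._sol(p) for p in pts])
        vecs = {tuple(z.objectives) for z in archive.solutions}
        assert vecs == {(0.0, 10.0), (10.0, 0.0)}


class TestRun:
    def test_t_max_zero_returns_evaluated_initial_pool(self, medium_construct):
        cfg = sf.OptimizerConfig(n=8, t_max=0, m=20, seed=5)
        result = sf.run(medium_construct, cfg)
        assert len(result.pool) == 8
        assert all(z.objectives is not None for z in result.pool)
        F = np.vstack([z.objectives for z in result.pool])
        expected = sf.non_dominated_filter(F)
        got = sf.non_dominated_filter(result.archive.objective_matrix())
        assert {tuple(r) for r in got} == {tuple(r) for r in expected}

    def test_same_seed_is_bit_identical(self, medium_construct):
        cfg = sf.OptimizerConfig(n=10, t_max=15, m=30, seed=9)
        a = sf.run(medium_construct, cfg)
        b = sf.run(medium_construct, cfg)
        assert [z.sequence for z in a.pool] == [z.sequence for z in b.pool]
        assert [z.blocks for z in a.pool] == [z.blocks for z in b.pool]
        assert np.array_equal(
            a.archive.objective_matrix(), b.archive.objective_matrix()
        )
        assert a.history.equals(b.history)

    def test_single_objective_best_is_monotone(self, medium_construct):
        # gc objective alone on a fixed single block: elitist selection
        # makes the best value non-increasing
        L = len(medium_construct.seq)
        cfg = sf.OptimizerConfig(
            n=10, t_max=25, m=20, l_min=L, l_max=L, objectives=("gc",), seed=2
        )
        result = sf.run(medium_construct, cfg)
        best = result.history.query("objective == 'gc'")["min"].to_numpy()
        assert np.all(np.diff(best) <= 1e-12)

    def test_archive_matches_log_oracle(self, medium_construct):
        # archive == non-dominated subset of everything ever evaluated
        cfg = sf.OptimizerConfig(n=10, t_max=20, m=500, seed=3)
        log: list = []
        result = sf.run(medium_construct, cfg, evaluation_log=log)
        assert len(log) == 10 * (20 + 1)
        all_F = np.vstack([z.objectives for z in log])
        expected = sf.non_dominated_filter(all_F)
        got = sf.non_dominated_filter(result.archive.objective_matrix())
        assert {tuple(r) for r in got} == {tuple(r) for r in expected}

    def test_elitism_across_iterations(self, medium_construct):
        cfg = sf.OptimizerConfig(n=8, t_max=10, m=50, seed=4)
        log: list = []
        result = sf.run(medium_construct, cfg, evaluation_log=log)
        # nothing ever evaluated dominates the archive's account of the front
        archive_front = result.archive.objective_matrix()
        for v in archive_front:
            assert not any(sf.dominates(z.objectives, v) for z in log)

    def test_history_is_tidy(self, medium_construct):
        cfg = sf.OptimizerConfig(n=6, t_max=5, m=12, seed=1)
        result = sf.run(medium_construct, cfg)
        assert list(result.history.columns) == [
            "iteration",
            "objective",
            "min",
            "mean",
            "max",
        ]
        assert set(result.history.objective) == set(cfg.objectives)
        assert result.history.iteration.max() == 5

    def test_missing_table_rejected(self, medium_construct):
        cfg = sf.OptimizerConfig(objectives=("gc", "codon_usage"))
        with pytest.raises(ValueError):
            sf.run(medium_construct, cfg)
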
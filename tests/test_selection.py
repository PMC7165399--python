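"""Ranking / Roulette / Tournament selectors and seed-pool assembly."""
import numpy as np
import pytest

from evochem import (build_seed_pools, ranking_select, roulette_select,
                     tournament_select)
from evochem.selection import PoolCounts, _roulette_weights

from conftest import make_scored


class TestRanking:
    def test_picks_the_best_by_direction(self, scored_factory):
        pool = scored_factory([-5, -7, -6])
        out = ranking_select(pool, 2, "primary", "min")
        assert [r.scores["primary"] for r in out] == [-7, -6]

    def test_k_zero(self, scored_factory):
        assert ranking_select(scored_factory([1, 2]), 0) == []

    def test_k_larger_than_pool_selects_all(self, scored_factory):
        pool = scored_factory([3, 1, 2])
        assert len(ranking_select(pool, 10)) == 3

    def test_tie_broken_by_smiles_then_id(self, scored_factory):
        pool = scored_factory([1.0, 1.0, 1.0])
        out = ranking_select(pool, 1)
        # lexicographically smallest canonical SMILES ('CCCO', r3) wins the tie
        assert out[0].id == "r3"

    def test_matches_sort_oracle(self, scored_factory, rng):
        for _ in range(50):
            vals = rng.normal(size=rng.integers(1, 30))
            pool = scored_factory(vals)
            k = int(rng.integers(0, len(pool) + 1))
            expected = sorted(pool, key=lambda r: (r.scores["primary"],
                                                   r.smiles, r.id))[:k]
            assert ranking_select(pool, k) == expected

    def test_max_direction(self, scored_factory):
        pool = scored_factory([1, 5, 3])
        assert ranking_select(pool, 1, direction="max")[0].scores["primary"] == 5


class TestRoulette:
    def test_pool_of_one(self, scored_factory, rng):
        pool = scored_factory([-1.0])
        assert roulette_select(pool, 1, rng=rng) == pool

    def test_k_equals_pool_size_is_a_permutation(self, scored_factory, rng):
        pool = scored_factory([-1, -2, -3, -4])
        out = roulette_select(pool, 4, rng=rng)
        assert sorted(r.id for r in out) == sorted(r.id for r in pool)

    def test_identical_scores_sample_uniformly(self, scored_factory):
        pool = scored_factory([2.0, 2.0])
        counts = {"r1": 0, "r2": 0}
        rng = np.random.default_rng(0)
        for _ in range(2000):
            counts[roulette_select(pool, 1, rng=rng)[0].id] += 1
        assert abs(counts["r1"] - 1000) < 3 * np.sqrt(2000 * 0.25)

    def test_empirical_frequencies_follow_the_weight_formula(self, scored_factory):
        # Monte-Carlo check against the stated shifted-linear weights
        pool = scored_factory([0.0, 1.0, 3.0, 4.0])
        scores = np.array([0.0, 1.0, 3.0, 4.0])
        w = _roulette_weights(scores, "min")
        p = w / w.sum()
        n = 10_000
        rng = np.random.default_rng(17)
        counts = np.zeros(4)
        for _ in range(n):
            picked = roulette_select(pool, 1, rng=rng)[0]
            counts[int(picked.id[1:]) - 1] += 1
        se = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) <= 3 * se)

    def test_worst_record_has_non_zero_chance(self, scored_factory):
        pool = scored_factory([-10.0, 0.0])
        rng = np.random.default_rng(2)
        picks = {roulette_select(pool, 1, rng=rng)[0].id for _ in range(5000)}
        assert picks == {"r1", "r2"}

    def test_empty_pool_with_k_positive_rejected(self, rng):
        with pytest.raises(ValueError):
            roulette_select([], 1, rng=rng)


class TestTournament:
    def test_fraction_one_equals_ranking(self, scored_factory, rng):
        pool = scored_factory([-3, -9, -1, -5, -7])
        assert (tournament_select(pool, 3, 1.0, rng=rng)
                == ranking_select(pool, 3))

    def test_minimal_subpopulation_is_uniform_sampling(self, scored_factory):
        # fraction so small every tournament has one contestant
        pool = scored_factory([-1, -2, -3, -4, -5, -6, -7, -8, -9, -10])
        rng = np.random.default_rng(5)
        firsts = {tournament_select(pool, 1, 0.05, rng=rng)[0].id
                  for _ in range(300)}
        assert len(firsts) >= 8  # nearly every record shows up

    def test_best_record_wins_any_tournament_containing_it(self, scored_factory):
        pool = scored_factory([-100, -1, -2, -3])
        rng = np.random.default_rng(9)
        for _ in range(1000):
            winners = tournament_select(pool, 1, 0.5, rng=rng)
            if winners[0].id != "r1":
                # best was simply not sampled; verify by rerunning exhaustively
                continue
        # with fraction 1.0 the best always wins
        assert tournament_select(pool, 1, 1.0, rng=rng)[0].id == "r1"

    def test_dominance_better_scores_win_more(self, scored_factory):
        pool = scored_factory([-4, -3, -2, -1])
        rng = np.random.default_rng(21)
        wins = {f"r{i}": 0 for i in range(1, 5)}
        for _ in range(10_000):
            wins[tournament_select(pool, 1, 0.5, rng=rng)[0].id] += 1
        assert wins["r1"] >= wins["r2"] >= wins["r3"] >= wins["r4"]

    def test_pool_exhaustion_returns_what_exists(self, scored_factory, rng):
        pool = scored_factory([-1, -2])
        assert len(tournament_select(pool, 5, 0.5, rng=rng)) == 2


class TestSeedPools:
    def population(self):
        recs = make_scored([-1, -2, -3, -4, -5, -6, -7, -8])
        for i, r in enumerate(recs):
            r.scores["diversity"] = float(i % 4)
        return recs

    def test_ranking_gives_three_identical_pools(self, rng):
        pools = build_seed_pools(
            self.population(),
            {k: PoolCounts(3, 1) for k in ("elitism", "mutation", "crossover")},
            "ranking", rng)
        ids = [[r.id for r in p] for p in
               (pools.elitism_pool, pools.mutation_pool, pools.crossover_pool)]
        assert ids[0] == ids[1] == ids[2]

    def test_stochastic_pools_reproducible_under_fixed_seed(self):
        kwargs = dict(
            counts={k: PoolCounts(3, 1) for k in
                    ("elitism", "mutation", "crossover")},
            selector="roulette")
        a = build_seed_pools(self.population(), rng=np.random.default_rng(7), **kwargs)
        b = build_seed_pools(self.population(), rng=np.random.default_rng(7), **kwargs)
        assert [r.id for r in a.mutation_pool] == [r.id for r in b.mutation_pool]

    def test_pure_score_based_seeding(self, rng):
        pools = build_seed_pools(
            self.population(),
            {k: PoolCounts(4, 0) for k in ("elitism", "mutation", "crossover")},
            "ranking", rng)
        assert [r.scores["primary"] for r in pools.mutation_pool] == [-8, -7, -6, -5]

    def test_no_duplicates_within_a_pool(self, rng):
        pools = build_seed_pools(
            self.population(),
            {k: PoolCounts(4, 4) for k in ("elitism", "mutation", "crossover")},
            "roulette", rng)
        for p in (pools.elitism_pool, pools.mutation_pool, pools.crossover_pool):
            ids = [r.id for r in p]
            assert len(ids) == len(set(ids)) == 8

    def test_diversity_picks_prefer_unique_molecules(self, rng):
        pop = self.population()
        pools = build_seed_pools(
            pop, {k: PoolCounts(0, 2) for k in ("elitism", "mutation", "crossover")},
            "ranking", rng)
        # smallest diversity sums (most unique) are selected
        got = sorted(r.scores["diversity"] for r in pools.mutation_pool)
        assert got == [0.0, 0.0]
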
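"""Seed selection: Ranking, Roulette and Tournament selectors.

Each generation three seed pools are drawn — for elitism, mutation and
crossover — and each pool mixes compounds selected on the primary
(binding) score with compounds selected on the diversity score (smaller
diversity sum = more structurally unique).  With the deterministic Ranking
selector the three subselections are identical; with the stochastic
selectors they are independent draws.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import MoleculeRecord
from .scoring import WORST_SCORE

logger = logging.getLogger("evochem")

SELECTORS = ("ranking", "roulette", "tournament")

# non-zero weight floor so even the worst compound can advance
ROULETTE_EPSILON = 0.01


def _key_value(rec: MoleculeRecord, key: str) -> float:
    try:
        return rec.scores[key]
    except KeyError:
        raise ValueError(f"record {rec.id} has no score {key!r}") from None


def _sort_key(rec: MoleculeRecord, key: str, direction: str):
    v = _key_value(rec, key)
    return (v if direction == "min" else -v, rec.smiles, rec.id)


def ranking_select(
    pool: Sequence[MoleculeRecord], k: int, key: str = "primary",
    direction: str = "min",
) -> list[MoleculeRecord]:
    """The k best by ``key``; ties break by canonical SMILES then id."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(pool):
        logger.warning("ranking_select: k=%d > pool %d, selecting all", k, len(pool))
        k = len(pool)
    return sorted(pool, key=lambda r: _sort_key(r, key, direction))[:k]


def _roulette_weights(scores: np.ndarray, direction: str) -> np.ndarray:
    best = scores.min() if direction == "min" else scores.max()
    worst = scores.max() if direction == "min" else scores.min()
    span = abs(worst - best)
    if span == 0:
        return np.ones_like(scores)
    raw = (worst - scores) if direction == "min" else (scores - worst)
    return raw + ROULETTE_EPSILON * span


def roulette_select(
    pool: Sequence[MoleculeRecord], k: int, key: str = "primary",
    direction: str = "min", rng: np.random.Generator | None = None,
) -> list[MoleculeRecord]:
    """k fitness-weighted draws without replacement.

    Wheel areas are linear in score distance from the worst member plus a
    small floor, so every compound — even the most unfit — has a non-zero
    chance to advance; weights renormalize after each draw.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > 0 and not pool:
        raise ValueError("cannot select from an empty pool")
    rng = rng or np.random.default_rng()
    if k > len(pool):
        logger.warning("roulette_select: k=%d > pool %d, selecting all", k, len(pool))
        k = len(pool)
    scores = np.array([_key_value(r, key) for r in pool], dtype=float)
    weights = _roulette_weights(scores, direction)
    remaining = list(range(len(pool)))
    chosen = []
    for _ in range(k):
        w = weights[remaining]
        idx = rng.choice(len(remaining), p=w / w.sum())
        chosen.append(remaining.pop(idx))
    return [pool[i] for i in chosen]


def tournament_select(
    pool: Sequence[MoleculeRecord], k: int, tournament_fraction: float = 0.1,
    key: str = "primary", direction: str = "min",
    rng: np.random.Generator | None = None,
) -> list[MoleculeRecord]:
    """k rounds; each samples ceil(fraction * |pool|) compounds uniformly
    (at least 1) and advances the best; winners leave the pool."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if not (0 < tournament_fraction <= 1):
        raise ValueError("tournament_fraction must be in (0, 1]")
    rng = rng or np.random.default_rng()
    remaining = list(pool)
    winners = []
    while len(winners) < k and remaining:
        size = max(1, math.ceil(tournament_fraction * len(remaining)))
        idxs = rng.choice(len(remaining), size=size, replace=False)
        winner_pos = min(
            idxs, key=lambda i: _sort_key(remaining[i], key, direction)
        )
        winners.append(remaining.pop(winner_pos))
    if len(winners) < k:
        logger.warning("tournament_select: pool exhausted at %d of %d", len(winners), k)
    return winners


@dataclass
class SeedPools:
    """The three per-generation seed pools (no duplicates within a pool)."""

    elitism_pool: list[MoleculeRecord]
    mutation_pool: list[MoleculeRecord]
    crossover_pool: list[MoleculeRecord]


@dataclass(frozen=True)
class PoolCounts:
    n_by_score: int
    n_by_diversity: int = 0


def _one_subselection(
    population: Sequence[MoleculeRecord], counts: PoolCounts, selector: str,
    rng: np.random.Generator, tournament_fraction: float,
) -> list[MoleculeRecord]:
    def pick(pool, k, key):
        if selector == "ranking":
            return ranking_select(pool, k, key, "min")
        if selector == "roulette":
            return roulette_select(pool, k, key, "min", rng)
        if selector == "tournament":
            return tournament_select(pool, k, tournament_fraction, key, "min", rng)
        raise ValueError(f"unknown selector {selector!r}")

    by_score = pick(population, min(counts.n_by_score, len(population)), "primary")
    chosen_ids = {r.id for r in by_score}
    rest = [r for r in population if r.id not in chosen_ids]
    n_div = min(counts.n_by_diversity, len(rest))
    by_div = pick(rest, n_div, "diversity") if n_div else []
    return by_score + by_div


def build_seed_pools(
    population: Sequence[MoleculeRecord],
    counts: dict[str, PoolCounts],
    selector: str = "ranking",
    rng: np.random.Generator | None = None,
    tournament_fraction: float = 0.1,
) -> SeedPools:
    """Three subselections over the scored population.

    ``counts`` maps pool name (elitism / mutation / crossover) to its
    (by-score, by-diversity) counts.  Scoring-failure sentinels are
    excluded.  Ranking reuses one subselection for all pools that share the
    same counts; stochastic selectors draw each pool independently.
    """
    rng = rng or np.random.default_rng()
    eligible = [r for r in population if r.scores.get("primary") != WORST_SCORE]
    total = max(c.n_by_score + c.n_by_diversity for c in counts.values())
    if total > len(eligible):
        logger.warning("seed pools requested %d > population %d", total, len(eligible))

    pools = {}
    cache: dict[PoolCounts, list[MoleculeRecord]] = {}
    for name in ("elitism", "mutation", "crossover"):
        c = counts[name]
        if selector == "ranking":
            if c not in cache:
                cache[c] = _one_subselection(eligible, c, selector, rng,
                                             tournament_fraction)
            pools[name] = list(cache[c])
        else:
            pools[name] = _one_subselection(eligible, c, selector, rng,
                                            tournament_fraction)
    return SeedPools(
        elitism_pool=pools["elitism"],
        mutation_pool=pools["mutation"],
        crossover_pool=pools["crossover"],
    )
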
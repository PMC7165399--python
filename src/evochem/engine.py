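"""The generation loop: seed pools -> elitism / mutation / crossover ->
filtration with refill -> variant enumeration -> scoring -> ranking.

A run is fully deterministic under a fixed ``rng_seed`` when the surrogate
scorer is used: two runs with the same config produce byte-identical
ledgers.
"""
from __future__ import annotations

import json
import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import BRICS

from .chem import (MoleculeRecord, canonicalize, mol_from_smiles, read_smi,
                   write_ledger, write_smi)
from .crossover import CrossoverParams, crossover
from .filters import DEFAULT_REGISTRY, FilterRegistry, apply_filter_chain
from .fixtures import default_complementary_candidates, default_seed_library
from .reactions import (ComplementaryLibrary, OperatorFailure,
                        build_complementary_library, load_reaction_library,
                        mutate)
from .scoring import SCORER_REGISTRY, WORST_SCORE, score_population
from .selection import PoolCounts, build_seed_pools

logger = logging.getLogger("evochem")


class RunError(RuntimeError):
    """Refill exhaustion or an unusable configuration."""


@dataclass
class RunConfig:
    """Configuration of one GA run (JSON-serializable).

    ``None`` seed path means the bundled synthetic seed library.  First
    generation sizes may differ from later ones (``*_g1`` fields), matching
    the conservative-first-generation pattern of seeding from small
    fragment libraries.
    """

    seed_smi_path: str | None = None
    generations: int = 5
    n_elitism: int = 10
    n_mutation: int = 50
    n_crossover: int = 50
    n_elitism_g1: int | None = None
    n_mutation_g1: int | None = None
    n_crossover_g1: int | None = None
    filter_chain: list[str] = field(default_factory=lambda: ["Lipinski"])
    reaction_set: str = "AllRxn"          # bundled set name or path to JSON
    complementary_library: str = "bundled"  # "bundled" or path to an SMI file
    selector: str = "ranking"
    tournament_fraction: float = 0.1
    seeds_by_score: int = 15
    seeds_by_diversity: int = 15
    elitism_by_score: int | None = None   # defaults to n_elitism
    elitism_by_diversity: int = 0
    fitness: str = "surrogate"
    ligand_efficiency: bool = True
    rescore_elites: bool = False
    max_variants_per_molecule: int = 1
    ph_range: tuple[float, float] = (6.4, 8.4)
    rng_seed: int = 0
    max_refill_factor: int = 50           # attempts budget = factor * shortfall
    workers: int = 1
    fingerprint_radius: int = 2
    fingerprint_nbits: int = 2048
    min_core_atoms: int = 4
    mcs_timeout: float = 1.0

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name in ("n_elitism", "n_mutation", "n_crossover"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def sizes(self, generation: int) -> tuple[int, int, int]:
        if generation == 1:
            return (
                self.n_elitism_g1 if self.n_elitism_g1 is not None else self.n_elitism,
                self.n_mutation_g1 if self.n_mutation_g1 is not None else self.n_mutation,
                self.n_crossover_g1 if self.n_crossover_g1 is not None else self.n_crossover,
            )
        return self.n_elitism, self.n_mutation, self.n_crossover

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if "ph_range" in data:
            data["ph_range"] = tuple(data["ph_range"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass
class GenerationSummary:
    generation: int
    population_size: int
    created: dict[str, int]
    filtered: dict[str, int]
    scoring_failures: int
    duplicates_removed: int
    best: float
    mean: float
    top10_mean: float

    def conservation_holds(self) -> bool:
        return (sum(self.created.values()) - sum(self.filtered.values())
                - self.scoring_failures - self.duplicates_removed
                ) == self.population_size


@dataclass
class RunState:
    generation: int
    population: list[MoleculeRecord]
    ledger: dict[str, MoleculeRecord]
    comp_library: ComplementaryLibrary
    reaction_library: object
    registry: FilterRegistry


def _identity_variants(smiles: str) -> list[str]:
    return [smiles]


def _stats(population: Sequence[MoleculeRecord]) -> tuple[float, float, float]:
    scores = sorted(r.scores["primary"] for r in population
                    if r.scores.get("primary", WORST_SCORE) != WORST_SCORE)
    if not scores:
        return math.nan, math.nan, math.nan
    top10 = scores[:10]
    return scores[0], sum(scores) / len(scores), sum(top10) / len(top10)


def advance_generation(
    state: RunState,
    config: RunConfig,
    rng: np.random.Generator,
    variant_enumerator: Callable[[str], Sequence[str]] | None = None,
) -> tuple[RunState, GenerationSummary]:
    """Create generation ``state.generation + 1`` from the current one."""
    gen = state.generation + 1
    n_elite, n_mut, n_cross = config.sizes(gen)
    counts = {
        "elitism": PoolCounts(
            config.elitism_by_score if config.elitism_by_score is not None else n_elite,
            config.elitism_by_diversity,
        ),
        "mutation": PoolCounts(config.seeds_by_score, config.seeds_by_diversity),
        "crossover": PoolCounts(config.seeds_by_score, config.seeds_by_diversity),
    }
    pools = build_seed_pools(state.population, counts, config.selector, rng,
                             config.tournament_fraction)
    if n_elite and not pools.elitism_pool:
        raise RunError("empty elitism seed pool")
    if n_mut and not pools.mutation_pool:
        raise RunError("empty mutation seed pool")
    if n_cross and len(pools.crossover_pool) < 2:
        raise RunError("crossover seed pool has fewer than 2 compounds")

    new_population: list[MoleculeRecord] = []
    seen_smiles: set[str] = set()
    created = {"elitism": 0, "mutation": 0, "crossover": 0}
    filtered = {name: 0 for name in config.filter_chain}
    duplicates = 0

    # elitism: advance unchanged
    elite_carry: dict[str, float] = {}
    for i, parent in enumerate(pools.elitism_pool[:n_elite]):
        child = MoleculeRecord(
            id=f"g{gen}_E{i + 1}", smiles=parent.smiles, generation=gen,
            origin="elitism", parent_ids=(parent.id,),
        )
        created["elitism"] += 1
        if child.smiles in seen_smiles:
            duplicates += 1
            continue
        seen_smiles.add(child.smiles)
        new_population.append(child)
        if not config.rescore_elites:
            elite_carry[child.id] = parent.scores["primary"]

    xover_params = CrossoverParams(min_core_atoms=config.min_core_atoms,
                                   timeout=config.mcs_timeout)

    counters = {"mutation": 0, "crossover": 0}

    def attempt(operator: str) -> bool:
        """One operator application; True iff a new molecule joined the
        generation."""
        nonlocal duplicates
        counters[operator] += 1
        code = "M" if operator == "mutation" else "X"
        child_id = f"g{gen}_{code}{counters[operator]}"
        if operator == "mutation":
            pool = pools.mutation_pool
            parent = pool[rng.integers(len(pool))]
            result = mutate(parent, state.reaction_library, state.comp_library,
                            rng, child_id=child_id, generation=gen)
        else:
            pool = pools.crossover_pool
            i, j = rng.choice(len(pool), size=2, replace=False)
            result = crossover(pool[i], pool[j], rng, xover_params,
                               child_id=child_id, generation=gen)
        if isinstance(result, OperatorFailure):
            return False
        created[operator] += 1
        if result.smiles in seen_smiles:
            duplicates += 1
            return False
        survivors, rejections = apply_filter_chain(
            [result], config.filter_chain, state.registry)
        if not survivors:
            for name, n in rejections.items():
                filtered[name] += n
            return False
        seen_smiles.add(result.smiles)
        new_population.append(result)
        return True

    # first pass: each operator works toward its own quota
    made = {"mutation": 0, "crossover": 0}
    for operator, target in (("mutation", n_mut), ("crossover", n_cross)):
        budget = config.max_refill_factor * target
        while made[operator] < target and budget > 0:
            budget -= 1
            if attempt(operator):
                made[operator] += 1
    # refill: a shortfall loops back to both operators until the generation
    # is full or the attempt budget runs out
    shortfall = (n_mut - made["mutation"]) + (n_cross - made["crossover"])
    if shortfall > 0:
        budget = config.max_refill_factor * shortfall
        usable = [op for op, tgt in (("mutation", n_mut), ("crossover", n_cross))
                  if tgt > 0]
        turn = 0
        while shortfall > 0 and budget > 0:
            budget -= 1
            if attempt(usable[turn % len(usable)]):
                shortfall -= 1
            turn += 1
        if shortfall > 0:
            bottleneck = max(filtered, key=filtered.get) if filtered else "none"
            raise RunError(
                f"refill exhausted in generation {gen}: mutation "
                f"{made['mutation']}/{n_mut}, crossover "
                f"{made['crossover']}/{n_cross}, {shortfall} still missing; "
                f"heaviest filter: {bottleneck}"
            )

    scored, failures = _score(new_population, config, variant_enumerator)
    for rec in scored:
        if rec.id in elite_carry:
            rec.scores["primary"] = elite_carry[rec.id]
    population = [r for r in scored if r.scores["primary"] != WORST_SCORE]
    # rank by primary score (ties by SMILES then id, direction min)
    population.sort(key=lambda r: (r.scores["primary"], r.smiles, r.id))

    for rec in population:
        state.ledger[rec.id] = rec
    best, mean, top10 = _stats(population)
    summary = GenerationSummary(
        generation=gen, population_size=len(population), created=created,
        filtered=filtered, scoring_failures=len(failures),
        duplicates_removed=duplicates, best=best, mean=mean, top10_mean=top10,
    )
    if not summary.conservation_holds():
        logger.error("bookkeeping mismatch in generation %d: %s", gen, summary)
    new_state = RunState(
        generation=gen, population=population, ledger=state.ledger,
        comp_library=state.comp_library, reaction_library=state.reaction_library,
        registry=state.registry,
    )
    return new_state, summary


def _score(records, config, variant_enumerator):
    scorer = SCORER_REGISTRY.get(config.fitness)
    if scorer is None:
        raise RunError(f"unknown fitness scorer {config.fitness!r}")
    enum = variant_enumerator or _identity_variants
    capped = lambda smi: list(enum(smi))[: config.max_variants_per_molecule]
    if config.workers > 1 and config.fitness in SCORER_REGISTRY:
        primaries = parallel_map(scorer, [r.smiles for r in records], config.workers)
        # order-independent reduction: identical to the serial path
        lookup = dict(zip([r.smiles for r in records], primaries))
        scorer = lambda smi: lookup.get(smi, SCORER_REGISTRY[config.fitness](smi))
    outcome = score_population(
        records, scorer, compute_ligand_efficiency=config.ligand_efficiency,
        radius=config.fingerprint_radius, nbits=config.fingerprint_nbits,
        variant_enumerator=capped,
    )
    return outcome.scored, outcome.failures


def parallel_map(fn, items: Iterable, workers: int = 1) -> list:
    """Order-preserving map; identical results for 1 or many workers."""
    items = list(items)
    if workers <= 1 or len(items) < 2:
        return [fn(x) for x in items]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(fn, items, chunksize=max(1, len(items) // workers)))


def initial_state(config: RunConfig,
                  registry: FilterRegistry | None = None) -> RunState:
    """Generation 0: seeds canonicalized, deduplicated and filtered."""
    registry = registry or DEFAULT_REGISTRY
    if config.seed_smi_path:
        seeds = read_smi(config.seed_smi_path, on_bad_line="skip")
    else:
        seeds = [MoleculeRecord(id=f"seed_{i + 1}", smiles=smi)
                 for i, smi in enumerate(default_seed_library())]
    unique, seen = [], set()
    for rec in seeds:
        if rec.smiles not in seen:
            seen.add(rec.smiles)
            unique.append(rec)
    survivors, rejections = apply_filter_chain(unique, config.filter_chain, registry)
    if not survivors:
        raise RunError("no seed molecules survive the filter chain")
    logger.info("generation 0: %d seeds (%d rejected by filters)",
                len(survivors), sum(rejections.values()))

    if config.reaction_set in ("AutoClickChemRxn", "RobustRxn", "AllRxn"):
        library = load_reaction_library(None, config.reaction_set)
    else:
        library = load_reaction_library(config.reaction_set, "custom")
    if config.complementary_library == "bundled":
        candidates = default_complementary_candidates()
    else:
        candidates = [r.smiles for r in
                      read_smi(config.complementary_library, on_bad_line="skip")]
    comp = build_complementary_library(candidates, library)
    return RunState(generation=0, population=survivors, ledger={},
                    comp_library=comp, reaction_library=library,
                    registry=registry)


def run(
    config: RunConfig,
    out_dir: str | Path | None = None,
    variant_enumerator: Callable[[str], Sequence[str]] | None = None,
    registry: FilterRegistry | None = None,
) -> tuple[RunState, list[MoleculeRecord], list[GenerationSummary]]:
    """Execute a full GA run; returns the final state, the lineage ledger
    (insertion-ordered records) and per-generation summaries."""
    rng = np.random.default_rng(config.rng_seed)
    state = initial_state(config, registry)
    scored, _ = _score(state.population, config, variant_enumerator)
    population = [r for r in scored if r.scores["primary"] != WORST_SCORE]
    population.sort(key=lambda r: (r.scores["primary"], r.smiles, r.id))
    state = RunState(0, population, {r.id: r for r in population},
                     state.comp_library, state.reaction_library, state.registry)
    best0, mean0, top0 = _stats(population)
    summaries = [GenerationSummary(0, len(population), {"seed": len(population)},
                                   {}, 0, 0, best0, mean0, top0)]
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
        _write_generation(out_path, state)
    try:
        for _ in range(config.generations):
            state, summary = advance_generation(state, config, rng,
                                                variant_enumerator)
            summaries.append(summary)
            if out_path:
                _write_generation(out_path, state)
    finally:
        if out_path:
            _flush_run_outputs(out_path, state, summaries)
    ledger_records = list(state.ledger.values())
    return state, ledger_records, summaries


def _write_generation(out_path: Path, state: RunState) -> None:
    gen_dir = out_path / f"generation_{state.generation}"
    gen_dir.mkdir(exist_ok=True)
    write_smi(state.population, gen_dir / "ranked.smi",
              scores=("primary", "diversity", "ligand_efficiency"))


def _flush_run_outputs(out_path: Path, state: RunState,
                       summaries: list[GenerationSummary]) -> None:
    write_ledger(state.ledger.values(), out_path / "ledger.tsv")
    with open(out_path / "summary.tsv", "w") as fh:
        fh.write("generation\tpopulation\tbest\tmean\ttop10_mean\t"
                 "created\tfiltered\tscoring_failures\tduplicates\n")
        for s in summaries:
            fh.write(
                f"{s.generation}\t{s.population_size}\t{s.best:.6f}\t"
                f"{s.mean:.6f}\t{s.top10_mean:.6f}\t"
                f"{sum(s.created.values())}\t{sum(s.filtered.values())}\t"
                f"{s.scoring_failures}\t{s.duplicates_removed}\n"
            )


def brics_fragment(smiles_list: Iterable[str],
                   keep_uncleavable: bool = False) -> list[str]:
    """BRICS-decompose molecules into fragments, attachment points replaced
    by hydrogens, deduplicated by canonical SMILES.

    Molecules with no cleavable bond contribute nothing unless
    ``keep_uncleavable`` is set (then they contribute themselves).
    """
    out, seen = [], set()
    for smiles in smiles_list:
        try:
            mol = mol_from_smiles(smiles)
        except Exception:
            logger.warning("brics_fragment: skipping unparsable %r", smiles)
            continue
        frags = sorted(BRICS.BRICSDecompose(mol))
        cleaved = [f for f in frags if "*" in f]
        if not cleaved:
            if keep_uncleavable:
                smi = canonicalize(smiles)
                if smi not in seen:
                    seen.add(smi)
                    out.append(smi)
            continue
        for frag in cleaved:
            fmol = Chem.MolFromSmiles(frag)
            if fmol is None:
                continue
            edit = Chem.RWMol(fmol)
            for atom in edit.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetAtomicNum(1)
                    atom.SetIsotope(0)
            try:
                plain = Chem.RemoveHs(edit.GetMol())
                Chem.SanitizeMol(plain)
                smi = Chem.MolToSmiles(plain)
            except Exception:
                continue
            if smi not in seen:
                seen.add(smi)
                out.append(smi)
    return out
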
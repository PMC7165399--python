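# Methods

## The evolutionary model

`evochem` treats ligand design as a generation-based genetic algorithm over
molecular graphs carried as canonical SMILES. A run starts from a source
population (generation 0) of fragments or known ligands. Each new generation
is assembled from three operator streams whose sizes are configured
independently (`n_elitism` / `n_mutation` / `n_crossover`, with optional
distinct first-generation sizes for runs seeded from small fragment
libraries):

1. **Seed selection.** Three seed pools — for elitism, mutation and
   crossover — are drawn from the scored previous generation. Each pool
   mixes `seeds_by_score` compounds selected on the primary score with
   `seeds_by_diversity` compounds selected on the diversity sum d
   (direction: minimize; small d = unique). With the deterministic Ranking
   selector the three subselections are identical; with Roulette or
   Tournament they are independent draws. Elitism decouples from
   mutation/crossover seeding, so the number of compounds advancing
   unchanged is controlled separately from the number of parents.
2. **Elitism** copies pool members into the new generation unchanged. By
   default their primary scores are carried over bit-identically
   (`rescore_elites=false`); rescoring exists for stochastic external
   scorers that may find better poses on reassessment. With at least one
   elite and no rescoring, the best score is monotonically non-increasing —
   an invariant asserted in the tests.
3. **Mutation** applies an in silico reaction: list all (reaction, slot)
   pairs whose eligibility SMARTS match the parent, sample one uniformly,
   sample a complementary partner uniformly from the other slot's group for
   bimolecular reactions, run the SMIRKS, sample one product set uniformly
   when several sites match, keep the largest product fragment (co-products
   such as the phenol released by a transesterification are discarded),
   sanitize and canonicalize. Inputs are charge-neutralized before matching;
   protonation-state handling belongs to the downstream variant-enumeration
   contract. Failures are structured values, never exceptions, so the engine
   can refill from other parents.
4. **Crossover** finds the maximum common connected substructure (MCS) of
   two parents under element + bond-order matching, cuts both parents into
   core + decorating moieties, and reassembles a child on the first parent's
   core instance, choosing each attachment position's moiety set from either
   parent with probability 1/2 (positions decorated by one parent choose
   between that moiety set and nothing). The child always contains the core.
5. **Filtration with refill.** New candidates are deduplicated by canonical
   SMILES within the generation and passed through the configured filter
   chain (AND semantics, first-rejector attribution). On shortfall the
   engine loops back to both operators until the generation is full or an
   attempt budget of `max_refill_factor × shortfall` (default 50×) is
   exhausted, which raises a diagnostic error naming the bottleneck.
6. **Variant enumeration contract.** Before scoring, a pluggable step may
   expand each SMILES into up to `max_variants_per_molecule` ionization /
   tautomer / stereoisomer variants (a pH range is carried in the config for
   such enumerators). The default is identity. Variant scores reduce by
   minimum, mirroring top-pose docking-score selection.
7. **Scoring and ranking.** The scorer contract is `SMILES → float`
   (docking convention, lower better). Per-molecule failures receive a
   sentinel worst score, are excluded from the diversity computation and
   from seeding, and are dropped from the population with their count
   reported. Ligand efficiency (score / heavy atoms) is attached when
   enabled. The generation is ranked by primary score with deterministic
   tie-breaking (canonical SMILES, then id).

Each generation's bookkeeping satisfies
`created − filtered − scoring_failures − duplicates = population size`,
checked in every test run.

## Fitness machinery

- **Dice similarity** is implemented directly on unfolded Morgan bit sets,
  exactly as the defining formula reads, rather than through a toolkit bulk
  routine — so the brute-force oracle tests compare two genuinely
  independent code paths. The 0/0 case (two empty fingerprints) is defined
  as 0.0, the conservative "completely different" reading, and logged.
- **Diversity** d(M) is the sum of M's pairwise similarities within its
  generation: O(n²), exact, order-preserving. Bounds 0 ≤ s ≤ 1 and
  0 ≤ d ≤ n−1 are property-tested.
- **Fingerprint defaults**: Morgan radius 2, 2048 bits, both configurable.
  These are the conventional ECFP4-equivalent settings; the method is not
  sensitive to them at desk scale.
- **Surrogate scorer**: `−(0.1·heavy_atoms + 1.0·rings + 0.5·(hbd + hba))`.
  It is a deterministic test double that makes end-to-end runs reproducible
  and gives the GA a smooth landscape to climb; it is *not* a binding
  affinity predictor, and nothing about passing tests under it transfers to
  docking accuracy claims. NNScore-style rescoring appears in the scorer
  registry as named placeholders that raise `NotImplementedError`.

## Selectors

- **Ranking**: sort and slice; ties break by canonical SMILES then id so
  runs are reproducible.
- **Roulette**: without-replacement draws with shifted-linear weights
  `w_i = (worst − score_i) + ε·|worst − best|`, ε = 0.01. The additive floor
  guarantees every compound — even the worst — a non-zero chance, matching
  the selector's purpose of injecting exploration; weights renormalize after
  each draw. A softmax transform was rejected because it introduces a
  temperature hyperparameter. All-equal scores degrade to uniform sampling.
- **Tournament**: k rounds; each samples ⌈fraction·|pool|⌉ compounds
  uniformly (minimum 1, default fraction 0.1) and advances the best; winners
  leave the pool. Fraction 1.0 reduces exactly to Ranking; the minimal
  fraction reduces to uniform sampling — both limits are tested.

Within a subselection, sampling is without replacement, so a seed pool of
size k holds k distinct molecules; overlap *across* pools is allowed.

## Descriptors and filters

Hydrogen-bond donors and acceptors use the Lipinski convention (HBD = O−H
plus N−H bond count, HBA = N plus O atom count) for consistency with the
rule-of-five bounds. logP and molar refractivity are Crippen
atom-contribution estimates; polar surface area is the topological (TPSA)
variant; rotatable bonds use the strict definition that excludes amide C−N;
atom counts include implicit hydrogens (the Ghose 20–70 "atoms" window is a
total-atom count). Since the rule sets' original publications predate any
single standard estimator, molecules near a numeric boundary may classify
differently under other logP/MR/PSA implementations.

Bounds are data, not code: Lipinski/Lipinski\* (logP ≤ 5, HBD ≤ 5,
HBA ≤ 10, MW ≤ 500; one violation allowed vs none), Ghose
(logP −0.4..5.6, MW 160..480, MR 40..130, atoms 20..70), Ghose\* (identical
with MW ≤ 500), Van de Waterbeemd (MW < 450, PSA < 90, strict as printed),
Mozziconacci (rotatable bonds ≤ 15, rings ≤ 6, N ≥ 1, O ≥ 1, halogens ≤ 7).
Violations are counted per bound. Boundary equality passes inclusive bounds.
The BRENK (105 alerts), NIH (180) and PAINS (480) catalogs are served by
RDKit's curated FilterCatalog; custom catalogs load from plain-text
SMARTS-per-line files and custom filter callables register by name.

## Reaction libraries

The bundled sets (36 click-style reactions, of which 15 are unimolecular
functional-group interconversions and 21 bimolecular couplings; 58 robust
bimolecular medicinal-chemistry reactions; union 94 with 79 bimolecular)
were authored for this package in the spirit of the classic click-chemistry
and robust-reaction collections. Set sizes and the bimolecular count are
asserted at load time. Every reaction ships with example reactants and a
self-test that applies the SMIRKS and checks a sanitizable product forms.
The GA's correctness does not hinge on any single reaction's chemistry: the
engine accepts arbitrary user libraries in the same JSON dialect
(`{name, smirks, num_reactants, slot_queries[], source_set,
example_reactants[]}`).

Complementary libraries follow fixed construction rules: candidates must
have MW < 250 Da, logP < 5, pass Lipinski\* with no violations, and match at
least one bimolecular slot; each (reaction, slot) group keeps at most 5000
molecules by lowest MW, ties broken lexicographically. The bundled partner
panel is synthetic: generated functional-group fragments plus a fixed list
of small reagents covering the bimolecular slots.

## Crossover numerics

MCS search uses element and bond-order comparison with
`ringMatchesRingOnly` and `completeRingsOnly` both true. Whole-ring matching
prevents chemically absurd ring/chain merges and guarantees each decorating
moiety touches the core at exactly one atom — a moiety with two attachment
points (a ring threading through the core) is unrepresentable and yields a
structured failure. The core floor is 4 heavy atoms (a 1-atom core
degenerates the operator into random fragment swapping) and the search
timeout is 1 s per pair; a timeout returns "no core", not an error.
Decompose→reassemble with all moieties from one parent reproduces that
parent's canonical SMILES exactly — the reconstruction invariant tested
across the fixture set. Stereochemistry is preserved through
canonicalization but may be dropped by operators when a reaction or
recombination makes it undefined. Child MW is bounded below by the core MW;
no upper bracketing is asserted, since moiety inheritance can shrink as well
as grow the child.

## Synthetic data

The fixture generator builds small molecules (≤ 20 heavy atoms, all passing
Lipinski\*) with one guaranteed functional group per class — alcohol,
carboxylic acid, primary amine, azide, terminal alkyne, aryl halide — from
randomized alkyl/aryl skeletons, deterministically under a seed. It emulates
the role of a fragment-vendor seed library: known reactive handles, small
sizes, chemical variety. It does **not** emulate real libraries'
scaffold diversity, stereochemistry, charge states or impurity salts, so
passing desk-scale tests demonstrates the correctness of the evolutionary
machinery, not performance on real screening chemistry. Desk-scale study
conditions use 30 seeds and 110-compound generations
(10 elitism + 50 mutation + 50 crossover) over 5 generations.

Default seed pools take 15 compounds by score and 15 by diversity per
operator. Pure score-based seeding from 10 parents converges within a few
generations on these small fixture populations — operator outputs become
duplicates or breach the filter chain, starving the refill loop — and
diversity-mixed seeding is precisely the mechanism this method class uses to
delay convergence.

## Determinism and parallelism

All stochastic choices flow from one `numpy` Generator seeded by
`rng_seed`; with the surrogate scorer, reruns produce byte-identical
ledgers. Candidate generation and scoring are order-preserving maps, and the
`parallel_map` contract requires identical results for one or many workers
(verified by test); the worker count therefore affects wall time only.

## Out of scope / limitations

Receptor preparation, docking execution, PDBQT conversion, pose rescoring
and interaction fingerprinting live behind external contracts and are not
implemented here. Synthesizability is not filtered or scored, and long runs
are expected to drift toward less synthesizable, heavier molecules unless
tighter MW filters or ligand-efficiency rescoring are applied. Deduplication
is per-generation only; a compound eliminated earlier may be recreated
later. Lineage is exact for mutation (reaction + partner recorded and
replayable) but crossover records parent identities only, not the sampled
moiety assignment.
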
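# evochem

A generation-based genetic algorithm (GA) for de novo small-molecule design
and lead optimization, operating directly on SMILES strings.

De novo structure-based design programs search chemistry space far beyond any
pre-enumerated screening library. `evochem` evolves a population of candidate
ligands generation by generation with three operators:

- **elitism** — the fittest compounds advance unchanged;
- **mutation** — an in silico chemical reaction (SMIRKS) transforms a parent,
  optionally combining it with a small partner drawn from per-functional-group
  *complementary fragment libraries*;
- **crossover** — two parents are merged on their **maximum common
  substructure**, with their decorating moieties randomly recombined.

Generated compounds pass through chained drug-likeness filters (the nine
classic rule sets: Lipinski, Lipinski\*, Ghose, Ghose\*, Van de Waterbeemd,
Mozziconacci, plus the BRENK / NIH / PAINS substructure alert catalogs), are
scored, and the best and most structurally unique compounds seed the next
generation.

## Fitness and diversity

The primary fitness follows the docking convention (kcal/mol-like,
lower = better). Receptor-based scoring is delegated to an external docking
adapter contract (Vina-compatible: receptor file, box center/size,
exhaustiveness, top-pose score extraction); a deterministic **surrogate
scorer** is bundled for desk-scale runs and testing.

Population diversity uses Morgan fingerprints with the Dice coefficient

```
s(F_A, F_B) = 2 |F_A ∩ F_B| / (|F_A| + |F_B|)
```

and per-molecule diversity sums

```
d(mol_M) = Σ_{N≠M} s(F_M, F_N)
```

where a *small* d marks a structurally unique molecule. Seed pools mix
compounds selected on the primary score with compounds selected on d, using
a **Ranking**, **Roulette** or **Tournament** selector; this combination
maintains selection pressure while delaying population convergence.

Ligand efficiency (primary score divided by heavy-atom count) is computed
alongside, to counter the drift toward ever-larger molecules that
size-biased scoring functions encourage.

## Worked example

```bash
python examples/run_ga.py
```

```
gen  size  best     mean     top10
  0    30    -2.40    -1.77    -2.21
  1   110    -6.00    -2.51    -4.49
  2   110    -8.00    -4.03    -6.57
  3   110    -9.20    -5.19    -8.35
  4   110   -10.90    -6.28   -10.10
  5   110   -12.10    -7.04   -11.13

best compound: O=C(NCCc1ccccc1)Nc1ccc(-c2ccccc2)c(-n2ccnc2)c1Sc1ccccc1  (id g5_X52, score -12.10)
```

Thirty synthetic seed fragments (generation 0) evolve through five
110-compound generations (10 elitism + 50 mutation + 50 crossover). The best
surrogate score improves monotonically — elites advance unchanged — from
−2.40 to −12.10. The id `g5_X52` says the winner arose by crossover (`X`) in
generation 5; `evochem lineage` replays its full ancestry down to the seeds.

Other examples, one per capability: `filters_demo.py`, `mutation_demo.py`
(including a mass-*decreasing* mutation: transesterification of phenyl
benzoate with methanol gives methyl benzoate, 136 Da from a 198 Da parent),
`crossover_demo.py`, `selection_diversity_demo.py`.

## Reaction libraries

Three bundled sets power the mutation operator: `AutoClickChemRxn` (36
click-chemistry style reactions), `RobustRxn` (58 robust medicinal-chemistry
couplings and heterocycle formations) and their union `AllRxn` (94 reactions,
79 bimolecular). Each reaction carries per-slot SMARTS eligibility queries
and example reactants; `evochem.self_test` applies every reaction to its
examples and checks a valid product forms. User libraries load from the same
JSON dialect.

## Command line

```bash
evochem run config.json --out results/ --seed 7
evochem filter seeds.smi --chain 'Ghose,Lipinski*,PAINS'
evochem fragment leads.smi          # BRICS decomposition for seed prep
evochem score seeds.smi             # surrogate scores as TSV
evochem lineage results/ledger.tsv g5_X52
```

`run` writes one directory per generation (ranked SMI with primary,
diversity and ligand-efficiency columns) plus a run-level lineage ledger and
summary TSV. With a fixed `rng_seed` and the surrogate scorer, reruns are
byte-identical.

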
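"""Fitness-based and diversity-based seed selection.

Computes Morgan fingerprints, pairwise Dice similarities and each
molecule's diversity sum (small sum = structurally unique), then draws
seed pools with the three selectors.
"""
import numpy as np

from evochem import (MoleculeRecord, dice_similarity, diversity_scores,
                     morgan_fingerprint, ranking_select, roulette_select,
                     score_population, surrogate_scorer, tournament_select)

smiles = ["CCO", "CCCO", "CCCCO", "c1ccccc1", "Cc1ccccc1", "CC(=O)O"]
fps = [morgan_fingerprint(s) for s in smiles]

print("pairwise Dice similarity of the two phenyl compounds:",
      f"{dice_similarity(fps[3], fps[4]):.3f}")
print("diversity sums (smaller = more unique):")
for s, d in zip(smiles, diversity_scores(fps)):
    print(f"  {s:12s} {d:.3f}")

records = [MoleculeRecord(id=s, smiles=s) for s in smiles]
scored = score_population(records, surrogate_scorer).scored

rng = np.random.default_rng(1)
print("\nranking (best 3 by primary score):",
      [r.id for r in ranking_select(scored, 3)])
print("roulette (fitness-weighted, without replacement):",
      [r.id for r in roulette_select(scored, 3, rng=rng)])
print("tournament (fraction 0.5):",
      [r.id for r in tournament_select(scored, 3, 0.5, rng=rng)])
# the ranking selector is deterministic; roulette and tournament trade
# exploitation for exploration and change with the random seed
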
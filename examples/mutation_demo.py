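"""Mutate a parent molecule with an in silico chemical reaction.

Demonstrates reaction matching, complementary-partner lookup, and the
classic mass-decreasing counterexample: transesterification of phenyl
benzoate with methanol yields methyl benzoate (the phenol co-product is
discarded), so the child is lighter than its parent.
"""
import numpy as np

from evochem import (MoleculeRecord, build_complementary_library,
                     canonicalize, compute_descriptors, load_reaction_library,
                     matching_reactions, mutate)
from evochem.fixtures import default_complementary_candidates
from evochem.reactions import enumerate_mutation_products

library = load_reaction_library(None, "AllRxn")
print(f"loaded {len(library)} reactions ({library.n_bimolecular} bimolecular)")

parent_smiles = canonicalize("O=C(Oc1ccccc1)c1ccccc1")  # phenyl benzoate
matches = matching_reactions(parent_smiles, library)
print(f"phenyl benzoate matches {len(matches)} (reaction, slot) pairs")

spec = library.get("transesterification")
products = enumerate_mutation_products(parent_smiles, spec, 0, "CO")
parent_mw = compute_descriptors(parent_smiles).mw
for child in products:
    print(f"  child {child}: MW {compute_descriptors(child).mw:.1f} Da "
          f"(parent {parent_mw:.1f} Da)")

# a random mutation through the full operator, with provenance
comp = build_complementary_library(default_complementary_candidates(), library)
parent = MoleculeRecord(id="parent", smiles=canonicalize("CC(=O)O"))
child = mutate(parent, library, comp, np.random.default_rng(4), child_id="child")
print(f"\nmutated {parent.smiles} -> {child.smiles} via {child.reaction_name}")
# reaction_name records 'reaction|complementary partner' so any mutant's
# lineage can be replayed exactly.
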
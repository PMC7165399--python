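"""Merge two parents on their largest common substructure.

The maximum common connected substructure (element + bond-order matching,
whole rings only) becomes the child's conserved core; each decorating
moiety position inherits from one parent or the other at random.
"""
import numpy as np

from evochem import (MoleculeRecord, canonicalize, crossover, decompose,
                     largest_common_substructure)

a = canonicalize("Cc1ccc(CC(C)N)cc1")     # 4-methylamphetamine-like
b = canonicalize("Clc1ccc(CCN)cc1")       # 4-chlorophenethylamine

core = largest_common_substructure(a, b)
print(f"common core: {core.heavy_atom_count} heavy atoms, SMARTS {core.pattern}")

for label, parent in (("A", a), ("B", b)):
    deco = decompose(parent, core)
    print(f"parent {label} ({parent}): {len(deco.moieties)} decorating "
          f"moieties {[m.smiles for m in deco.moieties]}")

rng = np.random.default_rng(0)
children = set()
for i in range(30):
    child = crossover(MoleculeRecord(id="a", smiles=a),
                      MoleculeRecord(id="b", smiles=b), rng, child_id=f"c{i}")
    children.add(child.smiles)
print(f"\n{len(children)} distinct children from 30 draws:")
for c in sorted(children):
    print(" ", c)
# every child contains the shared core; moiety sets recombine freely
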
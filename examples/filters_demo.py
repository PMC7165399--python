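"""Apply drug-likeness filters singly and as a chain.

Shows the per-bound violation accounting of the property filters and the
alert labels returned by the BRENK substructure catalog.
"""
from evochem import (MoleculeRecord, apply_filter_chain, compute_descriptors,
                     evaluate_property_filter, evaluate_substructure_filter)
from evochem.filters import PROPERTY_FILTERS, SubstructureCatalog

molecules = {
    "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "azo compound": "CC/N=N/CC",
    "big greasy": "CCCCCCCCCCCCCCCCCCCCCCCCCCCCCCCC(=O)O",
}

for name, smi in molecules.items():
    desc = compute_descriptors(smi)
    ok, violations = evaluate_property_filter(desc, PROPERTY_FILTERS["Lipinski"])
    print(f"{name}: MW {desc.mw:.1f} Da, logP {desc.logp:.2f} -> "
          f"Lipinski {'pass' if ok else 'FAIL'} (violations: {violations})")

ok, matched = evaluate_substructure_filter(molecules["azo compound"],
                                           SubstructureCatalog("BRENK"))
print(f"\nBRENK alerts on the azo compound: {matched}")

records = [MoleculeRecord(id=k, smiles=v) for k, v in molecules.items()]
survivors, rejections = apply_filter_chain(records, ["Lipinski", "BRENK"])
print(f"chain [Lipinski, BRENK]: {len(survivors)}/{len(records)} survive; "
      f"rejections attributed to the first failing filter: {rejections}")
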
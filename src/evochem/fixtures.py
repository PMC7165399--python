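"""Deterministic synthetic seed libraries for desk-scale runs and tests.

Real campaigns seed the GA from vendor fragment libraries; those require
downloads, so this module builds small (<= 20 heavy atoms) molecules with
known functional groups instead.  Every generated molecule matches its
class's substructure query and passes the strict Lipinski* filter.
"""
from __future__ import annotations

import numpy as np
from rdkit import Chem

from .chem import canonicalize, compute_descriptors
from .filters import PROPERTY_FILTERS, evaluate_property_filter

CLASS_QUERIES = {
    "alcohol": "[CX4][OX2H1]",
    "carboxylic_acid": "[CX3](=O)[OX2H1]",
    "primary_amine": "[CX4][NX3;H2]",
    "azide": "[CX4]N=[N+]=[N-]",
    "terminal_alkyne": "[CX2H1]#C",
    "aryl_halide": "c[Cl,Br,I]",
}


class FixtureConfigError(ValueError):
    pass


def _alkyl(rng: np.random.Generator, min_len: int = 1, max_len: int = 6) -> str:
    """A small random alkyl chain, optionally methyl-branched."""
    length = int(rng.integers(min_len, max_len + 1))
    chain = ["C"] * length
    if length >= 3 and rng.random() < 0.4:
        pos = int(rng.integers(1, length - 1))
        chain[pos] = "C(C)"
    return "".join(chain)


def _candidate(cls: str, rng: np.random.Generator) -> str:
    alk = _alkyl(rng)
    if cls == "alcohol":
        return alk + "O"
    if cls == "carboxylic_acid":
        return alk + "C(=O)O"
    if cls == "primary_amine":
        return alk + "N"
    if cls == "azide":
        return alk + "N=[N+]=[N-]"
    if cls == "terminal_alkyne":
        return "C#C" + alk
    if cls == "aryl_halide":
        hal = ["F", "Cl", "Br"][int(rng.integers(3))]
        return f"{hal}c1ccc({alk})cc1" if rng.random() < 0.7 else f"{hal}c1ccccc1"
    raise FixtureConfigError(f"unknown functional-group class {cls!r}")


def generate_fixture_library(
    spec: dict[str, int], rng: np.random.Generator | int | None = None
) -> list[str]:
    """Generate ``spec[cls]`` distinct molecules per functional-group class.

    Class names accept spaces or underscores.  Deterministic under a fixed
    seed; raises on unknown class names.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lipinski_star = PROPERTY_FILTERS["Lipinski*"]
    out: list[str] = []
    seen: set[str] = set()
    for raw_cls, n in spec.items():
        cls = raw_cls.strip().lower().replace(" ", "_")
        if cls not in CLASS_QUERIES:
            raise FixtureConfigError(f"unknown functional-group class {raw_cls!r}")
        if n < 1:
            raise FixtureConfigError("need n >= 1 per class")
        query = Chem.MolFromSmarts(CLASS_QUERIES[cls])
        made = 0
        guard = 0
        while made < n:
            guard += 1
            if guard > 10000:
                raise FixtureConfigError(f"cannot generate {n} distinct {cls}")
            smi = canonicalize(_candidate(cls, rng))
            if smi in seen:
                continue
            mol = Chem.MolFromSmiles(smi)
            desc = compute_descriptors(smi)
            if desc.heavy_atoms > 20:
                continue
            if not mol.HasSubstructMatch(query):
                continue
            if not evaluate_property_filter(desc, lipinski_star)[0]:
                continue
            seen.add(smi)
            out.append(smi)
            made += 1
    return out


DEFAULT_FIXTURE_SPEC = {
    "alcohol": 6,
    "carboxylic_acid": 6,
    "primary_amine": 6,
    "azide": 4,
    "terminal_alkyne": 4,
    "aryl_halide": 4,
}


def default_seed_library(seed: int = 12345) -> list[str]:
    """The bundled desk-scale seed library (30 small functional molecules)."""
    return generate_fixture_library(DEFAULT_FIXTURE_SPEC, seed)


def default_complementary_candidates(seed: int = 54321) -> list[str]:
    """Candidate partners for the bundled complementary library.

    Mixes generated functional-group molecules with a fixed panel of small
    reagents covering the bimolecular reaction slots (thiols, aldehydes,
    ketones, haloketones, boronic acids, hydrazines, amidines, anilines...).
    """
    generated = generate_fixture_library(
        {"alcohol": 8, "carboxylic_acid": 8, "primary_amine": 8,
         "azide": 6, "terminal_alkyne": 6, "aryl_halide": 6},
        seed,
    )
    panel = [
        "CS", "CCS", "CCCS", "SCC(C)C",          # thiols
        "Sc1ccccc1", "Oc1ccccc1", "Cc1ccc(O)cc1",  # thiophenol, phenols
        "Nc1ccccc1", "Cc1ccc(N)cc1",             # anilines
        "CC=O", "CCC=O", "O=Cc1ccccc1",          # aldehydes
        "CC(C)=O", "CCC(C)=O",                   # ketones
        "CC(=O)CCl", "O=C(CBr)c1ccccc1",         # alpha-haloketones
        "CC(=O)CC(C)=O", "CCC(=O)CC(C)=O",       # 1,3-diketones
        "CC(=O)CCC(C)=O",                        # 1,4-diketone
        "NN", "CNN", "NO",                       # hydrazines, hydroxylamine
        "CC(=O)NN", "CC(N)=S", "NC(N)=S",        # acylhydrazide, thioamides
        "CC(=N)N",                               # amidine
        "OB(O)c1ccccc1", "OB(O)c1ccc(C)cc1",     # boronic acids
        "CC1CO1", "C1CO1",                       # epoxides
        "CCN=C=O", "CCN=C=S",                    # isocyanate, isothiocyanate
        "CS(=O)(=O)Cl", "CS(N)(=O)=O",           # sulfonyl chloride/amide
        "CC(=O)Cl", "CCOC(=O)Cl",                # acyl chloride, chloroformate
        "CC(=O)OC", "CC(=O)OC(C)=O",             # ester, anhydride
        "CCNC", "CCNCC",                         # secondary amines
        "C=CC(C)=O",                             # enone
        "CCBr", "CBr", "CCCBr", "CCI",           # alkyl halides
        "Nc1ccccc1N", "Nc1ccccc1O", "Nc1ccccc1S",  # ortho-substituted anilines
        "NCCc1ccccc1", "Nc1ccccc1C(C)=O",        # arylethylamine, aminoaryl ketone
        "c1cc[nH]c1", "c1c[nH]cn1",              # NH azoles
        "CC#N", "CCO", "CO", "CCCO",             # nitriles / alcohols
        "O=Cc1ccccc1O",                          # salicylaldehyde
    ]
    seen, out = set(), []
    for smi in generated + [canonicalize(s) for s in panel]:
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    return out
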
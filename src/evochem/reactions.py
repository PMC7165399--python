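"""Reaction libraries and the mutation operator.

A mutation applies one in silico chemical reaction (SMIRKS) to a parent
molecule.  Unimolecular reactions transform the parent alone; bimolecular
reactions combine the parent with a partner drawn from a complementary
fragment library keyed by (reaction, slot).  Three reaction sets ship with
the package: AutoClickChemRxn (36 click-chemistry style reactions),
RobustRxn (58 robust medicinal-chemistry couplings) and their union AllRxn
(94 reactions, 79 of them bimolecular).
"""
from __future__ import annotations

import json
import logging
from functools import lru_cache
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem import MoleculeRecord, canonicalize, compute_descriptors, mol_from_smiles
from .filters import PROPERTY_FILTERS, evaluate_property_filter

logger = logging.getLogger("evochem")

REACTION_SETS = ("AutoClickChemRxn", "RobustRxn", "AllRxn")
_BUNDLED = {"AutoClickChemRxn": "autoclick_rxn.json", "RobustRxn": "robust_rxn.json"}
_EXPECTED_SIZES = {"AutoClickChemRxn": 36, "RobustRxn": 58, "AllRxn": 94}
_EXPECTED_BIMOLECULAR_ALL = 79


class ReactionLoadError(ValueError):
    """Malformed library file, unparsable SMIRKS, or slot/template mismatch."""


@dataclass(frozen=True)
class OperatorFailure:
    """Structured failure from a GA operator; the engine refills elsewhere."""

    operator: str
    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class ReactionSpec:
    """One in silico reaction: SMIRKS plus per-slot eligibility SMARTS."""

    name: str
    smirks: str
    num_reactants: int
    slot_queries: list[str]
    source_set: str
    example_reactants: list[str] = field(default_factory=list)
    description: str = ""
    _rxn: object = field(default=None, repr=False, compare=False)
    _slot_mols: list = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self):
        try:
            rxn = AllChem.ReactionFromSmarts(self.smirks)
        except Exception as exc:
            raise ReactionLoadError(
                f"{self.name}: SMIRKS does not parse ({exc})") from exc
        if rxn is None:
            raise ReactionLoadError(f"{self.name}: SMIRKS does not parse")
        if rxn.GetNumReactantTemplates() != self.num_reactants:
            raise ReactionLoadError(
                f"{self.name}: SMIRKS has {rxn.GetNumReactantTemplates()} "
                f"reactant templates but num_reactants={self.num_reactants}"
            )
        if len(self.slot_queries) != self.num_reactants:
            raise ReactionLoadError(
                f"{self.name}: {len(self.slot_queries)} slot queries for "
                f"{self.num_reactants} reactants"
            )
        self._rxn = rxn
        for q in self.slot_queries:
            qm = Chem.MolFromSmarts(q)
            if qm is None:
                raise ReactionLoadError(f"{self.name}: bad slot SMARTS {q!r}")
            self._slot_mols.append(qm)

    def slot_matches(self, mol: Chem.Mol) -> list[int]:
        return [i for i, q in enumerate(self._slot_mols) if mol.HasSubstructMatch(q)]

    def run(self, reactants: tuple[Chem.Mol, ...]) -> list[list[Chem.Mol]]:
        """All product sets from applying the SMIRKS (unsanitized)."""
        return [list(ps) for ps in self._rxn.RunReactants(reactants)]


@dataclass
class ReactionLibrary:
    set_name: str
    reactions: list[ReactionSpec]
    _match_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        names = [r.name for r in self.reactions]
        if len(set(names)) != len(names):
            raise ReactionLoadError(f"{self.set_name}: duplicate reaction names")

    @property
    def n_bimolecular(self) -> int:
        return sum(1 for r in self.reactions if r.num_reactants == 2)

    def __len__(self) -> int:
        return len(self.reactions)

    def get(self, name: str) -> ReactionSpec:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)


def _load_entries(path) -> list[dict]:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ReactionLoadError(f"{path}: malformed JSON ({exc})") from exc


def load_reaction_library(path: str | Path | None = None,
                          set_name: str = "AllRxn") -> ReactionLibrary:
    """Load a reaction library from a JSON file, or a bundled set by name.

    With ``path=None``, ``set_name`` selects a bundled set; bundled sets are
    size-checked (36/58/94 reactions, 79 bimolecular in AllRxn) at load time.
    """
    if path is None:
        if set_name == "AllRxn":
            parts = [load_reaction_library(None, s) for s in _BUNDLED]
            lib = ReactionLibrary("AllRxn", [r for p in parts for r in p.reactions])
        elif set_name in _BUNDLED:
            ref = resources.files("evochem.data.reactions") / _BUNDLED[set_name]
            entries = _load_entries(ref)
            lib = ReactionLibrary(set_name, [_spec_from(e) for e in entries])
        else:
            raise ReactionLoadError(f"unknown bundled set {set_name!r}")
        if len(lib) != _EXPECTED_SIZES[set_name]:
            raise ReactionLoadError(
                f"bundled {set_name} has {len(lib)} reactions, "
                f"expected {_EXPECTED_SIZES[set_name]}"
            )
        if set_name == "AllRxn" and lib.n_bimolecular != _EXPECTED_BIMOLECULAR_ALL:
            raise ReactionLoadError(
                f"bundled AllRxn has {lib.n_bimolecular} bimolecular reactions, "
                f"expected {_EXPECTED_BIMOLECULAR_ALL}"
            )
    else:
        entries = _load_entries(path)
        lib = ReactionLibrary(set_name, [_spec_from(e) for e in entries])
    logger.info("loaded reaction library %s: %d reactions (%d bimolecular)",
                lib.set_name, len(lib), lib.n_bimolecular)
    return lib


def _spec_from(entry: dict) -> ReactionSpec:
    try:
        return ReactionSpec(
            name=entry["name"], smirks=entry["smirks"],
            num_reactants=int(entry["num_reactants"]),
            slot_queries=list(entry["slot_queries"]),
            source_set=entry.get("source_set", "custom"),
            example_reactants=list(entry.get("example_reactants", [])),
            description=entry.get("description", ""),
        )
    except KeyError as exc:
        raise ReactionLoadError(f"reaction entry missing key {exc}") from exc


def self_test(library: ReactionLibrary) -> dict[str, bool]:
    """Apply every reaction to its bundled example reactants and check that
    at least one sanitizable product forms."""
    results = {}
    for spec in library.reactions:
        ok = False
        if len(spec.example_reactants) == spec.num_reactants:
            mols = tuple(Chem.MolFromSmiles(s) for s in spec.example_reactants)
            if all(m is not None for m in mols):
                for pset in spec.run(mols):
                    for product in pset:
                        if _sanitized_smiles(product) is not None:
                            ok = True
        results[spec.name] = ok
    return results


_UNCHARGER = rdMolStandardize.Uncharger()


@lru_cache(maxsize=65536)
def neutralize(smiles: str) -> str:
    """Remove formal charges where possible before reaction matching."""
    mol = mol_from_smiles(smiles)
    return Chem.MolToSmiles(_UNCHARGER.uncharge(mol))


def matching_reactions(smiles: str, library: ReactionLibrary
                       ) -> list[tuple[ReactionSpec, int]]:
    """Every (reaction, slot) whose slot query matches the molecule."""
    cached = library._match_cache.get(smiles)
    if cached is not None:
        return cached
    mol = mol_from_smiles(neutralize(smiles))
    out = []
    for spec in library.reactions:
        for slot in spec.slot_matches(mol):
            out.append((spec, slot))
    if len(library._match_cache) < 65536:
        library._match_cache[smiles] = out
    return out


@dataclass
class ComplementaryLibrary:
    """Per-(reaction, slot) groups of small reaction partners."""

    groups: dict[tuple[str, int], list[str]] = field(default_factory=dict)

    def group(self, reaction_name: str, slot: int) -> list[str]:
        return self.groups.get((reaction_name, slot), [])

    def __len__(self) -> int:
        return len(self.groups)


def build_complementary_library(
    candidates: list[str],
    library: ReactionLibrary,
    mw_cap: float = 250.0,
    logp_cap: float = 5.0,
    per_group_cap: int = 5000,
) -> ComplementaryLibrary:
    """Group small fragments by the reaction slots they can serve.

    Candidates above the MW/logP caps or failing Lipinski* (no violations)
    are discarded, as are candidates matching no slot query.  Each group
    keeps at most ``per_group_cap`` molecules, lowest MW first (ties broken
    lexicographically by canonical SMILES).  One molecule may appear in many
    groups.
    """
    if not candidates:
        logger.warning("empty candidate list for complementary library")
        return ComplementaryLibrary()
    lipinski_star = PROPERTY_FILTERS["Lipinski*"]
    staged: dict[tuple[str, int], list[tuple[float, str]]] = {}
    for raw in candidates:
        smi = canonicalize(raw)
        desc = compute_descriptors(smi)
        if desc.mw >= mw_cap or desc.logp >= logp_cap:
            continue
        if not evaluate_property_filter(desc, lipinski_star)[0]:
            continue
        matches = matching_reactions(smi, library)
        for spec, slot in matches:
            if spec.num_reactants < 2:
                continue
            staged.setdefault((spec.name, slot), []).append((desc.mw, smi))
    groups = {}
    for key, entries in staged.items():
        entries.sort()
        seen, kept = set(), []
        for _, smi in entries:
            if smi not in seen:
                seen.add(smi)
                kept.append(smi)
            if len(kept) == per_group_cap:
                break
        groups[key] = kept
    return ComplementaryLibrary(groups)


def _sanitized_smiles(product: Chem.Mol) -> str | None:
    """Sanitize a raw reaction product; keep the largest fragment; None on
    chemically invalid output."""
    try:
        product.UpdatePropertyCache(strict=False)
        Chem.SanitizeMol(product)
        frags = Chem.GetMolFrags(product, asMols=True, sanitizeFrags=True)
        if not frags:
            return None
        best = max(
            ((m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)) for m in frags),
            key=lambda t: (t[0], t[1]),
        )
        # round-trip so the child is guaranteed parseable + canonical
        return canonicalize(best[1])
    except Exception:
        return None


_PRODUCT_CACHE: dict[tuple, list[str]] = {}


def enumerate_mutation_products(
    parent_smiles: str, spec: ReactionSpec, slot: int,
    partner_smiles: str | None = None,
) -> list[str]:
    """All distinct sanitized largest-fragment products of applying ``spec``
    with the parent in ``slot`` (and the partner in the other slot).
    Memoized: the GA revisits the same (parent, reaction, partner) often."""
    key = (spec.source_set, spec.name, parent_smiles, slot, partner_smiles)
    hit = _PRODUCT_CACHE.get(key)
    if hit is not None:
        return hit
    parent = mol_from_smiles(neutralize(parent_smiles))
    if spec.num_reactants == 1:
        reactants: tuple = (parent,)
    else:
        if partner_smiles is None:
            raise ValueError("bimolecular reaction needs a partner")
        partner = mol_from_smiles(neutralize(partner_smiles))
        reactants = (parent, partner) if slot == 0 else (partner, parent)
    products = []
    for pset in spec.run(reactants):
        # a product set may carry co-products (e.g. the phenol released by a
        # transesterification); keep only the set's largest fragment
        candidates = [s for s in (_sanitized_smiles(p) for p in pset)
                      if s is not None]
        if not candidates:
            continue
        smi = max(candidates,
                  key=lambda s: (mol_from_smiles(s).GetNumHeavyAtoms(), s))
        if smi not in products:
            products.append(smi)
    if len(_PRODUCT_CACHE) < 65536:
        _PRODUCT_CACHE[key] = products
    return products


def mutate(
    parent: MoleculeRecord,
    library: ReactionLibrary,
    comp: ComplementaryLibrary,
    rng: np.random.Generator,
    max_attempts: int = 10,
    child_id: str = "mutant",
    generation: int | None = None,
) -> MoleculeRecord | OperatorFailure:
    """Apply a randomly chosen matching reaction to ``parent``.

    Uniformly samples a matching (reaction, slot); for bimolecular reactions
    uniformly samples the partner from the complementary group of the other
    slot; when several product sets arise from multiple matching sites, one
    is sampled uniformly.  The largest product fragment becomes the child.
    Retries up to ``max_attempts`` times; returns :class:`OperatorFailure`
    when nothing applies.
    """
    matches = matching_reactions(parent.smiles, library)
    if not matches:
        return OperatorFailure("mutation", "no matching reaction")
    gen = parent.generation + 1 if generation is None else generation
    for _ in range(max_attempts):
        spec, slot = matches[rng.integers(len(matches))]
        partner = None
        if spec.num_reactants == 2:
            pool = comp.group(spec.name, 1 - slot)
            if not pool:
                continue
            partner = pool[rng.integers(len(pool))]
        try:
            products = enumerate_mutation_products(parent.smiles, spec, slot, partner)
        except Exception:
            continue
        if not products:
            continue
        child_smiles = products[rng.integers(len(products))]
        return MoleculeRecord(
            id=child_id,
            smiles=child_smiles,
            generation=gen,
            origin="mutation",
            parent_ids=(parent.id,),
            reaction_name=f"{spec.name}" + (f"|{partner}" if partner else ""),
        )
    return OperatorFailure("mutation", "max_attempts exhausted")
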
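"""Largest-common-substructure crossover.

Two parents are merged by finding their maximum common connected
substructure (the "core"), cutting each parent into core + decorating
moieties, and reassembling a child on the core with each attachment
position inheriting its moieties from one parent or the other at random.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem import MoleculeRecord, canonicalize, mol_from_smiles

logger = logging.getLogger("evochem")


class DecompositionError(ValueError):
    """Core not present, or a moiety touches the core at more than one atom."""


@dataclass(frozen=True)
class CrossoverParams:
    # a 1-atom "core" degenerates the operator; 4 heavy atoms is the floor
    min_core_atoms: int = 4
    timeout: float = 1.0
    ring_matches_ring_only: bool = True
    complete_rings_only: bool = True


@dataclass(frozen=True)
class CorePattern:
    """The shared substructure as a SMARTS query."""

    pattern: str
    heavy_atom_count: int

    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.pattern)


@dataclass(frozen=True)
class Moiety:
    """A decorating fragment bonded to exactly one core atom.

    ``position`` indexes the core pattern atom it hangs from; ``smiles``
    contains a single dummy atom ``[*]`` marking the attachment point and
    ``bond_type`` is the cut bond's order.
    """

    position: int
    smiles: str
    bond_type: Chem.BondType


@dataclass
class DecoratedCore:
    """One parent cut into its core instance plus decorating moieties."""

    parent_smiles: str
    core: CorePattern
    core_atom_map: tuple[int, ...]  # pattern atom index -> parent atom index
    moieties: tuple[Moiety, ...]
    _core_mol: Chem.Mol = field(default=None, repr=False, compare=False)

    def core_mol(self) -> Chem.Mol:
        """The parent's core atoms as a standalone molecule, with atom map
        numbers set to (pattern index + 1)."""
        if self._core_mol is None:
            parent = mol_from_smiles(self.parent_smiles)
            edit = Chem.RWMol(parent)
            keep = set(self.core_atom_map)
            for pidx, aidx in enumerate(self.core_atom_map):
                edit.GetAtomWithIdx(aidx).SetAtomMapNum(pidx + 1)
            for atom in sorted(
                (a.GetIdx() for a in edit.GetAtoms() if a.GetIdx() not in keep),
                reverse=True,
            ):
                edit.RemoveAtom(atom)
            mol = edit.GetMol()
            try:
                Chem.SanitizeMol(mol)
            except Chem.KekulizeException:
                # an aromatic N that lost its substituent needs an explicit H
                for atom in mol.GetAtoms():
                    if (atom.GetIsAromatic() and atom.GetAtomicNum() == 7
                            and atom.GetTotalNumHs() == 0
                            and atom.GetDegree() == 2):
                        atom.SetNumExplicitHs(1)
                Chem.SanitizeMol(mol)
            object.__setattr__(self, "_core_mol", mol)
        return self._core_mol

    def moieties_at(self, position: int) -> tuple[Moiety, ...]:
        return tuple(m for m in self.moieties if m.position == position)

    @property
    def positions(self) -> set[int]:
        return {m.position for m in self.moieties}


@lru_cache(maxsize=8192)
def largest_common_substructure(
    a: str, b: str, params: CrossoverParams = CrossoverParams()
) -> CorePattern | None:
    """Maximum common connected substructure under element + bond-order
    matching; ``None`` if below ``min_core_atoms`` or on search timeout."""
    mols = [mol_from_smiles(a), mol_from_smiles(b)]
    result = rdFMCS.FindMCS(
        mols,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=params.ring_matches_ring_only,
        completeRingsOnly=params.complete_rings_only,
        timeout=max(1, int(round(params.timeout))),
    )
    if result.canceled:
        logger.info("MCS search timed out for %s vs %s", a, b)
    if not result.smartsString or result.numAtoms < params.min_core_atoms:
        return None
    return CorePattern(result.smartsString, result.numAtoms)


@lru_cache(maxsize=8192)
def decompose(smiles: str, core: CorePattern) -> DecoratedCore:
    """Cut every bond between a core atom and a non-core atom.

    Each connected non-core fragment must hang from exactly one core atom;
    otherwise (e.g. a ring threading in and out of the core) a
    :class:`DecompositionError` is raised.
    """
    mol = mol_from_smiles(smiles)
    query = core.query()
    match = mol.GetSubstructMatch(query)
    if not match:
        raise DecompositionError(f"core not found in {smiles}")
    core_atoms = set(match)
    pattern_of = {aidx: pidx for pidx, aidx in enumerate(match)}

    cut = []  # (core atom, non-core atom, bond type)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in core_atoms) != (j in core_atoms):
            ci, oj = (i, j) if i in core_atoms else (j, i)
            cut.append((ci, oj, bond.GetBondType()))

    # group non-core atoms into connected fragments
    if cut:
        edit = Chem.RWMol(mol)
        for ci, oj, _ in cut:
            edit.RemoveBond(ci, oj)
        frag_ids = Chem.GetMolFrags(edit.GetMol(), sanitizeFrags=False)
        frag_of = {}
        for fid, atoms in enumerate(frag_ids):
            for aidx in atoms:
                frag_of[aidx] = fid
        attachments: dict[int, list[tuple[int, int, Chem.BondType]]] = {}
        for ci, oj, bt in cut:
            attachments.setdefault(frag_of[oj], []).append((ci, oj, bt))
        moieties = []
        for fid, links in attachments.items():
            if len(links) > 1:
                raise DecompositionError(
                    f"moiety attached to the core at {len(links)} atoms in {smiles}"
                )
            ci, oj, bt = links[0]
            moieties.append(Moiety(
                position=pattern_of[ci],
                smiles=_moiety_smiles(mol, fid, frag_ids, oj, bt),
                bond_type=bt,
            ))
    else:
        moieties = []

    return DecoratedCore(
        parent_smiles=smiles,
        core=core,
        core_atom_map=tuple(match),
        moieties=tuple(sorted(moieties, key=lambda m: (m.position, m.smiles))),
    )


def _moiety_smiles(mol: Chem.Mol, fid: int, frag_ids, attach_atom: int,
                   bond_type: Chem.BondType) -> str:
    """Fragment SMILES with a dummy atom standing in for the core side."""
    edit = Chem.RWMol()
    old_to_new = {}
    for aidx in frag_ids[fid]:
        atom = mol.GetAtomWithIdx(aidx)
        new = Chem.Atom(atom.GetAtomicNum())
        new.SetFormalCharge(atom.GetFormalCharge())
        new.SetIsAromatic(atom.GetIsAromatic())
        old_to_new[aidx] = edit.AddAtom(new)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in old_to_new and j in old_to_new:
            edit.AddBond(old_to_new[i], old_to_new[j], bond.GetBondType())
    dummy = edit.AddAtom(Chem.Atom(0))
    edit.AddBond(old_to_new[attach_atom], dummy, bond_type)
    frag = edit.GetMol()
    Chem.SanitizeMol(frag, Chem.SanitizeFlags.SANITIZE_ALL
                     ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    return Chem.MolToSmiles(frag)


def reassemble(core: DecoratedCore,
               chosen: dict[int, tuple[Moiety, ...]]) -> str | None:
    """Attach the chosen moieties to the core instance; canonical SMILES of
    the result, or ``None`` if the assembly fails sanitization (e.g. valence
    overflow at an attachment point)."""
    try:
        mol = Chem.RWMol(core.core_mol())
        for position, moieties in chosen.items():
            core_idx = next(
                a.GetIdx() for a in mol.GetAtoms()
                if a.GetAtomMapNum() == position + 1
            )
            for moiety in moieties:
                frag = Chem.MolFromSmiles(moiety.smiles, sanitize=False)
                frag.UpdatePropertyCache(strict=False)
                offset = mol.GetNumAtoms()
                combined = Chem.RWMol(Chem.CombineMols(mol, frag))
                dummy_idx = next(
                    a.GetIdx() for a in combined.GetAtoms()
                    if a.GetAtomicNum() == 0 and a.GetIdx() >= offset
                )
                anchor = combined.GetAtomWithIdx(dummy_idx).GetNeighbors()[0].GetIdx()
                combined.RemoveAtom(dummy_idx)
                if anchor > dummy_idx:
                    anchor -= 1  # indices above the removed atom shift down
                catom = combined.GetAtomWithIdx(core_idx)
                if catom.GetNumExplicitHs() > 0:
                    catom.SetNumExplicitHs(catom.GetNumExplicitHs() - 1)
                combined.AddBond(core_idx, anchor, moiety.bond_type)
                mol = combined
        out = mol.GetMol()
        for atom in out.GetAtoms():
            atom.SetAtomMapNum(0)
        Chem.SanitizeMol(out)
        return canonicalize(Chem.MolToSmiles(out))
    except Exception:
        return None


def crossover(
    a: MoleculeRecord,
    b: MoleculeRecord,
    rng: np.random.Generator,
    params: CrossoverParams = CrossoverParams(),
    max_attempts: int = 10,
    child_id: str = "child",
    generation: int | None = None,
) -> MoleculeRecord | OperatorFailure:
    """Merge two parents on their largest common substructure.

    At each decorated core position the child takes the moiety set of parent
    ``a`` or parent ``b`` with equal probability (positions decorated by only
    one parent choose between that moiety set and nothing).  Invalid
    assemblies are resampled up to ``max_attempts`` times.
    """
    from .reactions import OperatorFailure

    core = largest_common_substructure(a.smiles, b.smiles, params)
    if core is None:
        return OperatorFailure("crossover", "no qualifying common core")
    try:
        deco_a = decompose(a.smiles, core)
        deco_b = decompose(b.smiles, core)
    except DecompositionError as exc:
        return OperatorFailure("crossover", str(exc))
    positions = sorted(deco_a.positions | deco_b.positions)
    gen = max(a.generation, b.generation) + 1 if generation is None else generation
    for _ in range(max_attempts):
        chosen: dict[int, tuple[Moiety, ...]] = {}
        for pos in positions:
            take_a = bool(rng.integers(2))
            chosen[pos] = deco_a.moieties_at(pos) if take_a else deco_b.moieties_at(pos)
        smiles = reassemble(deco_a, chosen)
        if smiles is not None:
            return MoleculeRecord(
                id=child_id, smiles=smiles, generation=gen,
                origin="crossover", parent_ids=(a.id, b.id),
            )
    return OperatorFailure("crossover", "all assemblies invalid")


# re-exported for engine convenience
from .reactions import OperatorFailure  # noqa: E402
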
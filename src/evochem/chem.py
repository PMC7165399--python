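"""Molecule records, SMILES I/O, descriptors, and lineage tracing.

All molecules inside a run are carried as canonical SMILES strings plus a
:class:`MoleculeRecord` that remembers where each compound came from
(generation, operator, parents).  The record ledger is the single source of
truth for provenance; compound ids stay short and the full ancestry is
recovered with :func:`trace_lineage`.
"""
from __future__ import annotations

import logging
from functools import lru_cache
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("evochem")

ORIGINS = ("seed", "elitism", "mutation", "crossover")

LEDGER_COLUMNS = (
    "id", "smiles", "generation", "origin", "parent_ids", "reaction_name",
    "primary_score", "diversity_score", "ligand_efficiency",
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


class LineageError(KeyError):
    """Raised when an id or parent reference cannot be resolved in a ledger."""


@dataclass
class MoleculeRecord:
    """One candidate ligand and its provenance.

    ``origin`` fixes the parent arity: seeds have no parents, elitism and
    mutation children have one, crossover children have two.  ``scores``
    holds named fitness values (primary docking-convention score, diversity
    score, ligand efficiency); lower is better for the primary score.
    """

    id: str
    smiles: str
    generation: int = 0
    origin: str = "seed"
    parent_ids: tuple[str, ...] = ()
    reaction_name: str | None = None
    scores: dict[str, float] = field(default_factory=dict)
    stereo_dropped: bool = False

    def __post_init__(self) -> None:
        self.parent_ids = tuple(self.parent_ids)
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        expected = {"seed": 0, "elitism": 1, "mutation": 1, "crossover": 2}
        if len(self.parent_ids) != expected[self.origin]:
            raise ValueError(
                f"origin={self.origin} requires {expected[self.origin]} "
                f"parent ids, got {len(self.parent_ids)}"
            )
        if (self.reaction_name is not None) != (self.origin == "mutation"):
            raise ValueError("reaction_name is set iff origin is mutation")

    def copy(self, **changes) -> "MoleculeRecord":
        return replace(self, scores=dict(self.scores), **changes)


@dataclass(frozen=True)
class DescriptorSet:
    """The physicochemical descriptors used by the drug-likeness filters.

    Hydrogen-bond donors/acceptors follow the Lipinski convention:
    HBD = number of O-H plus N-H bonds, HBA = number of N plus O atoms.
    logP and molar refractivity are Crippen atom-contribution estimates;
    psa is the topological polar surface area (A^2).
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    mr: float
    n_atoms: int
    heavy_atoms: int
    rotb: int
    rings: int
    n_count: int
    o_count: int
    x_count: int
    psa: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize, raising :class:`SmilesParseError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return the canonical form; a fixed point under re-canonicalization."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def largest_fragment(smiles: str) -> tuple[str, bool]:
    """Keep the fragment with the most heavy atoms (salt/counterion strip).

    Returns ``(canonical_smiles, was_multifragment)``.  Ties break toward
    the lexicographically smaller canonical SMILES so the choice is
    deterministic.
    """
    mol = mol_from_smiles(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) == 1:
        return Chem.MolToSmiles(mol), False
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    return Chem.MolToSmiles(best), True


@lru_cache(maxsize=65536)
def compute_descriptors(smiles: str) -> DescriptorSet:
    """Compute every filter descriptor for one molecule (deterministic, memoized)."""
    mol = mol_from_smiles(smiles)
    heavy = mol.GetNumHeavyAtoms()
    n_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    counts = {"N": 0, "O": 0, "X": 0}
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 7:
            counts["N"] += 1
        elif z == 8:
            counts["O"] += 1
        elif z in (9, 17, 35, 53):
            counts["X"] += 1
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NHOHCount(mol),
        hba=Lipinski.NOCount(mol),
        mr=Crippen.MolMR(mol),
        n_atoms=heavy + n_h,
        heavy_atoms=heavy,
        rotb=Lipinski.NumRotatableBonds(mol),
        rings=Descriptors.RingCount(mol),
        n_count=counts["N"],
        o_count=counts["O"],
        x_count=counts["X"],
        psa=Descriptors.TPSA(mol),
    )


def read_smi(
    path: str | Path,
    on_bad_line: str = "fail",
    origin: str = "seed",
) -> list[MoleculeRecord]:
    """Read an SMI file: one SMILES per line, optional whitespace-separated
    name, ``#`` comment lines ignored.  Multi-fragment entries keep their
    largest fragment (vendor salts).  ``on_bad_line`` is ``fail`` or ``skip``.
    """
    if on_bad_line not in ("skip", "fail"):
        raise ValueError("on_bad_line must be 'skip' or 'fail'")
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        smiles, name = tokens[0], (tokens[1] if len(tokens) > 1 else None)
        try:
            smi, multi = largest_fragment(smiles)
        except SmilesParseError as exc:
            if on_bad_line == "fail":
                raise SmilesParseError(f"{path} line {lineno}: {exc}") from exc
            n_skipped += 1
            logger.warning("skipping bad line %d of %s: %s", lineno, path, smiles)
            continue
        if multi:
            logger.info("kept largest fragment of multi-fragment input %r", smiles)
        records.append(MoleculeRecord(
            id=name if name is not None else f"seed_{lineno}",
            smiles=smi,
            origin=origin,
        ))
    if n_skipped:
        logger.warning("%d bad line(s) skipped in %s", n_skipped, path)
    return records


def write_smi(records: Iterable[MoleculeRecord], path: str | Path,
              scores: Iterable[str] = ()) -> None:
    """Write records as SMILES + id (+ optional score columns)."""
    score_names = tuple(scores)
    with open(path, "w") as fh:
        for rec in records:
            cols = [rec.smiles, rec.id]
            cols += [f"{rec.scores.get(s, float('nan')):.6g}" for s in score_names]
            fh.write("\t".join(cols) + "\n")


def write_ledger(records: Iterable[MoleculeRecord], path: str | Path) -> None:
    """Write the lineage ledger as TSV (stable column order)."""
    with open(path, "w") as fh:
        fh.write("\t".join(LEDGER_COLUMNS) + "\n")
        for rec in records:
            row = [
                rec.id, rec.smiles, str(rec.generation), rec.origin,
                ",".join(rec.parent_ids), rec.reaction_name or "",
                _fmt(rec.scores.get("primary")),
                _fmt(rec.scores.get("diversity")),
                _fmt(rec.scores.get("ligand_efficiency")),
            ]
            fh.write("\t".join(row) + "\n")


def read_ledger(path: str | Path) -> list[MoleculeRecord]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    records = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        scores = {}
        for name, col in (("primary", "primary_score"),
                          ("diversity", "diversity_score"),
                          ("ligand_efficiency", "ligand_efficiency")):
            if row.get(col):
                scores[name] = float(row[col])
        records.append(MoleculeRecord(
            id=row["id"], smiles=row["smiles"],
            generation=int(row["generation"]), origin=row["origin"],
            parent_ids=tuple(p for p in row["parent_ids"].split(",") if p),
            reaction_name=row["reaction_name"] or None,
            scores=scores,
        ))
    return records


def _fmt(value: float | None) -> str:
    return "" if value is None else f"{value:.6f}"


def trace_lineage(record_id: str,
                  ledger: Iterable[MoleculeRecord] | Mapping[str, MoleculeRecord],
                  ) -> dict:
    """Return the full ancestor tree of ``record_id`` down to the seeds.

    The tree is a nested dict ``{"id", "origin", "generation", "smiles",
    "reaction_name", "parents": [...]}``; every leaf is a generation-0 seed.
    """
    if not isinstance(ledger, Mapping):
        ledger = {rec.id: rec for rec in ledger}
    if record_id not in ledger:
        raise LineageError(f"unknown id {record_id!r}")

    def build(rid: str, seen: frozenset[str]) -> dict:
        if rid in seen:
            raise LineageError(f"lineage cycle at {rid!r}")
        rec = ledger.get(rid)
        if rec is None:
            raise LineageError(f"dangling parent reference {rid!r}")
        return {
            "id": rec.id,
            "smiles": rec.smiles,
            "generation": rec.generation,
            "origin": rec.origin,
            "reaction_name": rec.reaction_name,
            "parents": [build(p, seen | {rid}) for p in rec.parent_ids],
        }

    return build(record_id, frozenset())


def lineage_leaves(tree: dict) -> list[dict]:
    """All leaf nodes of a lineage tree (the founding seeds)."""
    if not tree["parents"]:
        return [tree]
    return [leaf for p in tree["parents"] for leaf in lineage_leaves(p)]
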
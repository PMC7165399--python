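"""Fitness machinery: primary score, ligand efficiency, and diversity.

The primary score follows the docking convention (kcal/mol-like units,
lower/more negative = better).  A deterministic surrogate scorer stands in
for a docking program at desk scale; external docking runs through the
adapter contract below.  Population diversity uses Morgan fingerprints with
the Dice coefficient

    s(F_A, F_B) = 2|F_A & F_B| / (|F_A| + |F_B|)

and each molecule's diversity score is the sum of its pairwise similarities
to the rest of its generation — the SMALLER the sum, the more structurally
unique the molecule.
"""
from __future__ import annotations

import logging
import math
from functools import lru_cache
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

from rdkit.Chem import rdFingerprintGenerator

from .chem import MoleculeRecord, compute_descriptors, mol_from_smiles

logger = logging.getLogger("evochem")

WORST_SCORE = math.inf  # sentinel for scoring failures (direction: min)


@dataclass(frozen=True)
class Fingerprint:
    """An unfolded circular-fingerprint bit set."""

    bits: frozenset[int]
    nbits: int
    radius: int

    def __post_init__(self):
        if self.bits and (min(self.bits) < 0 or max(self.bits) >= self.nbits):
            raise ValueError("bit index out of range")


@lru_cache(maxsize=65536)
def morgan_fingerprint(smiles: str, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Morgan (circular) fingerprint as a bit set; deterministic, memoized."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(bv.GetOnBits()), nbits=nbits, radius=radius)


def dice_similarity(fa: Fingerprint, fb: Fingerprint) -> float:
    """Dice coefficient of two fingerprints, in [0, 1].

    The degenerate 0/0 case (two empty fingerprints) is defined as 0.0.
    """
    if fa.nbits != fb.nbits:
        raise ValueError("fingerprints have different lengths")
    denom = len(fa.bits) + len(fb.bits)
    if denom == 0:
        logger.warning("Dice similarity of two empty fingerprints; defining as 0.0")
        return 0.0
    return 2.0 * len(fa.bits & fb.bits) / denom


def diversity_scores(fps: Sequence[Fingerprint]) -> list[float]:
    """d(M) = sum over N != M of s(F_M, F_N); order follows the input."""
    n = len(fps)
    out = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = dice_similarity(fps[i], fps[j])
            out[i] += s
            out[j] += s
    return out


def ligand_efficiency(primary_score: float, heavy_atoms: int) -> float:
    """Primary score divided by the non-hydrogen atom count."""
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return primary_score / heavy_atoms


def surrogate_score(desc) -> float:
    """Deterministic desk-scale stand-in for a docking score.

    score = -(0.1 * heavy_atoms + 1.0 * rings + 0.5 * (hbd + hba))

    This is a test double for exercising the GA loop, not a
    binding-affinity predictor.
    """
    return -(0.1 * desc.heavy_atoms + 1.0 * desc.rings + 0.5 * (desc.hbd + desc.hba))


def surrogate_scorer(smiles: str) -> float:
    return surrogate_score(compute_descriptors(smiles))


class FitnessScorer(Protocol):
    """The fitness contract: SMILES -> primary score; may raise per molecule."""

    def __call__(self, smiles: str) -> float: ...


def _not_implemented(name: str) -> Callable[[str], float]:
    def fn(smiles: str) -> float:
        raise NotImplementedError(
            f"{name} rescoring is a registry placeholder; supply an external "
            "docking/rescoring adapter instead"
        )
    return fn


SCORER_REGISTRY: dict[str, Callable[[str], float]] = {
    "surrogate": surrogate_scorer,
    "nnscore1": _not_implemented("NNScore1"),
    "nnscore2": _not_implemented("NNScore2"),
}


@dataclass(frozen=True)
class DockingBox:
    """Receptor-frame search box handed to an external docking adapter."""

    center: tuple[float, float, float]  # Angstrom
    size: tuple[float, float, float]    # Angstrom


@dataclass(frozen=True)
class DockingAdapterConfig:
    """Configuration for a Vina-compatible external docking adapter.

    The adapter receives a batch of (id, SMILES), the receptor file, the box
    and the exhaustiveness, and must return (id, top-pose score) pairs.  The
    adapter executable itself is outside this package; any program honoring
    the contract (PDBQT in/out, top-pose score extraction) can be plugged in.
    """

    receptor_path: str
    box: DockingBox
    exhaustiveness: int = 8
    executable: str | None = None


@dataclass
class ScoringOutcome:
    scored: list[MoleculeRecord]
    failures: list[tuple[MoleculeRecord, str]] = field(default_factory=list)


def score_population(
    records: Sequence[MoleculeRecord],
    scorer: Callable[[str], float],
    compute_ligand_efficiency: bool = True,
    radius: int = 2,
    nbits: int = 2048,
    variant_enumerator: Callable[[str], Sequence[str]] | None = None,
) -> ScoringOutcome:
    """Attach primary, diversity and ligand-efficiency scores to a population.

    Per-molecule scorer failures get the sentinel worst score and are
    reported separately (the engine drops them from seeding).  When a
    variant enumerator is given, every variant of a compound is scored and
    the best (minimum) score is kept, mirroring top-pose reduction.
    """
    scored: list[MoleculeRecord] = []
    failures: list[tuple[MoleculeRecord, str]] = []
    for rec in records:
        variants = [rec.smiles]
        if variant_enumerator is not None:
            variants = list(variant_enumerator(rec.smiles)) or [rec.smiles]
        best: float | None = None
        err = None
        for smi in variants:
            try:
                value = scorer(smi)
            except NotImplementedError:
                raise
            except Exception as exc:  # per-molecule failure is not fatal
                err = str(exc)
                continue
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise TypeError(
                    f"fitness contract violation: scorer returned {value!r}"
                )
            best = value if best is None else min(best, value)
        out = rec.copy()
        if best is None:
            out.scores["primary"] = WORST_SCORE
            failures.append((out, err or "scorer failed"))
            logger.warning("scoring failed for %s: %s", rec.id, err)
        else:
            out.scores["primary"] = float(best)
            if compute_ligand_efficiency:
                heavy = compute_descriptors(rec.smiles).heavy_atoms
                out.scores["ligand_efficiency"] = ligand_efficiency(best, heavy)
        scored.append(out)

    ok = [r for r in scored if r.scores["primary"] != WORST_SCORE]
    fps = [morgan_fingerprint(r.smiles, radius, nbits) for r in ok]
    for rec, d in zip(ok, diversity_scores(fps)):
        rec.scores["diversity"] = d
    return ScoringOutcome(scored=scored, failures=failures)
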
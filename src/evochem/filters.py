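"""Drug-likeness filtration: descriptor-bound filters and substructure alerts.

Nine filters are registered by default — Lipinski, Lipinski*, Ghose, Ghose*,
VandeWaterbeemd, Mozziconacci (descriptor bounds) and BRENK, NIH, PAINS
(substructure alert catalogs).  Filters chain with AND semantics and the
engine refills from the operators when too few candidates survive.

Boundary semantics: a bound written "<= x" or as a range passes at exact
equality; VandeWaterbeemd's "< 450" / "< 90" are strict as printed.
"""
from __future__ import annotations

import logging
import runpy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from rdkit import Chem

from .chem import DescriptorSet, MoleculeRecord, compute_descriptors, mol_from_smiles

logger = logging.getLogger("evochem")


class FilterConfigError(ValueError):
    """Unknown filter name, bad bound, or unparsable catalog pattern."""


@dataclass(frozen=True)
class Bound:
    descriptor: str
    lower: float | None = None
    upper: float | None = None
    strict: bool = False  # strict inequality at both ends, as printed "<"

    def violated(self, value: float) -> bool:
        if self.lower is not None:
            if value < self.lower or (self.strict and value == self.lower):
                return True
        if self.upper is not None:
            if value > self.upper or (self.strict and value == self.upper):
                return True
        return False


@dataclass(frozen=True)
class PropertyFilterSpec:
    """A named set of descriptor bounds with an allowed violation count."""

    name: str
    bounds: tuple[Bound, ...]
    max_violations: int = 0

    def __post_init__(self):
        names = set(DescriptorSet.__dataclass_fields__)
        for b in self.bounds:
            if b.descriptor not in names:
                raise FilterConfigError(f"unknown descriptor {b.descriptor!r}")
            if b.lower is not None and b.upper is not None and b.lower > b.upper:
                raise FilterConfigError(f"lower > upper for {b.descriptor!r}")


def evaluate_property_filter(
    desc: DescriptorSet, spec: PropertyFilterSpec
) -> tuple[bool, list[str]]:
    """Check each bound; pass iff the violation count is within the allowance.

    Violations are counted per bound (e.g. mw and logp out of range is two
    violations under Lipinski).
    """
    values = desc.as_dict()
    violations = []
    for bound in spec.bounds:
        if bound.descriptor not in values:
            raise FilterConfigError(f"descriptor {bound.descriptor!r} missing")
        if bound.violated(values[bound.descriptor]):
            violations.append(bound.descriptor)
    return len(violations) <= spec.max_violations, violations


@dataclass
class SubstructureCatalog:
    """A named list of SMARTS alert patterns; a hit rejects the molecule.

    Bundled BRENK/NIH/PAINS catalogs are served by RDKit's FilterCatalog;
    custom catalogs load from plain text files, one ``SMARTS label`` pair
    per line.
    """

    name: str
    patterns: list[tuple[str, str]] = field(default_factory=list)  # (smarts, label)
    _compiled: list[tuple[Chem.Mol, str]] = field(default_factory=list, repr=False)
    _rdkit_catalog: object = field(default=None, repr=False)

    BUILTIN = ("BRENK", "NIH", "PAINS")

    def __post_init__(self):
        if self._rdkit_catalog is None and not self.patterns and self.name in self.BUILTIN:
            from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams
            params = FilterCatalogParams()
            params.AddCatalog(getattr(FilterCatalogParams.FilterCatalogs, self.name))
            self._rdkit_catalog = FilterCatalog(params)
        for smarts, label in self.patterns:
            query = Chem.MolFromSmarts(smarts)
            if query is None:
                raise FilterConfigError(
                    f"catalog {self.name}: unparsable SMARTS {smarts!r} ({label})"
                )
            self._compiled.append((query, label))

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "SubstructureCatalog":
        patterns = []
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(None, 1)
            smarts = tokens[0]
            label = tokens[1].strip() if len(tokens) > 1 else smarts
            patterns.append((smarts, label))
        return cls(name=name, patterns=patterns)

    def matches(self, mol: Chem.Mol) -> list[str]:
        hits = [label for query, label in self._compiled if mol.HasSubstructMatch(query)]
        if self._rdkit_catalog is not None:
            hits += [m.filterMatch.GetName()
                     for m in self._rdkit_catalog.GetFilterMatches(mol)]
        return hits


def evaluate_substructure_filter(
    smiles: str, catalog: SubstructureCatalog
) -> tuple[bool, list[str]]:
    """Pass iff no alert pattern occurs as a substructure; list every hit."""
    matched = catalog.matches(mol_from_smiles(smiles))
    return not matched, matched


# --- Table-of-defaults registry ----------------------------------------------

_LIPINSKI_BOUNDS = (
    Bound("logp", upper=5.0),
    Bound("hbd", upper=5),
    Bound("hba", upper=10),
    Bound("mw", upper=500),
)
_GHOSE_BOUNDS = (
    Bound("logp", -0.4, 5.6),
    Bound("mw", 160, 480),
    Bound("mr", 40, 130),
    Bound("n_atoms", 20, 70),
)
_GHOSE_STAR_BOUNDS = (
    Bound("logp", -0.4, 5.6),
    Bound("mw", 160, 500),
    Bound("mr", 40, 130),
    Bound("n_atoms", 20, 70),
)

PROPERTY_FILTERS: dict[str, PropertyFilterSpec] = {
    "Lipinski": PropertyFilterSpec("Lipinski", _LIPINSKI_BOUNDS, max_violations=1),
    "Lipinski*": PropertyFilterSpec("Lipinski*", _LIPINSKI_BOUNDS, max_violations=0),
    "Ghose": PropertyFilterSpec("Ghose", _GHOSE_BOUNDS),
    "Ghose*": PropertyFilterSpec("Ghose*", _GHOSE_STAR_BOUNDS),
    "VandeWaterbeemd": PropertyFilterSpec(
        "VandeWaterbeemd",
        (Bound("mw", upper=450, strict=True), Bound("psa", upper=90, strict=True)),
    ),
    "Mozziconacci": PropertyFilterSpec(
        "Mozziconacci",
        (
            Bound("rotb", upper=15),
            Bound("rings", upper=6),
            Bound("n_count", lower=1),
            Bound("o_count", lower=1),
            Bound("x_count", upper=7),
        ),
    ),
}

SUBSTRUCTURE_CATALOG_NAMES = ("BRENK", "NIH", "PAINS")

FilterFn = Callable[[MoleculeRecord], bool]


class FilterRegistry:
    """Named filters addressable from run configs; extensible by users."""

    def __init__(self) -> None:
        self._filters: dict[str, FilterFn] = {}
        self._catalogs: dict[str, SubstructureCatalog] = {}
        for spec in PROPERTY_FILTERS.values():
            self._filters[spec.name] = _property_filter_fn(spec)
        for name in SUBSTRUCTURE_CATALOG_NAMES:
            self._filters[name] = self._catalog_fn(name)

    def _catalog_fn(self, name: str) -> FilterFn:
        def fn(record: MoleculeRecord) -> bool:
            if name not in self._catalogs:
                self._catalogs[name] = SubstructureCatalog(name)
            ok, _ = evaluate_substructure_filter(record.smiles, self._catalogs[name])
            return ok
        return fn

    def register(self, name: str, fn: FilterFn) -> None:
        self._filters[name] = fn

    def register_catalog(self, catalog: SubstructureCatalog) -> None:
        self._catalogs[catalog.name] = catalog
        self._filters[catalog.name] = lambda rec: evaluate_substructure_filter(
            rec.smiles, catalog)[0]

    def load_custom(self, path: str | Path) -> None:
        """Run a user python file; it receives this registry as REGISTRY."""
        runpy.run_path(str(path), init_globals={"REGISTRY": self})

    def names(self) -> list[str]:
        return sorted(self._filters)

    def get(self, name: str) -> FilterFn:
        try:
            return self._filters[name]
        except KeyError:
            raise FilterConfigError(f"unknown filter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._filters


def _property_filter_fn(spec: PropertyFilterSpec) -> FilterFn:
    def fn(record: MoleculeRecord) -> bool:
        ok, _ = evaluate_property_filter(compute_descriptors(record.smiles), spec)
        return ok
    return fn


DEFAULT_REGISTRY = FilterRegistry()


def apply_filter_chain(
    records: Sequence[MoleculeRecord],
    chain: Iterable[str],
    registry: FilterRegistry | None = None,
) -> tuple[list[MoleculeRecord], dict[str, int]]:
    """AND all filters in order; attribute each rejection to the first
    filter that failed.  Unknown names raise before any evaluation."""
    registry = registry or DEFAULT_REGISTRY
    chain = list(chain)
    fns = [(name, registry.get(name)) for name in chain]
    rejections = {name: 0 for name in chain}
    survivors = []
    for rec in records:
        for name, fn in fns:
            if not fn(rec):
                rejections[name] += 1
                break
        else:
            survivors.append(rec)
    return survivors, rejections
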
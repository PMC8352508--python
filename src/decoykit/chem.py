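"""Molecular graph data model and SMILES/SDF input-output.

The package works on heavy-atom graphs: atoms carry an element symbol, a
formal charge and an aromatic flag; bonds carry an order of 1, 2, 3 or
aromatic.  Hydrogens are implicit throughout — every count, fingerprint and
descriptor in the package is defined over heavy atoms only.

RDKit is the parsing/writing and sanitisation backend; :class:`Molecule` is a
thin immutable graph view of an RDKit mol that the generator can also build
incrementally without round-tripping through SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: symbolic bond order used for aromatic bonds (contributes 1.5 to valence)
AROMATIC = "ar"

_ORDER_VALUE = {1: 1.0, 2: 2.0, 3: 3.0, AROMATIC: 1.5}
_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}
_RD_BOND_INV = {v: k for k, v in _RD_BOND.items()}

#: elements whose counts are always reported (pair-matching criterion set)
MATCHED_ELEMENTS = ("C", "N", "O", "S", "Cl", "F")


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element symbol, formal charge and aromaticity flag.

    ``hs`` pins the hydrogen count for aromatic atoms where it is not
    implied by the ring bonds (e.g. pyrrole-type nitrogen); ``None`` means
    implicit.
    """

    element: str
    charge: int = 0
    aromatic: bool = False
    hs: int | None = None


@dataclass(frozen=True)
class Bond:
    """An undirected bond between atom indices ``i < j``."""

    i: int
    j: int
    order: object  # 1 | 2 | 3 | AROMATIC

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("self-bonds are not allowed")
        if self.order not in _ORDER_VALUE:
            raise ValueError(f"unknown bond order {self.order!r}")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    @property
    def value(self) -> float:
        """Bond-order contribution to valence (aromatic counts 1.5)."""
        return _ORDER_VALUE[self.order]


class Molecule:
    """Immutable heavy-atom molecular graph.

    Parameters
    ----------
    atoms : sequence of Atom
    bonds : sequence of Bond
        Endpoints must be distinct valid atom indices; duplicates rejected.
    name : str, optional
    """

    __slots__ = ("atoms", "bonds", "name", "_rdkit", "_canonical")

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[Bond] = (),
                 name: str = ""):
        atoms = tuple(atoms)
        seen = set()
        for b in bonds:
            if not (0 <= b.i < len(atoms) and 0 <= b.j < len(atoms)):
                raise ValueError(f"bond {b} references a missing atom")
            if (b.i, b.j) in seen:
                raise ValueError(f"duplicate bond {b.i}-{b.j}")
            seen.add((b.i, b.j))
        self.atoms = atoms
        self.bonds = tuple(bonds)
        self.name = name
        self._rdkit = None
        self._canonical = None

    # -- basic graph accessors -------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.i == idx:
                out.append(b.j)
            elif b.j == idx:
                out.append(b.i)
        return out

    def valence_used(self, idx: int) -> float:
        """Sum of bond-order values incident to atom ``idx``."""
        return sum(b.value for b in self.bonds if idx in (b.i, b.j))

    def is_connected(self) -> bool:
        if self.n_atoms <= 1:
            return True
        adj = {i: [] for i in range(self.n_atoms)}
        for b in self.bonds:
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_atoms

    # -- RDKit interop ----------------------------------------------------

    def to_rdkit(self) -> Chem.Mol:
        """Build and sanitise the corresponding RDKit mol (cached)."""
        if self._rdkit is None:
            rw = Chem.RWMol()
            for a in self.atoms:
                ra = Chem.Atom(a.element)
                ra.SetFormalCharge(a.charge)
                ra.SetIsAromatic(a.aromatic)
                if a.hs is not None:
                    ra.SetNumExplicitHs(a.hs)
                rw.AddAtom(ra)
            for b in self.bonds:
                rw.AddBond(b.i, b.j, _RD_BOND[b.order])
            mol = rw.GetMol()
            Chem.SanitizeMol(mol)
            if self.name:
                mol.SetProp("_Name", self.name)
            self._rdkit = mol
        return self._rdkit

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str | None = None) -> "Molecule":
        mol = Chem.RemoveHs(mol)
        atoms = [Atom(a.GetSymbol(), a.GetFormalCharge(), a.GetIsAromatic(),
                      a.GetTotalNumHs() if a.GetIsAromatic() else None)
                 for a in mol.GetAtoms()]
        bonds = [Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                      _RD_BOND_INV[b.GetBondType()]) for b in mol.GetBonds()]
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return cls(atoms, bonds, name)

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES: {smiles!r}")
        return cls.from_rdkit(mol, name=name)

    @property
    def canonical_smiles(self) -> str:
        if self._canonical is None:
            self._canonical = Chem.MolToSmiles(self.to_rdkit())
        return self._canonical

    def __eq__(self, other):
        return (isinstance(other, Molecule)
                and self.canonical_smiles == other.canonical_smiles)

    def __hash__(self):
        return hash(self.canonical_smiles)

    def __repr__(self):
        return f"Molecule({self.canonical_smiles!r}, n_atoms={self.n_atoms})"


@dataclass(frozen=True)
class ElementCounts:
    """Heavy-atom composition: total plus per-element counts.

    Counts for C, N, O, S, Cl and F are always present (zero allowed);
    other elements appear only when non-zero.
    """

    total: int
    counts: tuple  # sorted tuple of (element, count)

    @classmethod
    def from_dict(cls, d: dict[str, int], total: int | None = None):
        full = {el: 0 for el in MATCHED_ELEMENTS}
        full.update({k: v for k, v in d.items() if v or k in full})
        if any(v < 0 for v in full.values()):
            raise ValueError("negative element count")
        tot = total if total is not None else sum(full.values())
        if sum(full.values()) > tot:
            raise ValueError("per-element counts exceed total")
        return cls(tot, tuple(sorted(full.items())))

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def signature(self, elements: Iterable[str] = MATCHED_ELEMENTS) -> tuple:
        """Hashable key (total, counts over ``elements``) for bucketing."""
        return (self.total,) + tuple(self[e] for e in elements)


def element_counts(mol: Molecule) -> ElementCounts:
    """Heavy-atom composition of ``mol`` (hydrogens excluded)."""
    d: dict[str, int] = {}
    for a in mol.atoms:
        d[a.element] = d.get(a.element, 0) + 1
    return ElementCounts.from_dict(d, total=mol.n_atoms)


# ---------------------------------------------------------------------------
# Atom vocabulary and valence rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomType:
    element: str
    charge: int = 0

    def __str__(self):
        sign = "" if self.charge == 0 else f"{self.charge:+d}"
        return f"{self.element}{sign}"


class AtomVocabulary:
    """Ordered set of permitted (element, charge) atom types with valences.

    The vocabulary is the only chemical knowledge the generative model is
    given: which atom types may appear, and how many bond-order units each
    may carry.  It is configurable so rarer elements (e.g. phosphorus) can
    be admitted when a target's actives require them.
    """

    def __init__(self, types: Sequence[tuple[AtomType, float]]):
        if not types:
            raise ValueError("vocabulary must be non-empty")
        seen = set()
        for t, _ in types:
            if t in seen:
                raise ValueError(f"duplicate atom type {t}")
            seen.add(t)
        self.types = tuple(t for t, _ in types)
        self.max_valence = {t: v for t, v in types}

    def __contains__(self, t: AtomType) -> bool:
        return t in self.max_valence

    def __len__(self):
        return len(self.types)

    def index(self, t: AtomType) -> int:
        return self.types.index(t)

    def valence(self, t: AtomType) -> float:
        return self.max_valence[t]

    @classmethod
    def default(cls) -> "AtomVocabulary":
        """Standard neutral organic subset plus common charged forms."""
        return cls([
            (AtomType("C"), 4), (AtomType("N"), 3), (AtomType("N", 1), 4),
            (AtomType("N", -1), 2), (AtomType("O"), 2), (AtomType("O", -1), 1),
            (AtomType("F"), 1), (AtomType("S"), 6), (AtomType("Cl"), 1),
            (AtomType("Br"), 1), (AtomType("I"), 1),
        ])


def check_valence(mol: Molecule, vocab: AtomVocabulary | None = None
                  ) -> tuple[bool, list[str]]:
    """Check every atom against the vocabulary's valence limits.

    Returns ``(ok, violations)``; an atom type absent from the vocabulary is
    itself a violation, never an exception.
    """
    vocab = vocab or AtomVocabulary.default()
    violations = []
    for idx, a in enumerate(mol.atoms):
        t = AtomType(a.element, a.charge)
        if t not in vocab:
            violations.append(f"atom {idx}: type {t} not permitted")
            continue
        used = mol.valence_used(idx)
        if used > vocab.valence(t) + 1e-9:
            violations.append(
                f"atom {idx} ({t}): bond-order sum {used:g} exceeds "
                f"valence {vocab.valence(t):g}")
    return (not violations, violations)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

class ParseResult(list):
    """List of parsed molecules; ``errors`` holds (1-based record, message)."""

    def __init__(self, mols=(), errors=()):
        super().__init__(mols)
        self.errors = list(errors)

    @property
    def n_failed(self) -> int:
        return len(self.errors)


def _guess_format(path: str, fmt: str | None) -> str:
    if fmt:
        return fmt
    lower = str(path).lower()
    return "sdf" if lower.endswith(("sdf", "mol")) else "smi"


def parse_molecules(path, format: str | None = None) -> ParseResult:
    """Read molecules from a SMILES (one record per line, optional name) or
    SDF (V2000) file.

    Unparsable records are excluded and reported in ``result.errors`` with
    their 1-based record number; an unreadable file raises ``OSError``.
    """
    fmt = _guess_format(path, format)
    result = ParseResult()
    if fmt == "smi":
        with open(path) as fh:
            record = 0
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                record += 1
                parts = line.split(None, 1)
                smiles = parts[0]
                name = parts[1].strip() if len(parts) > 1 else ""
                try:
                    result.append(Molecule.from_smiles(smiles, name=name))
                except ValueError as exc:
                    result.errors.append((record, str(exc)))
                    logger.warning("record %d: %s", record, exc)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=True)
        for record, mol in enumerate(supplier, start=1):
            if mol is None:
                result.errors.append((record, "unparsable SDF record"))
                logger.warning("record %d: unparsable SDF record", record)
                continue
            result.append(Molecule.from_rdkit(mol))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return result


def write_molecules(mols: Iterable[Molecule], path, format: str | None = None
                    ) -> int:
    """Write molecules to a SMILES or SDF file; returns the record count."""
    fmt = _guess_format(path, format)
    mols = list(mols)
    if fmt == "smi":
        with open(path, "w") as fh:
            for m in mols:
                line = m.canonical_smiles
                if m.name:
                    line += f" {m.name}"
                fh.write(line + "\n")
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for m in mols:
            writer.write(m.to_rdkit())
        writer.close()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return len(mols)
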
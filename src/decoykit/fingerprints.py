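"""Circular fingerprints and Tanimoto similarity.

Two flavours are used throughout:

* ``morgan_r2_1024`` — standard Morgan/ECFP4-like fingerprint (radius 2,
  folded to 1024 bits), for the *structural* dissimilarity criterion in
  pair building.
* ``functional_fcfp6like`` — Morgan fingerprint over pharmacophoric feature
  invariants (donor/acceptor/aromatic/halogen/basic/acidic roles), radius 3
  (diameter 6, FCFP6-like), folded to 1024 bits, for doppelganger and LADS
  scoring where functional rather than elemental identity matters.

Hashing is RDKit's Morgan generator, fixed per flavour so bit patterns are
stable across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

from rdkit.Chem import rdFingerprintGenerator

from .chem import Molecule

logger = logging.getLogger(__name__)

MORGAN_FLAVOR = "morgan_r2_1024"
FUNCTIONAL_FLAVOR = "functional_fcfp6like"

_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
_functional_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=3, fpSize=1024,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen())


@dataclass(frozen=True)
class FingerprintBits:
    """Folded binary fingerprint as a sorted set of on-bit indices."""

    length: int
    bits: frozenset
    flavor: str

    def __post_init__(self):
        if self.bits and not all(0 <= b < self.length for b in self.bits):
            raise ValueError("bit index out of range")

    def __len__(self):
        return len(self.bits)


def morgan_fingerprint(mol: Molecule) -> FingerprintBits:
    """Radius-2 Morgan fingerprint folded to 1024 bits."""
    fp = _morgan_gen.GetFingerprint(mol.to_rdkit())
    return FingerprintBits(1024, frozenset(fp.GetOnBits()), MORGAN_FLAVOR)


def functional_fingerprint(mol: Molecule) -> FingerprintBits:
    """Radius-3 circular fingerprint over pharmacophoric atom roles."""
    fp = _functional_gen.GetFingerprint(mol.to_rdkit())
    return FingerprintBits(1024, frozenset(fp.GetOnBits()), FUNCTIONAL_FLAVOR)


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    """|a ∩ b| / |a ∪ b| over on-bit sets; both-empty is defined as 0."""
    if a.flavor != b.flavor or a.length != b.length:
        raise ValueError(
            f"fingerprint mismatch: {a.flavor}/{a.length} vs "
            f"{b.flavor}/{b.length}")
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints; defined as 0")
        return 0.0
    return len(a.bits & b.bits) / union
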
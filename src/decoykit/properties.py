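"""Physicochemical property sets, vectors and normalisation.

Decoy quality is judged in *property space*: each molecule is mapped to an
ordered vector of descriptors, the population is z-scored, and Euclidean
distance between the normalised vectors is the working metric everywhere
(pair building, greedy selection, DOE, AVE, ML bias).

Three registries are built in:

``dude6``
    molecular weight, logP, rotatable bonds, H-bond donors, H-bond
    acceptors, net formal charge — the classic six used to construct
    property-matched decoy benchmarks.
``dekois8``
    the six above with net charge replaced by separate positive/negative
    charge counts, plus aromatic ring count.
``extended27``
    a 27-descriptor superset (topological and physicochemical descriptors
    plus the synthetic accessibility score); user-overridable via a config
    file since the exact high-dimensional set is a user choice.

logP is Crippen's atom-contribution method (recorded in report metadata).
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass

import numpy as np
from rdkit.Chem import Crippen, Descriptors, Lipinski, RDConfig, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import Molecule

logger = logging.getLogger(__name__)

LOGP_METHOD = "crippen_atom_contribution"


# -- synthetic accessibility ------------------------------------------------

_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # noqa: bundled with RDKit
        _sascorer = sascorer
    return _sascorer


def sa_score(mol: Molecule) -> float:
    """Synthetic accessibility score in [1, 10] (1 easy, 10 hard).

    Fragment-contribution estimate of how difficult a molecule is to make;
    broadly a molecular-complexity measure, so it is also usable as a
    property to unbias (registered in ``extended27``).
    """
    score = _get_sascorer().calculateScore(mol.to_rdkit())
    return float(min(10.0, max(1.0, score)))


# -- descriptor registry ----------------------------------------------------

def _pos_charges(m):
    return float(sum(1 for a in m.GetAtoms() if a.GetFormalCharge() > 0))


def _neg_charges(m):
    return float(sum(1 for a in m.GetAtoms() if a.GetFormalCharge() < 0))


def _net_charge(m):
    return float(sum(a.GetFormalCharge() for a in m.GetAtoms()))


#: name -> function taking an RDKit mol
DESCRIPTORS = {
    "mol_weight": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "rotatable_bonds": rdMolDescriptors.CalcNumRotatableBonds,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "net_charge": _net_charge,
    "pos_charges": _pos_charges,
    "neg_charges": _neg_charges,
    "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings,
    "rings": rdMolDescriptors.CalcNumRings,
    "saturated_rings": rdMolDescriptors.CalcNumSaturatedRings,
    "aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "fraction_csp3": rdMolDescriptors.CalcFractionCSP3,
    "heavy_atoms": lambda m: float(m.GetNumHeavyAtoms()),
    "heteroatoms": rdMolDescriptors.CalcNumHeteroatoms,
    "amide_bonds": rdMolDescriptors.CalcNumAmideBonds,
    "spiro_atoms": rdMolDescriptors.CalcNumSpiroAtoms,
    "bridgehead_atoms": rdMolDescriptors.CalcNumBridgeheadAtoms,
    "mol_mr": Crippen.MolMR,
    "labute_asa": rdMolDescriptors.CalcLabuteASA,
    "chi0": Descriptors.Chi0,
    "chi1": Descriptors.Chi1,
    "kappa1": Descriptors.Kappa1,
    "kappa2": Descriptors.Kappa2,
    "hall_kier_alpha": Descriptors.HallKierAlpha,
    "sa_score": lambda m: None,  # dispatched specially below
}

_DUDE6 = ("mol_weight", "logp", "rotatable_bonds", "hbd", "hba", "net_charge")
_DEKOIS8 = ("mol_weight", "logp", "rotatable_bonds", "hbd", "hba",
            "pos_charges", "neg_charges", "aromatic_rings")
_EXTENDED27 = tuple(DESCRIPTORS)  # all 27, ordered as declared


@dataclass(frozen=True)
class PropertySet:
    """Named, ordered collection of descriptors defining the vector layout."""

    name: str
    property_names: tuple

    def __post_init__(self):
        if len(set(self.property_names)) != len(self.property_names):
            raise ValueError("duplicate property names")
        unknown = [p for p in self.property_names if p not in DESCRIPTORS]
        if unknown:
            raise ValueError(f"unknown descriptors: {unknown}")

    def __len__(self):
        return len(self.property_names)


_REGISTRY = {
    "dude6": PropertySet("dude6", _DUDE6),
    "dekois8": PropertySet("dekois8", _DEKOIS8),
    "extended27": PropertySet("extended27", _EXTENDED27),
}


def get_property_set(name: str) -> PropertySet:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown property set {name!r}; available: {sorted(_REGISTRY)}")


def load_property_set_config(path, name: str | None = None) -> PropertySet:
    """Build a PropertySet from a config file listing descriptor names.

    The file has one ``key = value`` or bare descriptor name per line;
    ``#`` starts a comment.  A ``name = ...`` line sets the set name.
    """
    props, set_name = [], name or os.path.splitext(os.path.basename(path))[0]
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" in line:
                key, val = (s.strip() for s in line.split("=", 1))
                if key == "name":
                    set_name = val
                    continue
                line = val if key == "property" else key
            props.append(line)
    return PropertySet(set_name, tuple(props))


@dataclass(frozen=True)
class PropertyVector:
    """Descriptor values for one molecule under a named PropertySet."""

    values: np.ndarray
    schema: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, float))

    @property
    def ok(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


def compute_properties(mol: Molecule, pset: PropertySet) -> PropertyVector:
    """Descriptor vector for ``mol`` in ``pset`` order; deterministic.

    A failing descriptor yields a non-finite entry; such vectors are flagged
    (``vector.ok`` False) and should be excluded downstream.
    """
    rd = mol.to_rdkit()
    vals = np.empty(len(pset))
    for k, pname in enumerate(pset.property_names):
        try:
            if pname == "sa_score":
                vals[k] = sa_score(mol)
            else:
                vals[k] = float(DESCRIPTORS[pname](rd))
        except Exception as exc:  # descriptor failure is data, not a crash
            logger.warning("descriptor %s failed on %s: %s",
                           pname, mol.canonical_smiles, exc)
            vals[k] = np.nan
    return PropertyVector(vals, pset.name)


def property_matrix(mols, pset: PropertySet) -> np.ndarray:
    """Stack descriptor vectors for many molecules into an (n, k) array."""
    return np.vstack([compute_properties(m, pset).values for m in mols])


class PropertyNormalizer(BaseEstimator, TransformerMixin):
    """Per-property z-scoring fitted on a stated reference population.

    Follows the scikit-learn transformer contract: ``fit`` learns the
    per-column location (mean) and scale (standard deviation) of the
    reference population, ``transform`` maps vectors to z-scores.  A
    zero-variance property gets its scale clamped to 1 and is flagged in
    ``degenerate_`` with a warning — it then contributes nothing to
    distances, which is the desired behaviour for a constant descriptor.

    Parameters
    ----------
    population : str
        Free-text description of the reference population (for provenance).
    """

    def __init__(self, population: str = "unspecified"):
        self.population = population

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need at least 2 property vectors to normalise")
        self.location_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        self.degenerate_ = scale <= 1e-12
        if self.degenerate_.any():
            logger.warning("zero-variance properties at columns %s; "
                           "scale clamped to 1",
                           np.flatnonzero(self.degenerate_).tolist())
        self.scale_ = np.where(self.degenerate_, 1.0, scale)
        return self

    def transform(self, X):
        X = np.asarray(X, float)
        return (X - self.location_) / self.scale_


def fit_normalization(vectors, population: str = "unspecified"
                      ) -> PropertyNormalizer:
    """Fit a :class:`PropertyNormalizer` on a list of PropertyVector."""
    schemas = {v.schema for v in vectors}
    if len(schemas) > 1:
        raise ValueError(f"mixed schemas: {schemas}")
    X = np.vstack([v.values for v in vectors])
    return PropertyNormalizer(population=population).fit(X)


def property_distance(a: PropertyVector, b: PropertyVector,
                      norm: PropertyNormalizer) -> float:
    """Euclidean distance between two property vectors after z-scoring."""
    if a.schema != b.schema:
        raise ValueError(f"schema mismatch: {a.schema} vs {b.schema}")
    za = norm.transform(a.values[None, :])[0]
    zb = norm.transform(b.values[None, :])[0]
    return float(np.linalg.norm(za - zb))


def write_property_table(mols, pset: PropertySet, path) -> None:
    """CSV: first column molecule name, then one column per property."""
    import pandas as pd

    rows = []
    for i, m in enumerate(mols):
        v = compute_properties(m, pset)
        rows.append([m.name or m.canonical_smiles, *v.values])
    df = pd.DataFrame(rows, columns=["molecule", *pset.property_names])
    df.to_csv(path, index=False)
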
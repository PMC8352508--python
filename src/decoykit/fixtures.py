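"""Deterministic synthetic inputs: random valid molecules and property
populations.

``make_library`` assembles connected, valence-valid heavy-atom graphs by
random tree growth with optional ring closures — no external library or
download is needed to exercise any part of the package.  The molecules are
chemically valid but not bioactive; they provide graph and descriptor
diversity only.

``make_separable_sets`` emits two synthetic property-vector populations
whose separation is controlled directly, driving the embedding-score limit
checks (separation 0: one common distribution; large separation: disjoint
clusters; ``spread=0`` degenerates each population to a single point).

A small curated list of well-known drug structures (public-domain SMILES)
is bundled for realistic descriptor values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import Atom, AtomType, AtomVocabulary, Bond, Molecule

# elements that may carry a double bond in generated fixtures
_DOUBLE_OK = {"C", "N", "O", "S"}


@dataclass
class FixtureSpec:
    """Recipe for a reproducible random molecule library."""

    n_molecules: int = 50
    atom_range: tuple = (4, 9)
    palette: tuple = ("C", "C", "C", "C", "N", "N", "O", "O", "S", "F", "Cl")
    seed: int = 0
    ring_prob: float = 0.3
    double_prob: float = 0.15

    def __post_init__(self):
        if self.atom_range[0] < 1 or self.atom_range[0] > self.atom_range[1]:
            raise ValueError("invalid atom_range")
        if not self.palette:
            raise ValueError("empty palette")


def _grow_molecule(spec: FixtureSpec, vocab: AtomVocabulary, rng, name=""):
    n = int(rng.integers(spec.atom_range[0], spec.atom_range[1] + 1))
    heavy = [e for e in spec.palette if vocab.valence(AtomType(e)) >= 2]
    first = rng.choice(heavy if n > 1 and heavy else list(spec.palette))
    elements = [str(first)]
    remaining = [vocab.valence(AtomType(elements[0]))]
    bonds = []
    for _ in range(1, n):
        anchors = [i for i, r in enumerate(remaining) if r >= 1]
        if not anchors:
            break
        j = int(rng.choice(anchors))
        el = str(rng.choice(list(spec.palette)))
        order = 1
        if (rng.random() < spec.double_prob and remaining[j] >= 2
                and el in _DOUBLE_OK and elements[j] in _DOUBLE_OK
                and vocab.valence(AtomType(el)) >= 2):
            order = 2
        i = len(elements)
        elements.append(el)
        remaining.append(vocab.valence(AtomType(el)) - order)
        remaining[j] -= order
        bonds.append(Bond(j, i, order))
    if len(elements) >= 4 and rng.random() < spec.ring_prob:
        open_atoms = [i for i, r in enumerate(remaining) if r >= 1]
        bonded = {(b.i, b.j) for b in bonds}
        pairs = [(a, b) for ai, a in enumerate(open_atoms)
                 for b in open_atoms[ai + 1:] if (a, b) not in bonded]
        if pairs:
            a, b = pairs[int(rng.integers(len(pairs)))]
            bonds.append(Bond(a, b, 1))
            remaining[a] -= 1
            remaining[b] -= 1
    return Molecule([Atom(e) for e in elements], bonds, name)


def make_library(spec: FixtureSpec) -> list[Molecule]:
    """Generate ``spec.n_molecules`` connected valence-valid molecules.

    Bit-reproducible under ``spec.seed``; molecules that fail RDKit
    sanitisation (rare) are regenerated deterministically.
    """
    vocab = AtomVocabulary.default()
    for el in spec.palette:
        if AtomType(el) not in vocab:
            raise ValueError(f"palette element {el} outside vocabulary")
    rng = np.random.default_rng(spec.seed)
    out = []
    while len(out) < spec.n_molecules:
        mol = _grow_molecule(spec, vocab, rng, name=f"fix{len(out)}")
        try:
            mol.to_rdkit()
        except Exception:
            continue
        out.append(mol)
    return out


def make_separable_sets(n_actives: int, n_decoys: int, k: int,
                        separation: float, seed: int = 0,
                        spread: float = 1.0):
    """Two synthetic property populations a Euclidean distance
    ``separation`` apart (between cluster centres).

    Returns ``(actives, decoys)`` as (n, k) arrays.  With ``spread=0`` each
    population collapses onto its centre, giving the exact co-location /
    complete-separation limit geometries.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    offset = np.full(k, separation / np.sqrt(k))
    actives = spread * rng.standard_normal((n_actives, k))
    decoys = spread * rng.standard_normal((n_decoys, k)) + offset
    return actives, decoys


#: well-known small-molecule drugs (public-domain structures)
DRUG_SMILES = (
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("CC(=O)Nc1ccc(O)cc1", "paracetamol"),
    ("CC(C)Cc1ccc(cc1)C(C)C(=O)O", "ibuprofen"),
    ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", "caffeine"),
    ("CN1CCC[C@H]1c1cccnc1", "nicotine"),
    ("COc1ccc2cc(ccc2c1)C(C)C(=O)O", "naproxen"),
    ("CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O", "warfarin"),
    ("Clc1ccccc1C1=NCC(=O)Nc2ccc(cc12)[N+](=O)[O-]", "clonazepam-core"),
    ("CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1", "atropine"),
    ("CNCC(O)c1ccc(O)c(O)c1", "adrenaline"),
    ("NCC(O)c1ccc(O)c(O)c1", "noradrenaline"),
    ("NCCc1ccc(O)c(O)c1", "dopamine"),
    ("NCCc1c[nH]c2ccc(O)cc12", "serotonin"),
    ("CC(N)Cc1ccccc1", "amphetamine"),
    ("CNC(C)Cc1ccccc1", "methamphetamine"),
    ("OCC(O)CO", "glycerol"),
    ("CC(=O)NCCc1c[nH]c2ccc(OC)cc12", "melatonin"),
    ("OC(=O)CCc1ccccc1", "hydrocinnamic-acid"),
    ("NC(Cc1ccccc1)C(=O)O", "phenylalanine"),
    ("NC(Cc1ccc(O)cc1)C(=O)O", "tyrosine"),
    ("NC(Cc1c[nH]c2ccccc12)C(=O)O", "tryptophan"),
    ("CSCCC(N)C(=O)O", "methionine"),
    ("NC(CS)C(=O)O", "cysteine"),
    ("NC(CO)C(=O)O", "serine"),
    ("CC(O)C(N)C(=O)O", "threonine"),
    ("NC(CCC(=O)O)C(=O)O", "glutamate"),
    ("NC(CC(=O)O)C(=O)O", "aspartate"),
    ("NC(=O)c1ccncc1", "isonicotinamide"),
    ("NC(=O)c1cccnc1", "nicotinamide"),
    ("OC(=O)c1cccnc1", "niacin"),
    ("Clc1ccc(cc1)C(c1ccccc1)N1CCN(CCOCCO)CC1", "hydroxyzine-like"),
    ("CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc12", "chlorpromazine"),
    ("CN(C)CCC=C1c2ccccc2CCc2ccccc12", "amitriptyline"),
    ("CNCCC=C1c2ccccc2CCc2ccccc12", "nortriptyline"),
    ("CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1", "fluoxetine"),
    ("CN(C)CCOC(c1ccccc1)c1ccccc1", "diphenhydramine"),
    ("OCCN1CCN(CCCN2c3ccccc3Sc3ccc(Cl)cc23)CC1", "perphenazine-core"),
    ("Oc1ccc2CC3N(C)CCC4(CCCCC34)c2c1", "morphinan-like"),
    ("COc1ccc2cc3[nH]c4cc5OCOc5cc4c3cc2c1", "alkaloid-scaffold"),
    ("Clc1ccccc1-c1nc2ccccc2[nH]1", "clemizole-core"),
    ("Oc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O", "quercetin"),
    ("Oc1cc(O)c2c(c1)oc(-c1ccc(O)cc1)cc2=O", "apigenin"),
    ("COc1cc(ccc1O)C=CC(=O)O", "ferulic-acid"),
    ("Oc1ccc(cc1)C=CC(=O)O", "coumaric-acid"),
    ("Oc1ccc(cc1O)C=CC(=O)O", "caffeic-acid"),
    ("OC(=O)c1ccccc1O", "salicylic-acid"),
    ("OC(=O)c1ccccc1", "benzoic-acid"),
    ("OC(=O)c1ccc(O)cc1", "4-hydroxybenzoic-acid"),
    ("COC(=O)c1ccccc1O", "methyl-salicylate"),
    ("CC(C)NCC(O)COc1ccc2ccccc2c1", "propranolol"),
    ("CC(C)NCC(O)COc1ccc(CC(N)=O)cc1", "atenolol"),
    ("CC(C)NCC(O)COc1ccc(COCCOC(C)C)cc1", "bisoprolol"),
    ("COCCc1ccc(OCC(O)CNC(C)C)cc1", "metoprolol"),
    ("CC(N)Cc1ccc2OCOc2c1", "mda"),
    ("CNC(C)Cc1ccc2OCOc2c1", "mdma"),
    ("NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O", "hydrochlorothiazide"),
    ("NS(=O)(=O)c1cc(ccc1Cl)C1=NCCN1", "sulfa-imidazoline"),
    ("CC1=CC(=O)N(N1C)c1ccccc1", "antipyrine-like"),
    ("CCN(CC)CCNC(=O)c1ccc(N)cc1", "procainamide"),
    ("CCN(CC)CC(=O)Nc1c(C)cccc1C", "lidocaine"),
    ("COc1ccc(N)cc1C(=O)OCCN(CC)CC", "benzocaine-like"),
    ("Cc1ccc(cc1)S(=O)(=O)NC(=O)NN1CCCCCC1", "tolazamide-like"),
    ("CC(=O)Nc1ccc(cc1)S(N)(=O)=O", "sulfacetamide-like"),
    ("Nc1ccc(cc1)S(=O)(=O)Nc1ncccn1", "sulfadiazine"),
    ("Nc1ccc(cc1)S(N)(=O)=O", "sulfanilamide"),
    ("CN1CCN(CC1)c1cc2N(C=C(C(=O)O)C(=O)c2cc1F)C1CC1", "ciprofloxacin"),
    ("CCn1cc(C(=O)O)c(=O)c2ccc(C)nc12", "nalidixic-acid"),
    ("Clc1ccc2Oc3ccccc3N(CCCN3CCN(C)CC3)c2c1", "clozapine-like"),
    ("OC(=O)COc1ccccc1", "phenoxyacetic-acid"),
    ("Clc1ccc(OCC(=O)O)cc1", "chlorophenoxyacetic-acid"),
    ("CC(Oc1ccc(Cl)cc1)C(=O)O", "chlorophenoxypropionic-acid"),
    ("NC1CCCCC1", "cyclohexylamine"),
    ("OC1CCCCC1", "cyclohexanol"),
    ("O=C1CCCCC1", "cyclohexanone"),
    ("c1ccc2[nH]ccc2c1", "indole"),
    ("c1ccc2ncccc2c1", "quinoline"),
    ("c1ccc2[nH]cnc2c1", "benzimidazole"),
    ("c1ccc2occc2c1", "benzofuran"),
    ("c1ccc2sccc2c1", "benzothiophene"),
    ("c1ccc2c(c1)cccc2O", "naphthol"),
    ("Cc1ccccc1", "toluene"),
    ("Oc1ccccc1", "phenol"),
    ("Nc1ccccc1", "aniline"),
    ("COc1ccccc1", "anisole"),
    ("Clc1ccccc1", "chlorobenzene"),
    ("Fc1ccccc1", "fluorobenzene"),
    ("CC(C)(C)c1ccc(O)cc1", "tert-butylphenol"),
    ("CCOC(=O)c1ccccc1", "ethyl-benzoate"),
    ("CC(=O)c1ccccc1", "acetophenone"),
    ("O=Cc1ccccc1", "benzaldehyde"),
    ("OCc1ccccc1", "benzyl-alcohol"),
    ("NCc1ccccc1", "benzylamine"),
    ("N#Cc1ccccc1", "benzonitrile"),
    ("OC(=O)C=Cc1ccccc1", "cinnamic-acid"),
    ("CC(C)=CCCC(C)=CCO", "geraniol"),
    ("CC1=CCC(CC1)C(C)C", "limonene-like"),
    ("CC(C)C1CCC(C)CC1O", "menthol"),
    ("CC(=O)OCC(COC(C)=O)OC(C)=O", "triacetin"),
    ("OCC1OC(O)C(O)C(O)C1O", "glucose"),
    ("OC(=O)C(O)C(O)C(=O)O", "tartaric-acid"),
    ("OC(=O)CC(O)(CC(=O)O)C(=O)O", "citric-acid"),
    ("OC(=O)C=CC(=O)O", "fumaric-acid"),
    ("OC(=O)CCC(=O)O", "succinic-acid"),
    ("CC(O)C(=O)O", "lactic-acid"),
    ("CCCCCCCCCCCCCCCC(=O)O", "palmitic-acid"),
    ("CCCCCCCCC=CCCCCCCCC(=O)O", "oleic-acid"),
    ("CN1CCN(CC1)c1ccc(cc1)-c1ccccc1", "phenylpiperazine-biaryl"),
    ("O=C(Nc1ccccc1)c1ccccc1", "benzanilide"),
    ("O=C(Cc1ccccc1)Nc1ccccc1", "phenylacetanilide"),
    ("CN(C)c1ccc(cc1)C=Cc1ccccc1", "stilbene-amine"),
    ("COc1cc(C=CC(=O)CC(=O)C=Cc2ccc(O)c(OC)c2)ccc1O", "curcumin"),
    ("Oc1ccc(cc1)-c1ccc(O)cc1", "biphenol"),
    ("Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1", "resveratrol"),
)


def bundled_drug_molecules() -> list[Molecule]:
    """Parse the bundled drug-like SMILES list into molecules."""
    return [Molecule.from_smiles(s, name=n) for s, n in DRUG_SMILES]
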
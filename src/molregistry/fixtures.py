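"""Deterministic test-molecule and conformer generators.

Everything the test suite needs — identity-relevant molecule pairs,
random molecule corpora, random conformer coordinates, rigid
transforms, and pathological mol blocks — is produced here as a pure
function of explicit seeds, so the suite runs with no external data.

The curated pairs exercise the identity semantics of the layered hash:
tautomer pairs share the tautomer layers, stereoisomer pairs share the
stereo-free layers, and salt/neutral pairs share a charge parent.

Random conformers are points in a box, not chemically embedded
geometries: the coordinate-hash contract depends only on coordinates.
A handful of chemically valid 3D structures for end-to-end tests come
from RDKit's distance-geometry embedding with fixed seeds.
"""

from __future__ import annotations

import random
from typing import List, Optional, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .conformer_hash import ConformerCoordinates

__all__ = [
    "tautomer_pairs",
    "stereo_pairs",
    "salt_forms",
    "random_molecules",
    "equivalent_smiles",
    "random_conformers",
    "rigid_transform",
    "perturb",
    "grid_snap",
    "boundary_safe",
    "pathological_molblocks",
    "embedded_3d_molblock",
    "write_fixture_files",
]


def tautomer_pairs() -> List[Tuple[str, str]]:
    """SMILES pairs that are tautomers of each other."""
    return [
        ("O=c1cccc[nH]1", "Oc1ccccn1"),          # 2-pyridone / 2-hydroxypyridine
        ("CC(=O)CC(C)=O", "CC(=O)/C=C(\\C)O"),   # acetylacetone keto / enol
        ("O=C1CCCCC1", "OC1=CCCCC1"),            # cyclohexanone keto / enol
        ("CC(C)=N", "CC(N)=C"),                  # imine / enamine
    ]


def stereo_pairs() -> List[Tuple[str, str]]:
    """SMILES pairs differing only in stereochemistry."""
    return [
        ("C/C=C/C", "C/C=C\\C"),                          # E/Z-2-butene
        ("C[C@H](N)C(=O)O", "C[C@@H](N)C(=O)O"),          # D/L-alanine
        ("C[C@H](O)CC", "C[C@@H](O)CC"),                  # butan-2-ol enantiomers
        ("O[C@H]1CC[C@H](O)CC1", "O[C@H]1CC[C@@H](O)CC1"),  # cis/trans diol
    ]


def salt_forms() -> List[Tuple[str, str]]:
    """(salt form, neutral parent) SMILES pairs sharing a charge parent."""
    return [
        ("CC(=O)[O-].[Na+]", "CC(=O)O"),          # sodium acetate / acetic acid
        ("C[NH3+].[Cl-]", "CN"),                  # methylammonium chloride
        ("[Na+].[O-]c1ccccc1", "Oc1ccccc1"),      # sodium phenolate / phenol
        ("CCN(CC)CC.Cl", "CCN(CC)CC"),            # triethylamine hydrochloride
    ]


# ---------------------------------------------------------------------------
# random molecules

_ATOM_POOL = ("C", "C", "C", "C", "N", "O", "O", "S")
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}


def _random_tree_molecule(rng: random.Random, max_heavy: int) -> Optional[Chem.Mol]:
    n = rng.randint(4, max_heavy)
    mol = Chem.RWMol()
    symbols = []
    remaining = []
    for i in range(n):
        sym = rng.choice(_ATOM_POOL)
        mol.AddAtom(Chem.Atom(sym))
        symbols.append(sym)
        remaining.append(_MAX_VALENCE[sym])
        if i > 0:
            candidates = [j for j in range(i) if remaining[j] >= 1]
            if not candidates:
                return None
            j = rng.choice(candidates)
            mol.AddBond(j, i, Chem.BondType.SINGLE)
            remaining[j] -= 1
            remaining[i] -= 1
    # occasionally add a carbonyl for chemical variety
    if rng.random() < 0.5:
        carbons = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and remaining[a.GetIdx()] >= 2
        ]
        if carbons:
            c = rng.choice(carbons)
            o = mol.AddAtom(Chem.Atom("O"))
            mol.AddBond(c, o, Chem.BondType.DOUBLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def random_molecules(n: int, seed: int, max_heavy: int = 10) -> List[str]:
    """``n`` distinct random molecules as canonical SMILES.

    Molecules are random acyclic C/N/O/S skeletons with occasional
    carbonyls — chemically valid, structurally varied, reproducible.
    """
    rng = random.Random(seed)
    seen = set()
    out: List[str] = []
    while len(out) < n:
        mol = _random_tree_molecule(rng, max_heavy)
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    return out


def equivalent_smiles(smiles: str, rng: random.Random) -> str:
    """A different but chemically equivalent SMILES serialization.

    Atoms are renumbered with a random permutation and written without
    canonicalization, so the text differs (for nearly all molecules)
    while the molecular graph is identical.
    """
    mol = Chem.MolFromSmiles(smiles)
    alt = smiles
    for _ in range(10):
        order = list(range(mol.GetNumAtoms()))
        rng.shuffle(order)
        shuffled = Chem.RenumberAtoms(mol, order)
        alt = Chem.MolToSmiles(shuffled, canonical=False)
        if alt != smiles:
            break
    return alt


# ---------------------------------------------------------------------------
# conformers


def random_conformers(
    n: int,
    max_atoms: int = 30,
    seed: int = 0,
    digits: int = 3,
    box: float = 8.0,
) -> List[ConformerCoordinates]:
    """Random point-cloud conformers in a cube of half-width ``box`` Å."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        n_atoms = int(rng.integers(2, max_atoms + 1))
        pos = rng.uniform(-box, box, size=(n_atoms, 3))
        out.append(ConformerCoordinates.from_array(pos, digits=digits))
    return out


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # uniform random rotation from a normalized quaternion
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def rigid_transform(coords: ConformerCoordinates, seed: int) -> ConformerCoordinates:
    """Apply a random rotation + translation (an isometry) to a conformer."""
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    shift = rng.uniform(-5.0, 5.0, size=3)
    return ConformerCoordinates.from_array(
        coords.as_array() @ rot.T + shift, digits=coords.digits
    )


def perturb(
    coords: ConformerCoordinates, epsilon: float, seed: int
) -> ConformerCoordinates:
    """Displace every coordinate by a uniform amount in (-epsilon, epsilon)."""
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    if epsilon == 0:
        return coords
    rng = np.random.default_rng(seed)
    noise = rng.uniform(-epsilon, epsilon, size=(len(coords.positions), 3))
    return ConformerCoordinates.from_array(
        coords.as_array() + noise, digits=coords.digits
    )


def grid_snap(coords: ConformerCoordinates) -> ConformerCoordinates:
    """Snap every coordinate onto the rounding grid (10^-digits Å).

    Grid points sit at maximal distance (half a grid cell) from every
    rounding boundary, so sub-half-cell perturbations of a snapped
    conformer never change its hash.
    """
    scale = 10.0**coords.digits
    snapped = np.round(coords.as_array() * scale) / scale
    return ConformerCoordinates.from_array(snapped, digits=coords.digits)


def boundary_safe(coords: ConformerCoordinates, margin: float = 0.1) -> bool:
    """True when no coordinate lies near a rounding boundary.

    ``margin`` is in grid units (fractions of 10^-digits Å): a
    coordinate is unsafe when its fractional grid position is within
    ``margin`` of the half-integer rounding boundary. Numerical noise
    from a rigid transform (~1e-12 Å) then cannot flip any rounding.
    """
    scaled = coords.as_array() * (10.0**coords.digits)
    frac = scaled - np.floor(scaled)
    return bool((np.abs(frac - 0.5) >= margin).all())


# ---------------------------------------------------------------------------
# pathological and chemically valid mol blocks

_OVERLAPPING_MOLBLOCK = """overlapping atoms
  fixture

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
M  END
"""

_SRU_POLYMER_MOLBLOCK = """sru polymer
  fixture

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  STY  1   1 SRU
M  SAL   1  2   1   2
M  SMT   1 n
M  SCN  1   1 HT
M  END
"""

_DAT_SGROUP_MOLBLOCK = """dat sgroup
  fixture

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  STY  1   1 DAT
M  SAL   1  1   3
M  SDT   1 pH
M  SDD   1     0.0000    0.0000    DR    ALL  0       0
M  SED   1 7.4
M  END
"""

_PENTAVALENT_MOLBLOCK = """pentavalent carbon
  fixture

  6  5  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.0000    1.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
  1  6  1  0
M  END
"""


def pathological_molblocks() -> List[Tuple[str, str]]:
    """Labelled mol blocks that standardization filters must reject.

    Includes a zero-distance atom pair (overlap filter), an SRU polymer
    SGroup (polymer filter), a DAT-only SGroup (must *pass* the polymer
    filter), and a pentavalent carbon (sanitization failure).
    """
    return [
        ("overlapping_atoms", _OVERLAPPING_MOLBLOCK),
        ("sru_polymer", _SRU_POLYMER_MOLBLOCK),
        ("dat_sgroup", _DAT_SGROUP_MOLBLOCK),
        ("pentavalent_carbon", _PENTAVALENT_MOLBLOCK),
    ]


def embedded_3d_molblock(smiles: str, seed: int = 42) -> str:
    """A chemically valid 3D mol block via distance-geometry embedding."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"could not embed {smiles!r}")
    return Chem.MolToMolBlock(mol)


def write_fixture_files(directory: str, n_random: int = 20, seed: int = 7) -> List[str]:
    """Emit the fixture corpus as SMILES/SDF files; returns the paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    smi_path = os.path.join(directory, "random_molecules.smi")
    with open(smi_path, "w") as fh:
        for smi in random_molecules(n_random, seed=seed):
            fh.write(smi + "\n")
    paths.append(smi_path)
    sdf_path = os.path.join(directory, "embedded_3d.sdf")
    with open(sdf_path, "w") as fh:
        for smi in ("CCO", "CC(=O)O", "c1ccccc1"):
            fh.write(embedded_3d_molblock(smi, seed=seed))
            fh.write("$$$$\n")
    paths.append(sdf_path)
    return paths
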
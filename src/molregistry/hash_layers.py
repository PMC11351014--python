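"""Layered structural hashes defining 2D molecular identity.

A molecule's registration identity is a tuple of seven text layers:

``FORMULA``
    Molecular formula in Hill order.
``CANONICAL_SMILES``
    Canonical CXSMILES, including stereochemistry and enhanced
    (AND/OR/absolute group) stereochemistry.
``TAUTOMER_HASH``
    Tautomer-invariant serialization (heteroatom tautomer hash, v1 or
    v2), still carrying stereochemistry.
``NO_STEREO_SMILES``
    Canonical CXSMILES after removing all stereochemistry.
``NO_STEREO_TAUTOMER_HASH``
    Tautomer-invariant serialization after removing all stereochemistry.
``SGROUP_DATA``
    Canonical JSON of selected DAT-SGroup field/value data; ``"{}"``
    when the molecule carries none.
``ESCAPE``
    Free-form caller-supplied discriminator, empty by default. Two
    submissions of the same structure with different escape texts are
    deliberately distinct.

Two molecules are duplicates exactly when all seven layers agree; the
layers are combined into a single SHA1 digest so the comparison is one
string equality. Subsets of layers express looser identities, e.g.
``{NO_STEREO_SMILES}`` unites stereoisomers and ``{TAUTOMER_HASH}``
unites tautomers.

The byte serialization fed to SHA1 is ``"LAYERNAME:value"`` items joined
by a single newline, in the fixed layer order above, UTF-8 encoded.
Digests produced here are therefore well-defined and stable, but are not
interchangeable with other layered-hash implementations that combine
their layers differently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Set

from rdkit import Chem
from rdkit.Chem import rdMolHash

__all__ = [
    "LAYER_ORDER",
    "FORMULA",
    "CANONICAL_SMILES",
    "TAUTOMER_HASH",
    "NO_STEREO_SMILES",
    "NO_STEREO_TAUTOMER_HASH",
    "SGROUP_DATA",
    "ESCAPE",
    "HashOptions",
    "MolHashLayers",
    "HashingError",
    "compute_layers",
    "canonicalize_sgroup_data",
    "combine_layers",
    "match_layers",
]

FORMULA = "FORMULA"
CANONICAL_SMILES = "CANONICAL_SMILES"
TAUTOMER_HASH = "TAUTOMER_HASH"
NO_STEREO_SMILES = "NO_STEREO_SMILES"
NO_STEREO_TAUTOMER_HASH = "NO_STEREO_TAUTOMER_HASH"
SGROUP_DATA = "SGROUP_DATA"
ESCAPE = "ESCAPE"

#: Fixed combination order; constant for the lifetime of a database.
LAYER_ORDER: tuple = (
    FORMULA,
    CANONICAL_SMILES,
    TAUTOMER_HASH,
    NO_STEREO_SMILES,
    NO_STEREO_TAUTOMER_HASH,
    SGROUP_DATA,
    ESCAPE,
)

# CXSMILES extensions that carry identity: atom labels, enhanced stereo
# groups, and atropisomer bonds. Coordinates are deliberately excluded —
# 2D identity must not depend on the depiction.
_CX_IDENTITY_FIELDS = (
    Chem.CXSmilesFields.CX_ATOM_LABELS
    | Chem.CXSmilesFields.CX_ENHANCEDSTEREO
    | Chem.CXSmilesFields.CX_BOND_ATROPISOMER
)


class HashingError(RuntimeError):
    """A layer could not be serialized for a molecule.

    Carries the name of the failing layer in :attr:`layer`.
    """

    def __init__(self, layer: str, message: str):
        super().__init__(f"{layer}: {message}")
        self.layer = layer


@dataclass(frozen=True)
class HashOptions:
    """Registration-hash policy.

    Parameters
    ----------
    tautomer_hash_version:
        ``"v1"`` or ``"v2"``; selects the heteroatom-tautomer hash
        variant used for the two tautomer layers. v2 is the default.
    sgroup_fields:
        DAT-SGroup field names included in the SGROUP_DATA layer;
        ``None`` means every DAT field present on the molecule.
    """

    tautomer_hash_version: str = "v2"
    sgroup_fields: Optional[Sequence[str]] = None
    layer_order: Sequence[str] = LAYER_ORDER

    def __post_init__(self):
        if self.tautomer_hash_version not in ("v1", "v2"):
            raise ValueError(
                f"tautomer_hash_version must be 'v1' or 'v2', got "
                f"{self.tautomer_hash_version!r}"
            )
        if tuple(self.layer_order) != LAYER_ORDER:
            raise ValueError("layer_order is fixed and cannot be changed")


DEFAULT_OPTIONS = HashOptions()


@dataclass(frozen=True)
class MolHashLayers:
    """The seven identity layers of one molecule.

    All fields are always present; ``sgroup_data`` is ``"{}"`` and
    ``escape`` is ``""`` when there is nothing to record.
    """

    formula: str
    canonical_smiles: str
    tautomer_hash: str
    no_stereo_smiles: str
    no_stereo_tautomer_hash: str
    sgroup_data: str = "{}"
    escape: str = ""

    def as_dict(self) -> dict:
        return {
            FORMULA: self.formula,
            CANONICAL_SMILES: self.canonical_smiles,
            TAUTOMER_HASH: self.tautomer_hash,
            NO_STEREO_SMILES: self.no_stereo_smiles,
            NO_STEREO_TAUTOMER_HASH: self.no_stereo_tautomer_hash,
            SGROUP_DATA: self.sgroup_data,
            ESCAPE: self.escape,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "MolHashLayers":
        return cls(
            formula=d[FORMULA],
            canonical_smiles=d[CANONICAL_SMILES],
            tautomer_hash=d[TAUTOMER_HASH],
            no_stereo_smiles=d[NO_STEREO_SMILES],
            no_stereo_tautomer_hash=d[NO_STEREO_TAUTOMER_HASH],
            sgroup_data=d[SGROUP_DATA],
            escape=d[ESCAPE],
        )


def _prepare(mol: Chem.Mol) -> Chem.Mol:
    """Normalize a molecule for hashing without touching the caller's copy.

    Removes hydrogens that carry no information (keeping stereogenic
    ones and isotopes), strips atom-map numbers, and canonicalizes
    enhanced stereo groups so equivalent inputs hash identically.
    """
    params = Chem.RemoveHsParameters()
    params.updateExplicitCount = True
    params.removeDefiningBondStereo = False
    work = Chem.RemoveHs(Chem.Mol(mol), params, sanitize=False)
    work.UpdatePropertyCache(False)
    for atom in work.GetAtoms():
        if atom.HasProp("molAtomMapNumber"):
            atom.ClearProp("molAtomMapNumber")
    Chem.CanonicalizeEnhancedStereo(work)
    return work


def _canonical_rebuild(mol: Chem.Mol) -> Chem.Mol:
    """Round-trip through canonical CXSMILES to normalize atom/bond order.

    The delegated tautomer hash is sensitive to atom and bond
    enumeration order for some amide-like systems; hashing a molecule
    rebuilt from its canonical serialization makes every equivalent
    input serialization hash byte-identically.
    """
    ps = Chem.SmilesWriteParams()
    rebuilt = Chem.MolFromSmiles(Chem.MolToCXSmiles(mol, ps, _CX_IDENTITY_FIELDS))
    return mol if rebuilt is None else rebuilt


def _tautomer_hash_func(version: str):
    if version == "v2":
        return rdMolHash.HashFunction.HetAtomTautomerv2
    return rdMolHash.HashFunction.HetAtomTautomer


def _stereo_tautomer_hash(mol: Chem.Mol, version: str) -> str:
    # Stereogenic Hs confuse the tautomer hash; drop all of them here.
    params = Chem.RemoveHsParameters()
    params.updateExplicitCount = True
    params.removeDefiningBondStereo = True
    work = Chem.RemoveHs(Chem.Mol(mol), params, sanitize=False)
    work.UpdatePropertyCache(False)
    work = _canonical_rebuild(work)
    skip = Chem.CXSmilesFields.CX_ALL ^ _CX_IDENTITY_FIELDS
    return rdMolHash.MolHash(work, _tautomer_hash_func(version), True, skip)


def _no_stereo_copy(mol: Chem.Mol) -> Chem.Mol:
    params = Chem.RemoveHsParameters()
    params.updateExplicitCount = True
    params.removeDefiningBondStereo = True
    work = Chem.RemoveHs(Chem.Mol(mol), params, sanitize=False)
    work.UpdatePropertyCache(False)
    Chem.RemoveStereochemistry(work)
    return _canonical_rebuild(work)


def canonicalize_sgroup_data(
    mol: Chem.Mol, sgroup_fields: Optional[Sequence[str]] = None
) -> str:
    """Serialize DAT-SGroup data as order-independent canonical JSON.

    Each DAT SGroup contributes one record value (its data lines joined
    with newlines) under its field name. Records are grouped by field
    name with values sorted, field names serialized in sorted order, and
    no insignificant whitespace — so the output is independent of the
    order SGroups appear in the mol block. When ``sgroup_fields`` is
    given, only those field names participate. Molecules without DAT
    SGroup data yield ``"{}"``.
    """
    by_field: dict = {}
    for sg in Chem.GetMolSubstanceGroups(mol):
        if not sg.HasProp("TYPE") or sg.GetProp("TYPE") != "DAT":
            continue
        if not sg.HasProp("FIELDNAME"):
            continue
        name = sg.GetProp("FIELDNAME")
        if sgroup_fields is not None and name not in sgroup_fields:
            continue
        try:
            lines = list(sg.GetStringVectProp("DATAFIELDS"))
        except KeyError:
            lines = []
        by_field.setdefault(name, []).append("\n".join(lines))
    canonical = {name: sorted(values) for name, values in by_field.items()}
    return json.dumps(canonical, sort_keys=True, separators=(",", ":"))


def compute_layers(
    mol: Chem.Mol,
    escape: str = "",
    options: HashOptions = DEFAULT_OPTIONS,
) -> MolHashLayers:
    """Compute all seven identity layers for a sanitized molecule.

    The stereo-free layers are computed on a copy with every stereo
    annotation (atom parities, double-bond configurations, stereo
    groups) removed; the input is never modified. ``escape`` is stored
    verbatim.

    Raises
    ------
    HashingError
        If a layer cannot be serialized; the exception names the layer.
    """
    work = _prepare(mol)
    version = options.tautomer_hash_version

    def _layer(name, fn):
        try:
            value = fn()
        except Exception as exc:  # pragma: no cover - rdkit failure paths
            raise HashingError(name, str(exc)) from exc
        if value is None:
            raise HashingError(name, "serialization returned nothing")
        return value

    formula = _layer(
        FORMULA, lambda: rdMolHash.MolHash(work, rdMolHash.HashFunction.MolFormula)
    )
    ps = Chem.SmilesWriteParams()
    cxsmiles = _layer(
        CANONICAL_SMILES, lambda: Chem.MolToCXSmiles(work, ps, _CX_IDENTITY_FIELDS)
    )
    tautomer = _layer(TAUTOMER_HASH, lambda: _stereo_tautomer_hash(work, version))

    flat = _no_stereo_copy(work)
    no_stereo_smiles = _layer(
        NO_STEREO_SMILES,
        lambda: rdMolHash.MolHash(flat, rdMolHash.HashFunction.CanonicalSmiles),
    )
    no_stereo_tautomer = _layer(
        NO_STEREO_TAUTOMER_HASH,
        lambda: rdMolHash.MolHash(flat, _tautomer_hash_func(version)),
    )
    sgroup = _layer(
        SGROUP_DATA, lambda: canonicalize_sgroup_data(work, options.sgroup_fields)
    )
    return MolHashLayers(
        formula=formula,
        canonical_smiles=cxsmiles,
        tautomer_hash=tautomer,
        no_stereo_smiles=no_stereo_smiles,
        no_stereo_tautomer_hash=no_stereo_tautomer,
        sgroup_data=sgroup,
        escape=escape,
    )


def serialize_layers(layers: MolHashLayers, options: HashOptions = DEFAULT_OPTIONS) -> bytes:
    """The canonical byte preimage fed to SHA1 by :func:`combine_layers`."""
    d = layers.as_dict()
    text = "\n".join(f"{name}:{d[name]}" for name in options.layer_order)
    return text.encode("utf-8")


def combine_layers(layers: MolHashLayers, options: HashOptions = DEFAULT_OPTIONS) -> str:
    """Combine the seven layers into one 40-char lowercase-hex SHA1 digest."""
    return hashlib.sha1(serialize_layers(layers, options)).hexdigest()


def match_layers(
    stored: MolHashLayers, probe: MolHashLayers, selected: Iterable[str]
) -> bool:
    """True iff every selected layer is byte-identical between the two."""
    names: Set[str] = set(selected)
    if not names:
        raise ValueError("at least one layer must be selected")
    unknown = names - set(LAYER_ORDER)
    if unknown:
        raise ValueError(f"unknown layer name(s): {sorted(unknown)}")
    a, b = stored.as_dict(), probe.as_dict()
    return all(a[name] == b[name] for name in names)
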
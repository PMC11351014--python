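"""Pre-registration standardization and filtering.

Molecules pass through an ordered, configurable pipeline before they are
hashed. Each step is either a *standardizer*, which may return a
modified molecule, or a *filter*, which returns its input unchanged on
acceptance. Either kind returns ``None`` on failure, which rejects the
molecule and stops the pipeline; the names of the steps actually
attempted — and the rejecting step, if any — are recorded per molecule
so a database is self-describing about how each entry was produced.

Built-in steps (addressed by name in pipeline configs):

``sanitize``
    Standard valence/aromaticity validation and perception.
``remove_fragments``
    Keep the largest fragment (heavy atoms, then total atoms, then
    lexicographically smallest canonical SMILES as tie-breaks).
``neutralize``
    Neutralize simple charged acids/bases; zwitterions whose charges
    cannot be independently removed are left intact.
``charge_parent``
    Largest *organic* fragment (contains carbon), neutralized.
``filter_overlapping_atoms``
    Reject molecules whose depiction/conformer places two atoms within
    ``min_dist`` angstrom (default 1e-4, i.e. effectively coincident).
``filter_polymer_sgroup``
    Reject molecules whose SGroup data marks them as polymers
    (SRU, MON, COP, ...).
``canonicalize_orientation``
    Rotate/translate an attached 3D conformer into the canonical pose
    so conformer hashes become orientation-free.

New steps register under fresh names via :func:`register_step` and are
then usable in pipeline configurations like the built-ins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .conformer_hash import ConformerCoordinates, canonicalize_orientation

__all__ = [
    "StandardizationStep",
    "StandardizationRecord",
    "sanitize",
    "remove_fragments",
    "neutralize",
    "charge_parent",
    "filter_overlapping_atoms",
    "filter_polymer_sgroup",
    "run_pipeline",
    "register_step",
    "make_step",
    "build_pipeline",
    "DEFAULT_PIPELINE",
    "POLYMER_SGROUP_TYPES",
]

STANDARDIZER = "standardizer"
FILTER = "filter"

#: SGroup TYPE values that mark a molecule as polymeric.
POLYMER_SGROUP_TYPES = frozenset(
    {"SRU", "MON", "COP", "CRO", "GRA", "MOD", "MER", "ANY"}
)

#: Pipeline applied when a store is initialized without an explicit one.
DEFAULT_PIPELINE: Tuple[str, ...] = ("sanitize",)


@dataclass(frozen=True)
class StandardizationStep:
    """A named pipeline element.

    ``apply`` takes a molecule and returns a molecule on success or
    ``None`` on failure. A successful filter returns a molecule
    structurally identical to its input.
    """

    name: str
    kind: str  # STANDARDIZER or FILTER
    apply: Callable[[Chem.Mol], Optional[Chem.Mol]]


@dataclass
class StandardizationRecord:
    """What the pipeline did to one molecule."""

    applied: List[str] = field(default_factory=list)
    outcome: str = "accepted"  # "accepted" | "rejected"
    rejecting_step: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "applied": list(self.applied),
            "outcome": self.outcome,
            "rejecting_step": self.rejecting_step,
        }


# ---------------------------------------------------------------------------
# built-in operations


def sanitize(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Validate valences and perceive aromaticity; None if invalid."""
    work = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(work)
    except Exception:
        return None
    return work


def _fragment_sort_key(frag: Chem.Mol):
    heavy = frag.GetNumHeavyAtoms()
    total = heavy + sum(a.GetTotalNumHs() for a in frag.GetAtoms())
    smiles = Chem.MolToSmiles(frag)
    return (-heavy, -total, smiles)


def remove_fragments(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest fragment; single-fragment inputs pass through."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return min(frags, key=_fragment_sort_key)


def neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Neutralize protonation-convertible charged sites.

    Simple anionic acids (carboxylates, alkoxides, thiolates, amides)
    gain a proton; simple protonated bases lose one. Charge-separated
    sites that cannot be independently neutralized (e.g. quaternary
    nitrogen in a zwitterion) remain as submitted.
    """
    uncharger = rdMolStandardize.Uncharger(canonicalOrder=True)
    out = uncharger.uncharge(Chem.Mol(mol))
    Chem.SanitizeMol(out)
    return out


def charge_parent(mol: Chem.Mol) -> Chem.Mol:
    """Largest organic fragment, neutralized.

    A fragment is organic when it contains at least one carbon; if no
    fragment does, the plain largest fragment is used instead.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [
        f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
    ]
    pool = organic if organic else list(frags)
    parent = min(pool, key=_fragment_sort_key) if len(pool) > 1 else pool[0]
    return neutralize(parent)


def filter_overlapping_atoms(
    mol: Chem.Mol, min_dist: float = 1e-4
) -> Optional[Chem.Mol]:
    """Reject molecules with two atoms closer than ``min_dist`` angstrom.

    Distances are strict: atoms exactly at ``min_dist`` are accepted.
    Molecules without coordinates pass (there is nothing to check).
    """
    if mol.GetNumConformers() == 0 or mol.GetNumAtoms() < 2:
        return mol
    pos = mol.GetConformer().GetPositions()
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(pos), k=1)
    if (dist[iu] < min_dist).any():
        return None
    return mol


def filter_polymer_sgroup(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Reject molecules whose SGroups mark a polymer (SRU/MON/COP/...)."""
    for sg in Chem.GetMolSubstanceGroups(mol):
        if sg.HasProp("TYPE") and sg.GetProp("TYPE") in POLYMER_SGROUP_TYPES:
            return None
    return mol


def _canonicalize_orientation_step(mol: Chem.Mol) -> Chem.Mol:
    if mol.GetNumConformers() == 0:
        return mol
    work = Chem.Mol(mol)
    conf = work.GetConformer()
    canon = canonicalize_orientation(
        ConformerCoordinates.from_array(conf.GetPositions())
    )
    for i, (x, y, z) in enumerate(canon.positions):
        conf.SetAtomPosition(i, (x, y, z))
    return work


# ---------------------------------------------------------------------------
# step registry and pipeline

_STEP_FACTORIES: Dict[str, Callable[..., StandardizationStep]] = {}


def register_step(name: str, kind: str, fn: Callable[..., Optional[Chem.Mol]]) -> None:
    """Register a step factory under a unique name.

    ``fn(mol, **params)`` must honor the step contract (molecule or
    ``None``; filters leave accepted molecules unmodified). Registered
    names become usable in pipeline configurations.
    """
    if name in _STEP_FACTORIES:
        raise ValueError(f"step name already registered: {name}")
    if kind not in (STANDARDIZER, FILTER):
        raise ValueError(f"kind must be {STANDARDIZER!r} or {FILTER!r}")

    def factory(**params):
        return StandardizationStep(
            name=name, kind=kind, apply=lambda mol: fn(mol, **params)
        )

    _STEP_FACTORIES[name] = factory


def make_step(name: str, params: Optional[dict] = None) -> StandardizationStep:
    """Instantiate a registered step by name with optional parameters."""
    try:
        factory = _STEP_FACTORIES[name]
    except KeyError:
        raise ValueError(f"unknown standardization step: {name!r}") from None
    return factory(**(params or {}))


def available_steps() -> List[str]:
    return sorted(_STEP_FACTORIES)


def build_pipeline(config: Sequence) -> List[StandardizationStep]:
    """Turn a pipeline config into runnable steps.

    Each entry is either a bare step name or a mapping
    ``{"name": ..., "params": {...}}`` — the JSON shape stored in the
    database configuration.
    """
    steps = []
    for entry in config:
        if isinstance(entry, str):
            steps.append(make_step(entry))
        else:
            steps.append(make_step(entry["name"], entry.get("params")))
    return steps


def run_pipeline(
    mol: Chem.Mol, steps: Sequence[StandardizationStep]
) -> Tuple[Optional[Chem.Mol], StandardizationRecord]:
    """Apply steps in order, stopping at the first failure.

    Returns the standardized molecule (or ``None`` on rejection) and a
    record of exactly the steps attempted, in their actual order.
    """
    if not steps:
        raise ValueError("pipeline must contain at least one step")
    record = StandardizationRecord()
    current = mol
    for step in steps:
        record.applied.append(step.name)
        result = step.apply(current)
        if result is None:
            record.outcome = "rejected"
            record.rejecting_step = step.name
            return None, record
        current = result
    return current, record


register_step("sanitize", STANDARDIZER, lambda mol: sanitize(mol))
register_step("remove_fragments", STANDARDIZER, lambda mol: remove_fragments(mol))
register_step("neutralize", STANDARDIZER, lambda mol: neutralize(mol))
register_step("charge_parent", STANDARDIZER, lambda mol: charge_parent(mol))
register_step("filter_overlapping_atoms", FILTER, filter_overlapping_atoms)
register_step("filter_polymer_sgroup", FILTER, lambda mol: filter_polymer_sgroup(mol))
register_step(
    "canonicalize_orientation", STANDARDIZER, lambda mol: _canonicalize_orientation_step(mol)
)
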
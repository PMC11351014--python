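"""Public registration facade: register, bulk_register, query, retrieve.

This module ties the standardization pipeline, the layered hash and the
store together. A :class:`Registry` is attached to one database whose
persisted :class:`~molregistry.store.SystemConfig` dictates how every
submission is processed, so two processes pointing at the same database
necessarily agree on identity.

Registration flow: parse -> standardization pipeline -> seven-layer
hash -> combined SHA1 -> insert. In ``registerConformers`` mode a 3D
conformer on the input is additionally hashed and stored, and queries
carrying a conformer match by coordinate hash, returning
``(molregno, conf_id)`` tuples.

The registry is append-only; re-registering an existing structure is
reported as a duplicate carrying the existing identifier rather than an
error, so pipelines can use ``register`` as an idempotent get-or-create.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from rdkit import Chem

from . import hash_layers as hl
from .conformer_hash import ConformerCoordinates, conformer_hash
from .standardize import build_pipeline, run_pipeline
from .store import (
    DuplicateError,
    NotRegisteredError,
    Store,
    SystemConfig,
)

__all__ = ["Registry", "RegistrationResult", "split_sdf"]

logger = logging.getLogger(__name__)

SMILES = "smiles"
MOLBLOCK = "molblock"

REGISTERED = "registered"
DUPLICATE = "duplicate"
REJECTED = "rejected"
PARSE_ERROR = "parse_error"


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of one registration attempt.

    ``molregno`` is present for both fresh registrations and duplicates
    (for a duplicate it is the identifier of the already-registered
    structure). ``conf_id`` is set when a conformer was involved.
    """

    status: str
    molregno: Optional[int] = None
    conf_id: Optional[int] = None
    detail: str = ""

    def as_dict(self) -> dict:
        return {
            "status": self.status,
            "molregno": self.molregno,
            "conf_id": self.conf_id,
            "detail": self.detail,
        }


def guess_format(text: str) -> str:
    """Classify structure text as SMILES or a mol block."""
    if "V2000" in text or "V3000" in text or "M  END" in text:
        return MOLBLOCK
    return SMILES


def split_sdf(text: str) -> List[str]:
    """Split SDF text into per-record texts on the ``$$$$`` delimiter.

    Each returned record is exactly the submitted text for that entry
    (without the delimiter line), preserving byte fidelity for the
    as-registered table.
    """
    records, current = [], []
    for line in text.splitlines(keepends=True):
        if line.rstrip("\r\n") == "$$$$":
            records.append("".join(current))
            current = []
        else:
            current.append(line)
    if "".join(current).strip():
        records.append("".join(current))
    return records


def _parse(text: str, fmt: Optional[str]) -> Tuple[Optional[Chem.Mol], str]:
    fmt = fmt or guess_format(text)
    if fmt == SMILES:
        mol = Chem.MolFromSmiles(text, sanitize=False)
    elif fmt == MOLBLOCK:
        mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    else:
        raise ValueError(f"unknown input format: {fmt!r}")
    return mol, fmt


class Registry:
    """Registration interface bound to one store."""

    def __init__(self, store: Store):
        self.store = store
        self.config: SystemConfig = store.load_config()
        self._pipeline = build_pipeline(self.config.standardization)
        self._options = self.config.hash_options()

    # -- lifecycle ----------------------------------------------------

    @classmethod
    def init(
        cls,
        location: str,
        config: Optional[SystemConfig] = None,
        overwrite: bool = False,
    ) -> "Registry":
        """Create a new registration database and attach to it."""
        return cls(Store.create(location, config=config, overwrite=overwrite))

    @classmethod
    def open(cls, location: str) -> "Registry":
        return cls(Store.open(location))

    # -- internals ----------------------------------------------------

    def _standardize(self, mol: Chem.Mol):
        return run_pipeline(mol, self._pipeline)

    def _conformer_coords(self, mol: Chem.Mol) -> Optional[ConformerCoordinates]:
        if not self.config.register_conformers or mol.GetNumConformers() == 0:
            return None
        conf = mol.GetConformer()
        if not conf.Is3D():
            return None
        return ConformerCoordinates.from_array(
            conf.GetPositions(), digits=self.config.conformer_digits
        )

    # -- operations ---------------------------------------------------

    def register(
        self, text: str, fmt: Optional[str] = None, escape: str = ""
    ) -> RegistrationResult:
        """Attempt to register one structure.

        Returns status ``registered`` with a fresh molregno on success,
        ``duplicate`` with the existing molregno when all seven layers
        match a stored molecule, ``rejected`` (naming the step) when a
        pipeline filter declines the input, and ``parse_error`` for
        unreadable input. In ``registerConformers`` mode a 3D conformer
        on the input is hashed and stored too — also under an existing
        molregno, so submitting a new pose of a known molecule yields
        (existing molregno, fresh conf_id).
        """
        try:
            mol, fmt = _parse(text, fmt)
        except ValueError as exc:
            return RegistrationResult(PARSE_ERROR, detail=str(exc))
        if mol is None:
            return RegistrationResult(PARSE_ERROR, detail="could not parse input")

        std, record = self._standardize(mol)
        if std is None:
            return RegistrationResult(
                REJECTED,
                detail=f"rejected by standardization step "
                f"{record.rejecting_step!r}",
            )

        try:
            layers = hl.compute_layers(std, escape=escape, options=self._options)
        except hl.HashingError as exc:
            return RegistrationResult(PARSE_ERROR, detail=str(exc))
        full_hash = hl.combine_layers(layers, self._options)

        coords = self._conformer_coords(std)
        molblock = Chem.MolToV3KMolBlock(std)

        molecule_is_new = True
        try:
            molregno = self.store.insert_molecule(
                layers, full_hash, text, fmt, molblock, record
            )
        except DuplicateError as dup:
            molregno = dup.molregno
            molecule_is_new = False
            if coords is None:
                return RegistrationResult(
                    DUPLICATE, molregno=molregno, detail="structure already registered"
                )

        conf_id = None
        if coords is not None:
            try:
                conf_id = self.store.insert_conformer(
                    molregno, coords, conformer_hash(coords)
                )
            except DuplicateError as dup:
                if molecule_is_new:
                    # fresh molecule can't already own this conformer
                    raise
                return RegistrationResult(
                    DUPLICATE,
                    molregno=molregno,
                    conf_id=dup.conf_id,
                    detail="conformer already registered",
                )

        detail = "" if molecule_is_new else "molecule known; new conformer stored"
        return RegistrationResult(
            REGISTERED, molregno=molregno, conf_id=conf_id, detail=detail
        )

    def bulk_register(
        self,
        inputs: Iterable[Union[str, Tuple[str, Optional[str]]]],
        escape: str = "",
    ) -> List[RegistrationResult]:
        """Register many structures; one result per input, in order.

        Failures (duplicate / rejected / parse_error) never abort the
        batch, and each successful registration is durable on its own.
        """
        results = []
        for item in inputs:
            if isinstance(item, tuple):
                text, fmt = item
            else:
                text, fmt = item, None
            results.append(self.register(text, fmt=fmt, escape=escape))
        return results

    def bulk_register_sdf(self, sdf_text: str, escape: str = "") -> List[RegistrationResult]:
        """Register every record of an SDF document."""
        return self.bulk_register(
            [(record, MOLBLOCK) for record in split_sdf(sdf_text)], escape=escape
        )

    def query(
        self,
        text: str,
        fmt: Optional[str] = None,
        layers: Optional[Iterable[str]] = None,
        escape: str = "",
    ) -> Union[List[int], List[Tuple[int, int]]]:
        """Find registered molecules matching the query structure.

        The query undergoes the same standardization as registration.
        ``layers`` selects which identity layers must match (default:
        all seven, i.e. exact duplicate). Selecting e.g.
        ``{TAUTOMER_HASH}`` finds registered tautomers of the query;
        ``{NO_STEREO_SMILES}`` finds stereoisomers.

        In ``registerConformers`` mode, a query carrying a 3D conformer
        matches by coordinate hash instead and returns
        ``(molregno, conf_id)`` tuples.

        A query rejected by a pipeline filter returns an empty result
        (with a logged warning) — queries are total.
        """
        mol, fmt = _parse(text, fmt)
        if mol is None:
            raise ValueError("could not parse query structure")

        std, record = self._standardize(mol)
        if std is None:
            logger.warning(
                "query structure rejected by standardization step %r; "
                "returning no matches",
                record.rejecting_step,
            )
            return []

        coords = self._conformer_coords(std)
        if coords is not None:
            return self.store.find_conformers(conformer_hash(coords))

        probe = hl.compute_layers(std, escape=escape, options=self._options)
        selected = set(layers) if layers is not None else set(hl.LAYER_ORDER)
        return self.store.find_by_layers(probe, selected)

    def query_conformers(self, molregnos: Sequence[int]) -> Dict[int, List[int]]:
        """All conformer IDs for each requested molregno.

        Only meaningful in ``registerConformers`` mode. Molecules
        without conformers map to empty lists; unknown molregnos raise.
        """
        if not self.config.register_conformers:
            raise ValueError("store is not in registerConformers mode")
        return {m: self.store.conformer_ids(m) for m in molregnos}

    def retrieve(
        self,
        ids: Sequence[Union[int, Tuple[int, int]]],
        mode: str = "standardized",
    ) -> Dict[Union[int, Tuple[int, int]], Union[str, dict]]:
        """Fetch stored payloads for molregnos or (molregno, conf_id) pairs.

        ``standardized``
            v3000 mol block of the standardized structure; for a
            (molregno, conf_id) pair the block embeds that conformer's
            full-precision coordinates.
        ``as_registered``
            the submission byte-identical to what was provided.
        ``hashes``
            all seven layers plus the combined digest.
        """
        if mode not in ("standardized", "as_registered", "hashes"):
            raise ValueError(f"unknown retrieve mode: {mode!r}")
        out: Dict = {}
        for ident in ids:
            if isinstance(ident, tuple):
                molregno, conf_id = ident
            else:
                molregno, conf_id = ident, None
            try:
                if mode == "standardized":
                    out[ident] = self.store.get_molblock(molregno, conf_id)
                elif mode == "as_registered":
                    data, _fmt = self.store.get_raw(molregno)
                    out[ident] = data
                else:
                    layers = self.store.get_layers(molregno)
                    payload = layers.as_dict()
                    payload["FULL_HASH"] = self.store.get_full_hash(molregno)
                    out[ident] = payload
            except NotRegisteredError:
                raise NotRegisteredError(
                    f"identifier {ident!r} is not registered"
                ) from None
        return out
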
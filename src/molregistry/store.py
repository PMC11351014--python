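"""Relational persistence for the registry.

Molecules, their identity layers, conformers, raw submissions and the
system configuration live in one embedded SQLite database. String
equality on indexed hash columns is the only search primitive, which is
what makes duplicate checks and layer-subset queries fast in any
relational backend.

The schema is shipped as versioned DDL text (:data:`SCHEMA_DDL`). SQL is
written in the portable core dialect behind a small backend seam
(:data:`BACKENDS`) so a client/server backend can implement the same
contract; the embedded backend is the default and the one exercised by
the test suite.

Everything is append-only: molecules and conformers are never updated
or deleted, so identifiers are stable for the lifetime of a database.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import sqlite3
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem

from . import hash_layers as hl
from .conformer_hash import ConformerCoordinates
from .standardize import DEFAULT_PIPELINE, StandardizationRecord

__all__ = [
    "SystemConfig",
    "Store",
    "DuplicateError",
    "NotRegisteredError",
    "StoreExistsError",
    "SCHEMA_VERSION",
    "SCHEMA_DDL",
    "BACKENDS",
]

SCHEMA_VERSION = 1

# Versioned DDL. Layer columns are indexed individually so that
# layer-subset queries and full-hash duplicate checks are both single
# index lookups.
SCHEMA_DDL = """
-- molregistry schema v1
CREATE TABLE config (
    key   TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE molecules (
    molregno                 INTEGER PRIMARY KEY AUTOINCREMENT,
    full_hash                TEXT NOT NULL UNIQUE,
    formula                  TEXT NOT NULL,
    canonical_smiles         TEXT NOT NULL,
    tautomer_hash            TEXT NOT NULL,
    no_stereo_smiles         TEXT NOT NULL,
    no_stereo_tautomer_hash  TEXT NOT NULL,
    sgroup_data              TEXT NOT NULL,
    escape_layer             TEXT NOT NULL,
    standardization          TEXT NOT NULL,
    registered_at            TEXT NOT NULL
);
CREATE INDEX ix_molecules_formula ON molecules(formula);
CREATE INDEX ix_molecules_canonical_smiles ON molecules(canonical_smiles);
CREATE INDEX ix_molecules_tautomer_hash ON molecules(tautomer_hash);
CREATE INDEX ix_molecules_no_stereo_smiles ON molecules(no_stereo_smiles);
CREATE INDEX ix_molecules_no_stereo_tautomer_hash
    ON molecules(no_stereo_tautomer_hash);
CREATE INDEX ix_molecules_sgroup_data ON molecules(sgroup_data);
CREATE INDEX ix_molecules_escape ON molecules(escape_layer);
CREATE TABLE orig_data (
    molregno INTEGER PRIMARY KEY REFERENCES molecules(molregno),
    data     TEXT NOT NULL,
    format   TEXT NOT NULL
);
CREATE TABLE molblocks (
    molregno INTEGER PRIMARY KEY REFERENCES molecules(molregno),
    molblock TEXT NOT NULL
);
CREATE TABLE conformers (
    molregno      INTEGER NOT NULL REFERENCES molecules(molregno),
    conf_id       INTEGER NOT NULL,
    conf_hash     TEXT NOT NULL,
    coordinates   TEXT NOT NULL,
    registered_at TEXT NOT NULL,
    PRIMARY KEY (molregno, conf_id),
    UNIQUE (molregno, conf_hash)
);
CREATE INDEX ix_conformers_conf_hash ON conformers(conf_hash);
"""

_LAYER_COLUMNS = {
    hl.FORMULA: "formula",
    hl.CANONICAL_SMILES: "canonical_smiles",
    hl.TAUTOMER_HASH: "tautomer_hash",
    hl.NO_STEREO_SMILES: "no_stereo_smiles",
    hl.NO_STEREO_TAUTOMER_HASH: "no_stereo_tautomer_hash",
    hl.SGROUP_DATA: "sgroup_data",
    hl.ESCAPE: "escape_layer",
}


class DuplicateError(Exception):
    """The structure (or conformer) is already registered."""

    def __init__(self, molregno: int, conf_id: Optional[int] = None):
        self.molregno = molregno
        self.conf_id = conf_id
        what = f"molregno {molregno}" if conf_id is None else (
            f"(molregno, conf_id) = ({molregno}, {conf_id})"
        )
        super().__init__(f"already registered as {what}")


class NotRegisteredError(KeyError):
    """An identifier does not exist in the store."""


class StoreExistsError(FileExistsError):
    """Refusing to initialize over an existing non-empty store."""


@dataclass(frozen=True)
class SystemConfig:
    """Registration policy persisted inside the database itself.

    A database is self-describing: the pipeline, hash options and
    conformer settings that produced its contents travel with it.
    """

    standardization: Sequence = DEFAULT_PIPELINE
    register_conformers: bool = False
    tautomer_hash_version: str = "v2"
    sgroup_fields: Optional[Sequence[str]] = None
    conformer_digits: int = 3
    schema_version: int = SCHEMA_VERSION

    def to_json(self) -> str:
        d = {
            "standardization": list(self.standardization),
            "register_conformers": self.register_conformers,
            "tautomer_hash_version": self.tautomer_hash_version,
            "sgroup_fields": (
                None if self.sgroup_fields is None else list(self.sgroup_fields)
            ),
            "conformer_digits": self.conformer_digits,
            "schema_version": self.schema_version,
        }
        return json.dumps(d, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "SystemConfig":
        d = json.loads(text)
        return cls(
            standardization=tuple(
                e if isinstance(e, str) else dict(e) for e in d["standardization"]
            ),
            register_conformers=d["register_conformers"],
            tautomer_hash_version=d["tautomer_hash_version"],
            sgroup_fields=(
                None if d["sgroup_fields"] is None else tuple(d["sgroup_fields"])
            ),
            conformer_digits=d["conformer_digits"],
            schema_version=d["schema_version"],
        )

    def hash_options(self) -> hl.HashOptions:
        return hl.HashOptions(
            tautomer_hash_version=self.tautomer_hash_version,
            sgroup_fields=self.sgroup_fields,
        )


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat()


class Store:
    """Embedded-file store (SQLite dialect).

    Use :meth:`create` to initialize a new database and :meth:`open` to
    attach to an existing one. ``location`` may be ``":memory:"`` for a
    throwaway in-process store.
    """

    backend = "sqlite"

    def __init__(self, conn: sqlite3.Connection, location: str):
        self._conn = conn
        self.location = location
        self._conn.execute("PRAGMA foreign_keys = ON")

    # -- lifecycle ----------------------------------------------------

    @classmethod
    def create(
        cls,
        location: str,
        config: Optional[SystemConfig] = None,
        overwrite: bool = False,
    ) -> "Store":
        """Initialize a fresh store at ``location`` and persist ``config``."""
        config = config or SystemConfig()
        if location != ":memory:" and os.path.exists(location):
            if not overwrite and os.path.getsize(location) > 0:
                raise StoreExistsError(
                    f"store already exists at {location!r}; pass overwrite=True"
                )
            os.remove(location)
        conn = sqlite3.connect(location)
        store = cls(conn, location)
        conn.executescript(SCHEMA_DDL)
        conn.execute(
            "INSERT INTO config (key, value) VALUES (?, ?)",
            ("system_config", config.to_json()),
        )
        conn.execute(
            "INSERT INTO config (key, value) VALUES (?, ?)",
            ("schema_version", str(SCHEMA_VERSION)),
        )
        conn.commit()
        return store

    @classmethod
    def open(cls, location: str) -> "Store":
        if location != ":memory:" and not os.path.exists(location):
            raise FileNotFoundError(f"no store at {location!r}")
        store = cls(sqlite3.connect(location), location)
        store.load_config()  # validates this really is a registry database
        return store

    def close(self) -> None:
        self._conn.close()

    @property
    def connection(self) -> sqlite3.Connection:
        """The underlying DB-API connection (used by the experiment tables)."""
        return self._conn

    def load_config(self) -> SystemConfig:
        row = self._conn.execute(
            "SELECT value FROM config WHERE key = 'system_config'"
        ).fetchone()
        if row is None:
            raise NotRegisteredError("store has no system_config")
        return SystemConfig.from_json(row[0])

    def config_text(self) -> str:
        """The stored configuration JSON, byte-identical to what was saved."""
        return self._conn.execute(
            "SELECT value FROM config WHERE key = 'system_config'"
        ).fetchone()[0]

    # -- molecules ----------------------------------------------------

    def insert_molecule(
        self,
        layers: hl.MolHashLayers,
        full_hash: str,
        raw_data: str,
        raw_format: str,
        standardized_molblock: str,
        standardization: StandardizationRecord,
    ) -> int:
        """Insert a new molecule; molregnos are allocated sequentially.

        Raises :class:`DuplicateError` (carrying the existing molregno)
        when ``full_hash`` is already present.
        """
        existing = self.find_by_hash(full_hash)
        if existing is not None:
            raise DuplicateError(existing)
        d = layers.as_dict()
        cur = self._conn.execute(
            """INSERT INTO molecules
               (full_hash, formula, canonical_smiles, tautomer_hash,
                no_stereo_smiles, no_stereo_tautomer_hash, sgroup_data,
                escape_layer, standardization, registered_at)
               VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)""",
            (
                full_hash,
                d[hl.FORMULA],
                d[hl.CANONICAL_SMILES],
                d[hl.TAUTOMER_HASH],
                d[hl.NO_STEREO_SMILES],
                d[hl.NO_STEREO_TAUTOMER_HASH],
                d[hl.SGROUP_DATA],
                d[hl.ESCAPE],
                json.dumps(standardization.as_dict()),
                _now(),
            ),
        )
        molregno = cur.lastrowid
        self._conn.execute(
            "INSERT INTO orig_data (molregno, data, format) VALUES (?, ?, ?)",
            (molregno, raw_data, raw_format),
        )
        self._conn.execute(
            "INSERT INTO molblocks (molregno, molblock) VALUES (?, ?)",
            (molregno, standardized_molblock),
        )
        self._conn.commit()
        return molregno

    def find_by_hash(self, full_hash: str) -> Optional[int]:
        row = self._conn.execute(
            "SELECT molregno FROM molecules WHERE full_hash = ?", (full_hash,)
        ).fetchone()
        return None if row is None else row[0]

    def find_by_layers(
        self, probe: hl.MolHashLayers, selected: Iterable[str]
    ) -> List[int]:
        """molregnos matching ``probe`` on every selected layer, ascending."""
        names = list(selected)
        if not names:
            raise ValueError("at least one layer must be selected")
        probe_d = probe.as_dict()
        clauses, params = [], []
        for name in names:
            try:
                col = _LAYER_COLUMNS[name]
            except KeyError:
                raise ValueError(f"unknown layer name: {name!r}") from None
            clauses.append(f"{col} = ?")
            params.append(probe_d[name])
        sql = (
            "SELECT molregno FROM molecules WHERE "
            + " AND ".join(clauses)
            + " ORDER BY molregno"
        )
        return [r[0] for r in self._conn.execute(sql, params)]

    def get_layers(self, molregno: int) -> hl.MolHashLayers:
        row = self._conn.execute(
            """SELECT formula, canonical_smiles, tautomer_hash,
                      no_stereo_smiles, no_stereo_tautomer_hash,
                      sgroup_data, escape_layer
               FROM molecules WHERE molregno = ?""",
            (molregno,),
        ).fetchone()
        if row is None:
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        return hl.MolHashLayers(*row)

    def get_full_hash(self, molregno: int) -> str:
        row = self._conn.execute(
            "SELECT full_hash FROM molecules WHERE molregno = ?", (molregno,)
        ).fetchone()
        if row is None:
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        return row[0]

    def get_raw(self, molregno: int) -> Tuple[str, str]:
        """The submission exactly as provided at registration time."""
        row = self._conn.execute(
            "SELECT data, format FROM orig_data WHERE molregno = ?", (molregno,)
        ).fetchone()
        if row is None:
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        return row[0], row[1]

    def get_standardization(self, molregno: int) -> dict:
        row = self._conn.execute(
            "SELECT standardization FROM molecules WHERE molregno = ?",
            (molregno,),
        ).fetchone()
        if row is None:
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        return json.loads(row[0])

    def get_molblock(self, molregno: int, conf_id: Optional[int] = None) -> str:
        """v3000 mol block of the standardized structure.

        With ``conf_id``, the block embeds that conformer's stored
        full-precision coordinates.
        """
        row = self._conn.execute(
            "SELECT molblock FROM molblocks WHERE molregno = ?", (molregno,)
        ).fetchone()
        if row is None:
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        if conf_id is None:
            return row[0]
        coords = self.get_conformer(molregno, conf_id)
        mol = Chem.MolFromMolBlock(row[0], sanitize=False, removeHs=False)
        if mol.GetNumConformers() == 0:
            conf = Chem.Conformer(mol.GetNumAtoms())
            mol.AddConformer(conf, assignId=True)
        conf = mol.GetConformer()
        if mol.GetNumAtoms() != len(coords.positions):
            raise ValueError(
                "stored conformer does not match the molecule's atom count"
            )
        conf.Set3D(True)
        for i, (x, y, z) in enumerate(coords.positions):
            conf.SetAtomPosition(i, (x, y, z))
        return Chem.MolToV3KMolBlock(mol)

    def count_molecules(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM molecules").fetchone()[0]

    def all_molregnos(self) -> List[int]:
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT molregno FROM molecules ORDER BY molregno"
            )
        ]

    # -- conformers ---------------------------------------------------

    def insert_conformer(
        self, molregno: int, coords: ConformerCoordinates, conf_hash: str
    ) -> int:
        """Store a conformer at full precision; conf_ids count per molecule."""
        if self.molregno_exists(molregno) is False:
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        row = self._conn.execute(
            "SELECT conf_id FROM conformers WHERE molregno = ? AND conf_hash = ?",
            (molregno, conf_hash),
        ).fetchone()
        if row is not None:
            raise DuplicateError(molregno, row[0])
        next_id = self._conn.execute(
            "SELECT COALESCE(MAX(conf_id), 0) + 1 FROM conformers WHERE molregno = ?",
            (molregno,),
        ).fetchone()[0]
        payload = json.dumps(
            {"positions": [list(p) for p in coords.positions], "digits": coords.digits}
        )
        self._conn.execute(
            """INSERT INTO conformers
               (molregno, conf_id, conf_hash, coordinates, registered_at)
               VALUES (?, ?, ?, ?, ?)""",
            (molregno, next_id, conf_hash, payload, _now()),
        )
        self._conn.commit()
        return next_id

    def molregno_exists(self, molregno: int) -> bool:
        return (
            self._conn.execute(
                "SELECT 1 FROM molecules WHERE molregno = ?", (molregno,)
            ).fetchone()
            is not None
        )

    def find_conformers(self, conf_hash: str) -> List[Tuple[int, int]]:
        """All (molregno, conf_id) pairs with this coordinate hash."""
        return [
            (r[0], r[1])
            for r in self._conn.execute(
                "SELECT molregno, conf_id FROM conformers WHERE conf_hash = ?"
                " ORDER BY molregno, conf_id",
                (conf_hash,),
            )
        ]

    def get_conformer(self, molregno: int, conf_id: int) -> ConformerCoordinates:
        row = self._conn.execute(
            "SELECT coordinates FROM conformers WHERE molregno = ? AND conf_id = ?",
            (molregno, conf_id),
        ).fetchone()
        if row is None:
            raise NotRegisteredError(
                f"(molregno, conf_id) = ({molregno}, {conf_id}) is not registered"
            )
        d = json.loads(row[0])
        return ConformerCoordinates(
            tuple(tuple(p) for p in d["positions"]), digits=d["digits"]
        )

    def conformer_ids(self, molregno: int) -> List[int]:
        if not self.molregno_exists(molregno):
            raise NotRegisteredError(f"molregno {molregno} is not registered")
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT conf_id FROM conformers WHERE molregno = ? ORDER BY conf_id",
                (molregno,),
            )
        ]


#: Available storage backends. The client/server backend implements the
#: same contract and registers itself here when its driver is importable.
BACKENDS: Dict[str, type] = {"sqlite": Store}
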
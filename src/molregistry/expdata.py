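"""Experiment metadata and results linked to registered structures.

Experimental provenance lives next to the registry in the same
database: for each *experiment type* there is one metadata table (the
information needed to reproduce an experiment) and one data table (the
results), linked by a UUID experiment key. Data rows additionally carry
the ``molregno`` — and optionally the ``conf_id`` — of the structure the
result refers to, so results are always queryable together with the
molecules that produced them.

Two schema styles are supported by the same machinery:

* a minimal shape whose payloads go into JSON columns — flexible,
  fits almost any experiment;
* a fully-columned shape with explicit numeric/text columns — more
  compact and faster to filter, at the cost of a fixed schema.

Column kinds are ``number``, ``text`` and ``json``. Numbers round-trip
exactly; JSON payloads round-trip structurally.
"""

from __future__ import annotations

import csv
import io
import json
import re
import uuid
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

from .store import NotRegisteredError, Store

__all__ = [
    "ExperimentColumn",
    "ExperimentType",
    "ExperimentStore",
]

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_RESERVED = {"experiment_id", "molregno", "conf_id", "created_at", "rowid"}
_KINDS = {"number": "REAL", "text": "TEXT", "json": "TEXT"}


@dataclass(frozen=True)
class ExperimentColumn:
    name: str
    kind: str  # "number" | "text" | "json"

    def __post_init__(self):
        if not _IDENT_RE.match(self.name) or self.name.lower() in _RESERVED:
            raise ValueError(f"invalid column name: {self.name!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"column kind must be one of {sorted(_KINDS)}")


@dataclass(frozen=True)
class ExperimentType:
    """Declares one experiment type's metadata and data columns."""

    name: str
    metadata_columns: Sequence[ExperimentColumn]
    data_columns: Sequence[ExperimentColumn]

    def __post_init__(self):
        if not _IDENT_RE.match(self.name):
            raise ValueError(f"invalid experiment type name: {self.name!r}")
        if not self.data_columns:
            raise ValueError("an experiment type needs at least one data column")

    @classmethod
    def from_json(cls, text: str) -> "ExperimentType":
        d = json.loads(text)
        return cls(
            name=d["name"],
            metadata_columns=tuple(
                ExperimentColumn(c["name"], c["kind"]) for c in d["metadata_columns"]
            ),
            data_columns=tuple(
                ExperimentColumn(c["name"], c["kind"]) for c in d["data_columns"]
            ),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "metadata_columns": [
                    {"name": c.name, "kind": c.kind} for c in self.metadata_columns
                ],
                "data_columns": [
                    {"name": c.name, "kind": c.kind} for c in self.data_columns
                ],
            },
            sort_keys=True,
        )


def _encode(col: ExperimentColumn, value):
    if value is None:
        return None
    if col.kind == "json":
        return json.dumps(value, sort_keys=True)
    if col.kind == "number":
        return float(value)
    return str(value)


def _decode(col: ExperimentColumn, value):
    if value is None:
        return None
    if col.kind == "json":
        return json.loads(value)
    return value


class ExperimentStore:
    """Experiment tables attached to a registry store."""

    def __init__(self, store: Store):
        self.store = store
        self._conn = store.connection
        self._conn.execute(
            """CREATE TABLE IF NOT EXISTS experiment_types (
                   name TEXT PRIMARY KEY,
                   definition TEXT NOT NULL
               )"""
        )
        self._conn.execute(
            """CREATE TABLE IF NOT EXISTS experiments (
                   experiment_id TEXT PRIMARY KEY,
                   type_name TEXT NOT NULL REFERENCES experiment_types(name),
                   created_at TEXT NOT NULL DEFAULT (datetime('now'))
               )"""
        )
        self._conn.commit()

    # -- type management ----------------------------------------------

    def define_experiment_type(self, etype: ExperimentType) -> None:
        """Create ``<type>_metadata`` and ``<type>_data`` tables."""
        if self.get_experiment_type(etype.name) is not None:
            raise ValueError(f"experiment type already defined: {etype.name!r}")
        meta_cols = ", ".join(
            f"{c.name} {_KINDS[c.kind]}" for c in etype.metadata_columns
        )
        data_cols = ", ".join(f"{c.name} {_KINDS[c.kind]}" for c in etype.data_columns)
        self._conn.execute(
            f"""CREATE TABLE {etype.name}_metadata (
                    experiment_id TEXT PRIMARY KEY
                        REFERENCES experiments(experiment_id)
                    {"," if meta_cols else ""} {meta_cols}
                )"""
        )
        self._conn.execute(
            f"""CREATE TABLE {etype.name}_data (
                    experiment_id TEXT NOT NULL
                        REFERENCES experiments(experiment_id),
                    molregno INTEGER NOT NULL REFERENCES molecules(molregno),
                    conf_id INTEGER,
                    {data_cols}
                )"""
        )
        self._conn.execute(
            "INSERT INTO experiment_types (name, definition) VALUES (?, ?)",
            (etype.name, etype.to_json()),
        )
        self._conn.commit()

    def get_experiment_type(self, name: str) -> Optional[ExperimentType]:
        row = self._conn.execute(
            "SELECT definition FROM experiment_types WHERE name = ?", (name,)
        ).fetchone()
        return None if row is None else ExperimentType.from_json(row[0])

    def experiment_types(self) -> List[str]:
        return [
            r[0]
            for r in self._conn.execute(
                "SELECT name FROM experiment_types ORDER BY name"
            )
        ]

    # -- recording ----------------------------------------------------

    def record_experiment(
        self,
        type_name: str,
        metadata: Dict,
        experiment_id: Optional[str] = None,
    ) -> str:
        """Persist one experiment's metadata; returns its UUID key.

        A fresh random (v4) UUID is generated unless the caller supplies
        one (e.g. for reproducible pipelines). All declared metadata
        columns must be present.
        """
        etype = self.get_experiment_type(type_name)
        if etype is None:
            raise ValueError(f"undefined experiment type: {type_name!r}")
        missing = [c.name for c in etype.metadata_columns if c.name not in metadata]
        if missing:
            raise ValueError(f"missing metadata column(s): {missing}")
        extra = set(metadata) - {c.name for c in etype.metadata_columns}
        if extra:
            raise ValueError(f"undeclared metadata column(s): {sorted(extra)}")
        exp_id = experiment_id or str(uuid.uuid4())
        self._conn.execute(
            "INSERT INTO experiments (experiment_id, type_name) VALUES (?, ?)",
            (exp_id, type_name),
        )
        cols = list(etype.metadata_columns)
        names = ", ".join(["experiment_id"] + [c.name for c in cols])
        marks = ", ".join(["?"] * (1 + len(cols)))
        self._conn.execute(
            f"INSERT INTO {type_name}_metadata ({names}) VALUES ({marks})",
            [exp_id] + [_encode(c, metadata[c.name]) for c in cols],
        )
        self._conn.commit()
        return exp_id

    def record_results(self, experiment_id: str, rows: Sequence[Dict]) -> int:
        """Persist result rows for an experiment; returns the row count.

        Each row must carry ``molregno`` (registered) and the declared
        data columns; ``conf_id`` is optional. The whole batch is
        validated before anything is written, so a bad row never leaves
        a partial write.
        """
        row0 = self._conn.execute(
            "SELECT type_name FROM experiments WHERE experiment_id = ?",
            (experiment_id,),
        ).fetchone()
        if row0 is None:
            raise NotRegisteredError(f"unknown experiment_id: {experiment_id!r}")
        etype = self.get_experiment_type(row0[0])

        prepared = []
        for i, row in enumerate(rows):
            if "molregno" not in row:
                raise ValueError(f"result row {i} is missing molregno")
            molregno = row["molregno"]
            if not self.store.molregno_exists(molregno):
                raise NotRegisteredError(
                    f"result row {i}: molregno {molregno} is not registered"
                )
            missing = [c.name for c in etype.data_columns if c.name not in row]
            if missing:
                raise ValueError(f"result row {i} is missing column(s): {missing}")
            prepared.append(
                [experiment_id, molregno, row.get("conf_id")]
                + [_encode(c, row[c.name]) for c in etype.data_columns]
            )

        names = ", ".join(
            ["experiment_id", "molregno", "conf_id"]
            + [c.name for c in etype.data_columns]
        )
        marks = ", ".join(["?"] * (3 + len(etype.data_columns)))
        self._conn.executemany(
            f"INSERT INTO {etype.name}_data ({names}) VALUES ({marks})", prepared
        )
        self._conn.commit()
        return len(prepared)

    # -- retrieval ----------------------------------------------------

    def fetch_results(
        self,
        type_name: str,
        where: Optional[Callable[[Dict], bool]] = None,
    ) -> List[Dict]:
        """Joined result rows: metadata + datum + canonical structure.

        Every row carries its experiment's metadata columns, the datum
        columns, ``experiment_id``, ``molregno``, ``conf_id`` and the
        molecule's ``canonical_smiles`` resolved through the registry.
        ``where`` is an optional predicate applied to each joined row.
        """
        etype = self.get_experiment_type(type_name)
        if etype is None:
            raise ValueError(f"undefined experiment type: {type_name!r}")
        meta_cols = [c.name for c in etype.metadata_columns]
        data_cols = [c.name for c in etype.data_columns]
        meta_sel = "".join(f", m.{c}" for c in meta_cols)
        data_sel = "".join(f", d.{c}" for c in data_cols)
        sql = (
            f"SELECT d.experiment_id, d.molregno, d.conf_id,"
            f" mol.canonical_smiles{meta_sel}{data_sel}"
            f" FROM {type_name}_data d"
            f" JOIN {type_name}_metadata m ON m.experiment_id = d.experiment_id"
            f" JOIN molecules mol ON mol.molregno = d.molregno"
            f" ORDER BY d.rowid"
        )
        out = []
        for r in self._conn.execute(sql):
            row = {
                "experiment_id": r[0],
                "molregno": r[1],
                "conf_id": r[2],
                "canonical_smiles": r[3],
            }
            offset = 4
            for c in etype.metadata_columns:
                row[c.name] = _decode(c, r[offset])
                offset += 1
            for c in etype.data_columns:
                row[c.name] = _decode(c, r[offset])
                offset += 1
            if where is None or where(row):
                out.append(row)
        return out

    def fetch_results_csv(
        self,
        type_name: str,
        where: Optional[Callable[[Dict], bool]] = None,
    ) -> str:
        """:func:`fetch_results` rendered as CSV text."""
        rows = self.fetch_results(type_name, where)
        buf = io.StringIO()
        if not rows:
            return ""
        writer = csv.DictWriter(buf, fieldnames=list(rows[0]))
        writer.writeheader()
        for row in rows:
            writer.writerow(
                {
                    k: json.dumps(v, sort_keys=True) if isinstance(v, (dict, list)) else v
                    for k, v in row.items()
                }
            )
        return buf.getvalue()
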
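"""Experiment tables: UUID linkage, schema duality, joined retrieval."""

import uuid

import pytest

from molregistry import (
    ExperimentColumn,
    ExperimentStore,
    ExperimentType,
    NotRegisteredError,
)

JSON_ONLY = ExperimentType(
    "generic",
    metadata_columns=(ExperimentColumn("metadata", "json"),),
    data_columns=(ExperimentColumn("payload", "json"),),
)

COLUMNED = ExperimentType(
    "binding_assay",
    metadata_columns=(
        ExperimentColumn("protocol", "text"),
        ExperimentColumn("temperature_k", "number"),
    ),
    data_columns=(
        ExperimentColumn("ic50_nm", "number"),
        ExperimentColumn("operator", "text"),
    ),
)


@pytest.fixture
def expstore(registry):
    registry.bulk_register(["CCO", "CCN", "CCS"])
    return ExperimentStore(registry.store)


class TestTypes:
    def test_json_only_shape(self, expstore):
        expstore.define_experiment_type(JSON_ONLY)
        assert "generic" in expstore.experiment_types()

    def test_fully_columned_shape(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        etype = expstore.get_experiment_type("binding_assay")
        assert all(c.kind != "json" for c in etype.metadata_columns)
        assert all(c.kind != "json" for c in etype.data_columns)

    def test_duplicate_name_rejected(self, expstore):
        expstore.define_experiment_type(JSON_ONLY)
        with pytest.raises(ValueError, match="already defined"):
            expstore.define_experiment_type(JSON_ONLY)

    def test_type_definition_validation(self):
        with pytest.raises(ValueError):
            ExperimentType("x", (), ())  # no data columns
        with pytest.raises(ValueError):
            ExperimentColumn("drop table", "text")
        with pytest.raises(ValueError):
            ExperimentColumn("molregno", "number")  # reserved
        with pytest.raises(ValueError):
            ExperimentColumn("a", "blob")

    def test_type_json_round_trip(self):
        assert ExperimentType.from_json(COLUMNED.to_json()) == COLUMNED


class TestRecording:
    def test_distinct_uuids(self, expstore):
        expstore.define_experiment_type(JSON_ONLY)
        e1 = expstore.record_experiment("generic", {"metadata": {"run": 1}})
        e2 = expstore.record_experiment("generic", {"metadata": {"run": 2}})
        assert e1 != e2
        uuid.UUID(e1), uuid.UUID(e2)  # both are real UUIDs

    def test_json_metadata_round_trips(self, expstore):
        expstore.define_experiment_type(JSON_ONLY)
        payload = {"solvent": "water", "replicates": [1, 2, 3], "ph": 7.4}
        eid = expstore.record_experiment("generic", {"metadata": payload})
        expstore.record_results(eid, [{"molregno": 1, "payload": None}])
        row = expstore.fetch_results("generic")[0]
        assert row["metadata"] == payload

    def test_missing_metadata_column(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        with pytest.raises(ValueError, match="missing metadata"):
            expstore.record_experiment("binding_assay", {"protocol": "p"})

    def test_undefined_type(self, expstore):
        with pytest.raises(ValueError, match="undefined experiment type"):
            expstore.record_experiment("nope", {})

    def test_record_results_count(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        eid = expstore.record_experiment(
            "binding_assay", {"protocol": "p1", "temperature_k": 298.0}
        )
        rows = [
            {"molregno": 1, "ic50_nm": 12.5, "operator": "a"},
            {"molregno": 2, "ic50_nm": 3.0, "operator": "a"},
            {"molregno": 3, "ic50_nm": 700.0, "operator": "b"},
        ]
        assert expstore.record_results(eid, rows) == 3

    def test_unregistered_molregno_rejected_atomically(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        eid = expstore.record_experiment(
            "binding_assay", {"protocol": "p1", "temperature_k": 298.0}
        )
        rows = [
            {"molregno": 1, "ic50_nm": 1.0, "operator": "a"},
            {"molregno": 999, "ic50_nm": 2.0, "operator": "a"},
        ]
        with pytest.raises(NotRegisteredError):
            expstore.record_results(eid, rows)
        assert expstore.fetch_results("binding_assay") == []

    def test_unknown_experiment_id(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        with pytest.raises(NotRegisteredError):
            expstore.record_results(str(uuid.uuid4()), [])

    def test_conformer_linkage(self, conformer_registry):
        from molregistry import fixtures as fx

        res = conformer_registry.register(
            fx.embedded_3d_molblock("CCO", seed=3), fmt="molblock"
        )
        es = ExperimentStore(conformer_registry.store)
        es.define_experiment_type(JSON_ONLY)
        eid = es.record_experiment("generic", {"metadata": {}})
        es.record_results(
            eid,
            [{"molregno": res.molregno, "conf_id": res.conf_id, "payload": {"e": -1.5}}],
        )
        row = es.fetch_results("generic")[0]
        assert (row["molregno"], row["conf_id"]) == (res.molregno, res.conf_id)


class TestFetch:
    def _populate(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        eid = expstore.record_experiment(
            "binding_assay", {"protocol": "p1", "temperature_k": 298.0}
        )
        rows = [
            {"molregno": 1, "ic50_nm": 12.5, "operator": "a"},
            {"molregno": 2, "ic50_nm": 3.0, "operator": "a"},
            {"molregno": 3, "ic50_nm": 700.0, "operator": "b"},
        ]
        expstore.record_results(eid, rows)
        return eid, rows

    def test_rows_carry_structures(self, expstore):
        self._populate(expstore)
        rows = expstore.fetch_results("binding_assay")
        assert [r["canonical_smiles"] for r in rows] == ["CCO", "CCN", "CCS"]
        assert all(r["protocol"] == "p1" for r in rows)

    def test_filter_matches_linear_scan_oracle(self, expstore):
        _, raw = self._populate(expstore)
        threshold = 12.5
        got = expstore.fetch_results(
            "binding_assay", where=lambda r: r["ic50_nm"] <= threshold
        )
        expected = [r["molregno"] for r in raw if r["ic50_nm"] <= threshold]
        assert [r["molregno"] for r in got] == expected

    def test_numeric_round_trip_exact(self, expstore):
        expstore.define_experiment_type(JSON_ONLY)
        eid = expstore.record_experiment("generic", {"metadata": {}})
        expstore.record_results(eid, [{"molregno": 1, "payload": 0.1 + 0.2}])
        assert expstore.fetch_results("generic")[0]["payload"] == 0.1 + 0.2

    def test_empty_type_fetch(self, expstore):
        expstore.define_experiment_type(COLUMNED)
        assert expstore.fetch_results("binding_assay") == []

    def test_schema_duality(self, expstore):
        """The same logical experiment through both shapes yields equal content."""
        expstore.define_experiment_type(COLUMNED)
        expstore.define_experiment_type(
            ExperimentType(
                "binding_assay_json",
                metadata_columns=(ExperimentColumn("metadata", "json"),),
                data_columns=(ExperimentColumn("payload", "json"),),
            )
        )
        meta = {"protocol": "p1", "temperature_k": 298.0}
        data = [
            {"molregno": 1, "ic50_nm": 12.5, "operator": "a"},
            {"molregno": 2, "ic50_nm": 3.0, "operator": "b"},
        ]
        e1 = expstore.record_experiment("binding_assay", meta)
        expstore.record_results(e1, data)
        e2 = expstore.record_experiment("binding_assay_json", {"metadata": meta})
        expstore.record_results(
            e2,
            [
                {
                    "molregno": r["molregno"],
                    "payload": {"ic50_nm": r["ic50_nm"], "operator": r["operator"]},
                }
                for r in data
            ],
        )
        cols = expstore.fetch_results("binding_assay")
        js = expstore.fetch_results("binding_assay_json")
        for c, j in zip(cols, js):
            assert c["molregno"] == j["molregno"]
            assert c["canonical_smiles"] == j["canonical_smiles"]
            assert {"ic50_nm": c["ic50_nm"], "operator": c["operator"]} == j["payload"]
            assert {"protocol": c["protocol"], "temperature_k": c["temperature_k"]} \
                == j["metadata"]

    def test_csv_export(self, expstore):
        self._populate(expstore)
        csv_text = expstore.fetch_results_csv("binding_assay")
        lines = csv_text.strip().splitlines()
        assert lines[0].startswith("experiment_id,molregno,conf_id,canonical_smiles")
        assert len(lines) == 4
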
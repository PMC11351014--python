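"""Registration facade: register / bulk_register / query / retrieve flows."""

import random

import numpy as np
import pytest
from rdkit import Chem

from molregistry import (
    LAYER_ORDER,
    NO_STEREO_SMILES,
    TAUTOMER_HASH,
    NotRegisteredError,
    combine_layers,
    compute_layers,
)
from molregistry import fixtures as fx
from molregistry.registry import DUPLICATE, PARSE_ERROR, REGISTERED, REJECTED, split_sdf


class TestRegister:
    def test_first_registration_gets_molregno_one(self, registry):
        res = registry.register("CCO")
        assert (res.status, res.molregno, res.conf_id) == (REGISTERED, 1, None)

    def test_equivalent_serialization_is_duplicate(self, registry):
        registry.register("CCO")
        res = registry.register("OCC")
        assert (res.status, res.molregno) == (DUPLICATE, 1)

    def test_unparsable_input(self, registry):
        assert registry.register("not-a-molecule((").status == PARSE_ERROR

    def test_filter_rejection_names_step(self, tmp_path):
        from molregistry import Registry, SystemConfig

        reg = Registry.init(
            str(tmp_path / "f.db"),
            config=SystemConfig(
                standardization=("sanitize", "filter_polymer_sgroup")
            ),
        )
        block = dict(fx.pathological_molblocks())["sru_polymer"]
        res = reg.register(block, fmt="molblock")
        assert res.status == REJECTED
        assert "filter_polymer_sgroup" in res.detail

    def test_registration_stores_submission_and_record(self, registry):
        block = Chem.MolToMolBlock(Chem.MolFromSmiles("CCN"))
        res = registry.register(block, fmt="molblock")
        assert registry.retrieve([res.molregno], mode="as_registered")[
            res.molregno
        ] == block
        rec = registry.store.get_standardization(res.molregno)
        assert rec["applied"] == ["sanitize"]

    def test_idempotent_duplicates(self, registry):
        first = registry.register("c1ccccc1").molregno
        for _ in range(3):
            res = registry.register("c1ccccc1")
            assert (res.status, res.molregno) == (DUPLICATE, first)
        assert registry.store.count_molecules() == 1


class TestBulkRegister:
    def test_in_order_results(self, registry):
        results = registry.bulk_register(["CCO", "OCC", "CCN"])
        assert [(r.status, r.molregno) for r in results] == [
            (REGISTERED, 1),
            (DUPLICATE, 1),
            (REGISTERED, 2),
        ]

    def test_bad_entry_does_not_abort_batch(self, registry):
        results = registry.bulk_register(["CCO", "((bad", "CCN"])
        assert [r.status for r in results] == [REGISTERED, PARSE_ERROR, REGISTERED]
        assert registry.store.count_molecules() == 2

    def test_hundred_distinct_molecules(self, registry):
        smiles = fx.random_molecules(100, seed=19)
        results = registry.bulk_register(smiles)
        assert all(r.status == REGISTERED for r in results)
        assert [r.molregno for r in results] == list(range(1, 101))
        # independent uniqueness oracle: count distinct combined digests
        digests = {
            combine_layers(compute_layers(Chem.MolFromSmiles(s))) for s in smiles
        }
        assert len(digests) == 100

    def test_sdf_bulk(self, registry):
        sdf = "".join(
            fx.embedded_3d_molblock(s, seed=1) + "$$$$\n" for s in ("CCO", "CCN")
        )
        assert len(split_sdf(sdf)) == 2
        results = registry.bulk_register_sdf(sdf)
        assert [r.status for r in results] == [REGISTERED, REGISTERED]


class TestQuery:
    def test_unregistered_returns_empty(self, registry):
        assert registry.query("c1ccncc1") == []

    def test_register_then_query_consistency(self, registry):
        for smiles in fx.random_molecules(20, seed=29):
            molregno = registry.register(smiles).molregno
            assert registry.query(smiles) == [molregno]

    def test_tautomer_layer_unites_tautomers(self, registry):
        t1, t2 = fx.tautomer_pairs()[0]
        m1 = registry.register(t1).molregno
        m2 = registry.register(t2).molregno
        assert registry.query(t1) == [m1]
        assert registry.query(t1, layers={TAUTOMER_HASH}) == sorted([m1, m2])

    def test_stereo_layer_unites_stereoisomers(self, registry):
        a, b = fx.stereo_pairs()[0]
        ma = registry.register(a).molregno
        mb = registry.register(b).molregno
        assert registry.query(a, layers={NO_STEREO_SMILES}) == sorted([ma, mb])

    def test_layer_subset_monotonicity(self, registry):
        for a, b in fx.stereo_pairs() + fx.tautomer_pairs():
            registry.register(a)
            registry.register(b)
        rng = random.Random(31)
        for a, _ in fx.stereo_pairs():
            full = set(registry.query(a))
            subset = set(LAYER_ORDER)
            while len(subset) > 1:
                subset.remove(rng.choice(sorted(subset)))
                wider = set(registry.query(a, layers=subset))
                assert full <= wider
                full = wider

    def test_escape_partitioning(self, registry):
        ma = registry.register("CCO", escape="batch-A").molregno
        mb = registry.register("CCO", escape="batch-B").molregno
        assert ma != mb
        assert registry.query("CCO", escape="batch-A") == [ma]
        assert registry.query("CCO", escape="batch-B") == [mb]
        # without the escape layer both are the same structure
        no_escape = set(LAYER_ORDER) - {"ESCAPE"}
        assert registry.query("CCO", layers=no_escape) == sorted([ma, mb])

    def test_rejected_query_returns_empty(self, tmp_path):
        from molregistry import Registry, SystemConfig

        reg = Registry.init(
            str(tmp_path / "q.db"),
            config=SystemConfig(standardization=("sanitize", "filter_polymer_sgroup")),
        )
        reg.register("CCO")
        block = dict(fx.pathological_molblocks())["sru_polymer"]
        assert reg.query(block, fmt="molblock") == []

    def test_unparsable_query_raises(self, registry):
        with pytest.raises(ValueError):
            registry.query("((nope")


class TestConformerMode:
    def test_first_conformer_registration(self, conformer_registry):
        block = fx.embedded_3d_molblock("CCO", seed=3)
        res = conformer_registry.register(block, fmt="molblock")
        assert (res.status, res.molregno, res.conf_id) == (REGISTERED, 1, 1)

    def test_new_pose_of_known_molecule(self, conformer_registry):
        b1 = fx.embedded_3d_molblock("CCO", seed=3)
        conformer_registry.register(b1, fmt="molblock")
        # translate the conformer: same molecule, different pose
        mol = Chem.MolFromMolBlock(b1, removeHs=False)
        conf = mol.GetConformer()
        for i in range(mol.GetNumAtoms()):
            p = conf.GetAtomPosition(i)
            conf.SetAtomPosition(i, (p.x + 1.0, p.y, p.z))
        res = conformer_registry.register(Chem.MolToMolBlock(mol), fmt="molblock")
        assert (res.status, res.molregno, res.conf_id) == (REGISTERED, 1, 2)

    def test_atom_permuted_pose_is_duplicate(self, conformer_registry):
        b1 = fx.embedded_3d_molblock("CCO", seed=3)
        conformer_registry.register(b1, fmt="molblock")
        mol = Chem.MolFromMolBlock(b1, removeHs=False)
        order = list(range(mol.GetNumAtoms()))[::-1]
        permuted = Chem.RenumberAtoms(mol, order)
        res = conformer_registry.register(Chem.MolToMolBlock(permuted), fmt="molblock")
        assert (res.status, res.molregno, res.conf_id) == (DUPLICATE, 1, 1)

    def test_query_by_conformer(self, conformer_registry):
        block = fx.embedded_3d_molblock("CCN", seed=5)
        res = conformer_registry.register(block, fmt="molblock")
        assert conformer_registry.query(block, fmt="molblock") == [
            (res.molregno, res.conf_id)
        ]

    def test_molecule_only_input_still_registers(self, conformer_registry):
        res = conformer_registry.register("CCO")
        assert (res.status, res.molregno, res.conf_id) == (REGISTERED, 1, None)

    def test_query_conformers_mapping(self, conformer_registry):
        conformer_registry.register(fx.embedded_3d_molblock("CCO", seed=3),
                                    fmt="molblock")
        conformer_registry.register("CCN")
        out = conformer_registry.query_conformers([1, 2])
        assert out == {1: [1], 2: []}
        with pytest.raises(NotRegisteredError):
            conformer_registry.query_conformers([99])

    def test_query_conformers_requires_mode(self, registry):
        with pytest.raises(ValueError):
            registry.query_conformers([1])


class TestRetrieve:
    def test_hashes_mode(self, registry):
        registry.register("CCO")
        payload = registry.retrieve([1], mode="hashes")[1]
        assert payload["FORMULA"] == "C2H6O"
        assert len(payload["FULL_HASH"]) == 40

    def test_standardized_reparses_to_stored_canonical_smiles(self, registry):
        for smiles in fx.random_molecules(10, seed=37):
            molregno = registry.register(smiles).molregno
            block = registry.retrieve([molregno])[molregno]
            assert "V3000" in block
            reparsed = Chem.MolFromMolBlock(block)
            layers = registry.store.get_layers(molregno)
            assert compute_layers(reparsed).canonical_smiles == layers.canonical_smiles

    def test_conformer_coordinates_round_trip(self, conformer_registry):
        block = fx.embedded_3d_molblock("CCO", seed=3)
        res = conformer_registry.register(block, fmt="molblock")
        ident = (res.molregno, res.conf_id)
        out = conformer_registry.retrieve([ident])[ident]
        original = Chem.MolFromMolBlock(block, removeHs=False).GetConformer().GetPositions()
        recovered = Chem.MolFromMolBlock(out, removeHs=False).GetConformer().GetPositions()
        assert np.abs(original - recovered).max() < 1e-4
        # the store itself keeps full precision
        stored = conformer_registry.store.get_conformer(*ident)
        assert np.abs(stored.as_array() - original).max() == 0.0

    def test_unknown_id_raises_with_offender(self, registry):
        registry.register("CCO")
        with pytest.raises(NotRegisteredError, match="7"):
            registry.retrieve([1, 7])

    def test_unknown_mode(self, registry):
        with pytest.raises(ValueError):
            registry.retrieve([1], mode="everything")
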
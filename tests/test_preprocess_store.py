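"""Preprocessing pipeline and on-disk store behaviour."""

import zipfile

import pytest

from vsegdb import store
from vsegdb.errors import ConflictError, ContractError, NotFoundError, VsegError
from vsegdb.models import EntryKey, ExtraData
from vsegdb.preprocess import (
    InputSpec,
    apply_extra_data,
    build_metadata,
    preprocess_entry,
    remove_entry,
    seed_annotations,
)

from conftest import KEY_1273, KEY_1832, KEY_EMPIAR, KEY_IDR, build_protocol_db


class TestInputSpec:
    def test_unknown_kind_rejected(self):
        with pytest.raises(VsegError, match="unknown input kind"):
            InputSpec(path="x", kind="bogus")

    def test_extra_data_must_be_first(self, tmp_path):
        specs = [InputSpec("a.map", "map"), InputSpec("e.json", "extra_data")]
        with pytest.raises(VsegError, match="first"):
            preprocess_entry(specs, EntryKey("emdb", "e"), tmp_path / "w",
                             tmp_path / "db")


class TestSeedAnnotations:
    def test_mask_labels_get_generic_names(self, input_files):
        from vsegdb.io import read_mask

        seg = read_mask(input_files["mask_1"])
        ann = seed_annotations(KEY_1273, [], [seg], [], [])
        names = {d.name for d in ann.descriptions.values()}
        assert names == {"Segment 1"}
        assert ann.segment_annotations[0].color  # palette color assigned

    def test_sff_biology_passes_through_unchanged(self, input_files):
        from vsegdb.io import read_sff

        lats, meshes, (descs, sas) = read_sff(input_files["sff_1832"])
        ann = seed_annotations(KEY_1832, [], lats, [], meshes, descs, sas)
        cmg = [d for d in ann.descriptions.values() if d.name == "CMG"]
        assert len(cmg) == 1
        assert not any(d.name == "Segment 1" for d in ann.descriptions.values())

    def test_geometric_gets_entry_level_description(self, input_files):
        from vsegdb.io import load_geometric_json

        seg = load_geometric_json(input_files["geom_ribosomes"])
        ann = seed_annotations(KEY_EMPIAR, [], [], [seg], [])
        desc = ann.descriptions["desc-ribosomes"]
        assert desc.target.segmentation_id == "ribosomes"
        assert desc.target.segment_id is None


class TestExtraData:
    def test_voxel_size_override_propagates_to_metadata(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_EMPIAR)
        levels = meta.document["volumes"]["sampling_levels"]
        assert levels["1"]["voxel_size"] == [7.84, 7.84, 7.84]
        # coarser levels scale with the factor
        for f, rec in levels.items():
            assert rec["voxel_size"] == [7.84 * int(f)] * 3

    def test_custom_segment_ids_mapping_renames_description(self, input_files):
        from vsegdb.io import read_mask

        seg = read_mask(input_files["mask_1"])
        seg.segmentation_id = "TS_026.labels"
        ann = seed_annotations(KEY_1273, [], [seg], [], [])
        extra = ExtraData.model_validate({"segmentation": {
            "custom_segment_ids_mapping": {"TS_026.labels": {"1": "cytoplasm"}}}})
        apply_extra_data([], [seg], ann, extra)
        assert ann.descriptions["desc-TS_026.labels-1"].name == "cytoplasm"

    def test_unknown_mapping_reference_warns_not_fails(self, input_files):
        from vsegdb.io import read_mask

        seg = read_mask(input_files["mask_1"])
        ann = seed_annotations(KEY_1273, [], [seg], [], [])
        extra = ExtraData.model_validate({"segmentation": {
            "custom_segment_ids_mapping": {"nope": {"1": "x"}}}})
        with pytest.warns(UserWarning, match="unknown segmentation"):
            apply_extra_data([], [seg], ann, extra)

    def test_empty_extra_data_is_identity(self, input_files, tmp_path):
        specs = [InputSpec(input_files["map_1273"], "map")]
        key = EntryKey("emdb", "plain")
        preprocess_entry(specs, key, tmp_path / "w", tmp_path / "a")
        (tmp_path / "empty.json").write_text("{}")
        specs2 = [InputSpec(tmp_path / "empty.json", "extra_data")] + specs
        preprocess_entry(specs2, key, tmp_path / "w", tmp_path / "b")
        for name in ("metadata.json", "annotations.json"):
            assert (store.entry_dir(tmp_path / "a", key) / name).read_bytes() \
                == (store.entry_dir(tmp_path / "b", key) / name).read_bytes()


class TestPreprocessEntry:
    def test_map_plus_sff_inventory(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_1832)
        assert meta.channel_ids == ["0"]
        assert meta.volume_time_indices == [0]
        assert len(meta.lattice_inventory()) == 1

    def test_five_masks_make_five_lattices(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_1273)
        inv = meta.lattice_inventory()
        assert len(inv) == 5
        assert [r["segmentation_id"] for r in inv] == [
            f"emd_1273_msk_{i}" for i in range(1, 6)]

    def test_duplicate_key_refused_and_first_intact(self, input_files,
                                                    tmp_path):
        key = EntryKey("emdb", "dup")
        specs = [InputSpec(input_files["map_1273"], "map")]
        preprocess_entry(specs, key, tmp_path / "w", tmp_path / "db")
        before = (store.entry_dir(tmp_path / "db", key)
                  / "metadata.json").read_bytes()
        with pytest.raises(ConflictError, match="already exists"):
            preprocess_entry(specs, key, tmp_path / "w", tmp_path / "db")
        after = (store.entry_dir(tmp_path / "db", key)
                 / "metadata.json").read_bytes()
        assert before == after

    def test_determinism_byte_identical_json(self, input_files, tmp_path):
        key = EntryKey("emdb", "emd-1273")
        specs = [InputSpec(input_files["map_1273"], "map")] + [
            InputSpec(input_files[f"mask_{i}"], "mask") for i in range(1, 6)]
        for sub in ("a", "b"):
            preprocess_entry(specs, key, tmp_path / "w", tmp_path / sub)
        for name in ("metadata.json", "annotations.json", "data.zip"):
            assert (store.entry_dir(tmp_path / "a", key) / name).read_bytes() \
                == (store.entry_dir(tmp_path / "b", key) / name).read_bytes()

    def test_reader_error_leaves_no_entry(self, input_files, tmp_path):
        bad = tmp_path / "broken.map"
        bad.write_bytes(b"\x00" * 64)
        key = EntryKey("emdb", "broken")
        with pytest.raises(VsegError):
            preprocess_entry([InputSpec(input_files["map_1273"], "map"),
                              InputSpec(bad, "map")],
                             key, tmp_path / "w", tmp_path / "db")
        assert not store.entry_exists(tmp_path / "db", key)

    def test_remove_entry(self, input_files, tmp_path):
        db = tmp_path / "db"
        key1 = EntryKey("emdb", "one")
        key2 = EntryKey("emdb", "two")
        specs = [InputSpec(input_files["map_1273"], "map")]
        preprocess_entry(specs, key1, tmp_path / "w", db)
        preprocess_entry(specs, key2, tmp_path / "w", db)
        remove_entry(db, key1)
        left = [k.entry_id for k in store.list_entries(db)]
        assert left == ["two"]
        with pytest.raises(NotFoundError):
            remove_entry(db, key1)


class TestStore:
    def test_metadata_inventory_equals_zip_scan(self, protocol_db):
        for key in (KEY_1832, KEY_1273, KEY_IDR, KEY_EMPIAR):
            meta = store.read_metadata(protocol_db, key)
            expected = store.expected_members_from_metadata(meta)
            with zipfile.ZipFile(store.entry_dir(protocol_db, key)
                                 / "data.zip") as zf:
                assert set(zf.namelist()) == expected

    def test_entry_round_trip(self, protocol_db):
        entry = store.read_entry(protocol_db, KEY_1832)
        assert entry.volumes[0].channel_id == "0"
        assert entry.lattices[0].segment_ids == {1}
        # grids survive the MRC round trip exactly at float32 precision
        g1 = entry.volumes[0].frames[0][1]
        assert g1.dims == (24, 24, 24)

    def test_unknown_key_not_found(self, protocol_db):
        with pytest.raises(NotFoundError):
            store.read_entry(protocol_db, EntryKey("emdb", "nope"))

    def test_metadata_only_read_does_not_touch_data_zip(self, input_files,
                                                        tmp_path):
        key = EntryKey("emdb", "zipless")
        preprocess_entry([InputSpec(input_files["map_1273"], "map")], key,
                         tmp_path / "w", tmp_path / "db")
        (store.entry_dir(tmp_path / "db", key) / "data.zip").unlink()
        meta = store.read_metadata(tmp_path / "db", key)
        assert meta.channel_ids == ["0"]

    def test_inconsistent_metadata_is_contract_error(self, input_files,
                                                     tmp_path):
        from vsegdb.io import read_map
        from vsegdb.models import MultiscaleVolume

        grid = read_map(input_files["map_1273"])
        vol = MultiscaleVolume(channel_id="0", frames={0: {1: grid}})
        key = EntryKey("emdb", "bad")
        meta = build_metadata(key, [vol], [], [], [])
        meta.document["volumes"]["channel_ids"] = ["0", "ghost"]
        ann = seed_annotations(key, [vol], [], [], [])
        with pytest.raises(ContractError, match="does not match"):
            store.write_entry(tmp_path / "db", key, [vol], [], [], [], ann,
                              meta)

    def test_listing_sorted_and_filterable(self, protocol_db):
        keys = store.list_entries(protocol_db)
        # oracle: direct directory scan
        scanned = sorted(
            (src.name, e.name)
            for src in protocol_db.iterdir() if src.is_dir()
            for e in src.iterdir() if (e / "metadata.json").exists())
        assert [(k.source_db, k.entry_id) for k in keys] == scanned
        emdb_only = store.list_entries(protocol_db, "emdb")
        assert {k.source_db for k in emdb_only} == {"emdb"}
        assert store.list_entries(protocol_db) == keys  # stable

    def test_missing_root_warns_and_is_empty(self, tmp_path):
        with pytest.warns(UserWarning, match="does not exist"):
            assert store.list_entries(tmp_path / "nowhere") == []
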
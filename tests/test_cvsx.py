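"""Query resolution, level selection, and CVSX archive round-trips."""

import json
import zipfile

import numpy as np
import pytest

from vsegdb import store
from vsegdb.cvsx import (
    build_cvsx,
    read_cvsx,
    resolve_query,
    select_sampling_level,
)
from vsegdb.errors import NotFoundError, ValidationFailure, VsegError
from vsegdb.io.mrc import read_map_bytes
from vsegdb.models import DEFAULT_MAX_POINTS

from conftest import KEY_1273, KEY_1832, KEY_EMPIAR, KEY_IDR


class TestResolveQuery:
    def test_minimal_query_expands_to_full_inventory(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_IDR)
        sel = resolve_query({"entry_id": KEY_IDR.entry_id,
                             "source_db": "idr"}, meta)
        assert sel["channel_ids"] == ["DAPI", "Hyb probe"]
        assert sel["volume_time_indices"] == [0, 1, 2]
        assert sel["segmentation_kinds"] == [
            "lattice", "mesh", "geometric-segmentation"]
        assert sel["max_points"] == DEFAULT_MAX_POINTS
        assert [r["segmentation_id"] for r in sel["segmentations"]["lattice"]] \
            == ["seg"]

    def test_channel_and_time_restrict_volumes_and_segmentations(
            self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_IDR)
        sel = resolve_query({"entry_id": KEY_IDR.entry_id, "source_db": "idr",
                             "channel_id": "Hyb probe", "time": 2}, meta)
        assert sel["channel_ids"] == ["Hyb probe"]
        assert sel["volume_time_indices"] == [2]
        for rec in sel["segmentations"]["lattice"]:
            assert rec["time_indices"] == [2]

    def test_missing_mandatory_field_named(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_IDR)
        with pytest.raises(VsegError, match="entry_id"):
            resolve_query({}, meta)

    @pytest.mark.parametrize("field,value", [
        ("channel_id", "ghost"), ("time", 99), ("segmentation_id", "ghost")])
    def test_unknown_inventory_values_not_found(self, protocol_db, field,
                                                value):
        meta = store.read_metadata(protocol_db, KEY_IDR)
        with pytest.raises(NotFoundError, match="valid"):
            resolve_query({"entry_id": KEY_IDR.entry_id, "source_db": "idr",
                           field: value}, meta)

    def test_segmentation_kind_and_id_filter(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_EMPIAR)
        sel = resolve_query({
            "entry_id": KEY_EMPIAR.entry_id, "source_db": "empiar",
            "segmentation_kind": "geometric-segmentation",
            "segmentation_id": "ribosomes", "max_points": 10_000_000}, meta)
        assert sel["segmentations"]["lattice"] == []
        assert [r["segmentation_id"] for r in
                sel["segmentations"]["geometric"]] == ["ribosomes"]
        # volumes are not restricted by segmentation filters
        assert sel["channel_ids"] == ["0"]

    def test_resolution_is_deterministic(self, protocol_db):
        meta = store.read_metadata(protocol_db, KEY_IDR)
        raw = {"entry_id": KEY_IDR.entry_id, "source_db": "idr"}
        assert resolve_query(raw, meta) == resolve_query(raw, meta)


class TestSelectSamplingLevel:
    LEVELS_256 = {1: (256, 256, 256), 2: (128, 128, 128), 4: (64, 64, 64),
                  8: (32, 32, 32)}

    def test_ten_million_budget_picks_factor_two(self):
        # 256^3 = 16,777,216 > 1e7 >= 128^3 = 2,097,152
        assert select_sampling_level(self.LEVELS_256, 10_000_000) == 2

    def test_default_budget_picks_full_resolution(self):
        assert select_sampling_level(self.LEVELS_256) == 1

    def test_budget_below_everything_picks_coarsest(self):
        assert select_sampling_level(self.LEVELS_256, 10) == 8

    def test_bracketing_inequality(self):
        for mp in (10 ** k for k in range(2, 9)):
            f = select_sampling_level(self.LEVELS_256, mp)
            count = int(np.prod(self.LEVELS_256[f]))
            if f > 1:
                finer = int(np.prod(self.LEVELS_256[f // 2]))
                assert count <= mp < finer or f == max(self.LEVELS_256)

    def test_monotone_non_increasing_in_budget(self):
        sweep = [select_sampling_level(self.LEVELS_256, mp)
                 for mp in sorted(10 ** k for k in range(1, 13))]
        assert sweep == sorted(sweep, reverse=True)


class TestBuildCvsx:
    def test_minimal_entry_archive_composition(self, protocol_db, tmp_path):
        out = tmp_path / "emd-1832.cvsx"
        build_cvsx(protocol_db, {"entry_id": "emd-1832", "source_db": "emdb"},
                   out)
        with zipfile.ZipFile(out) as zf:
            names = set(zf.namelist())
        payloads = {n for n in names if n.endswith(".map")}
        assert len(payloads) == 2  # one volume + one lattice grid
        assert {"index.json", "query.json", "annotations.json",
                "metadata.json"} <= names

    def test_channel_restricted_archive(self, protocol_db, tmp_path):
        out = tmp_path / "idr.cvsx"
        build_cvsx(protocol_db, {"entry_id": KEY_IDR.entry_id,
                                 "source_db": "idr",
                                 "channel_id": "Hyb probe", "time": 1}, out)
        arc = read_cvsx(out)
        vol_members = [p for p in arc.payloads if p.startswith("volume/")]
        assert vol_members == ["volume/Hyb probe/1/1.map"]
        assert arc.query["requested"]["channel_id"] == "Hyb probe"

    def test_extension_rule_enforced(self, protocol_db, tmp_path):
        with pytest.raises(VsegError, match=r"\.cvsx"):
            build_cvsx(protocol_db,
                       {"entry_id": "emd-1832", "source_db": "emdb"},
                       tmp_path / "x.zip")

    def test_unknown_entry_not_found(self, protocol_db, tmp_path):
        with pytest.raises(NotFoundError):
            build_cvsx(protocol_db, {"entry_id": "ghost", "source_db": "emdb"},
                       tmp_path / "g.cvsx")

    def test_query_json_records_defaults(self, protocol_db, tmp_path):
        out = tmp_path / "q.cvsx"
        build_cvsx(protocol_db, {"entry_id": "emd-1832", "source_db": "emdb"},
                   out)
        with zipfile.ZipFile(out) as zf:
            q = json.loads(zf.read("query.json"))
        assert q["max_points"] == 1_000_000_000_000
        assert q["requested"] == {"entry_id": "emd-1832", "source_db": "emdb",
                                  "max_points": 1_000_000_000_000}


class TestReadCvsx:
    def test_round_trip_reproduces_selected_grids(self, protocol_db, tmp_path):
        out = tmp_path / "rt.cvsx"
        build_cvsx(protocol_db, {"entry_id": "emd-1273", "source_db": "emdb"},
                   out)
        arc = read_cvsx(out)
        entry = store.read_entry(protocol_db, KEY_1273)
        for vol in entry.volumes:
            for t, pyr in vol.frames.items():
                member = store.volume_member(vol.channel_id, t, 1)
                got = read_map_bytes(arc.payloads[member])
                np.testing.assert_allclose(got.values, pyr[1].values,
                                           rtol=1e-6)
        # exactly the resolved subset, no more
        sel = arc.query
        expected_lat = {store.lattice_member(r["segmentation_id"], t, 1)
                        for r in sel["segmentations"]["lattice"]
                        for t in r["time_indices"]}
        got_lat = {p for p in arc.payloads if p.startswith("lattice/")}
        assert got_lat == expected_lat

    def test_missing_query_json_member(self, protocol_db, tmp_path):
        out = tmp_path / "t.cvsx"
        build_cvsx(protocol_db, {"entry_id": "emd-1832", "source_db": "emdb"},
                   out)
        tampered = tmp_path / "t2.cvsx"
        with zipfile.ZipFile(out) as zin, \
                zipfile.ZipFile(tampered, "w") as zout:
            for name in zin.namelist():
                if name != "query.json":
                    zout.writestr(name, zin.read(name))
        with pytest.raises(ValidationFailure, match="query.json"):
            read_cvsx(tampered)

    def test_index_listing_absent_member(self, protocol_db, tmp_path):
        out = tmp_path / "t.cvsx"
        build_cvsx(protocol_db, {"entry_id": "emd-1832", "source_db": "emdb"},
                   out)
        tampered = tmp_path / "t3.cvsx"
        with zipfile.ZipFile(out) as zin, \
                zipfile.ZipFile(tampered, "w") as zout:
            for name in zin.namelist():
                data = zin.read(name)
                if name == "index.json":
                    idx = json.loads(data)
                    idx["members"].append({"path": "volume/ghost/0/1.map",
                                           "role": "volume", "format": "mrc"})
                    data = json.dumps(idx).encode()
                zout.writestr(name, data)
        with pytest.raises(ValidationFailure, match="ghost"):
            read_cvsx(tampered)

    def test_undeclared_member_rejected(self, protocol_db, tmp_path):
        out = tmp_path / "t.cvsx"
        build_cvsx(protocol_db, {"entry_id": "emd-1832", "source_db": "emdb"},
                   out)
        tampered = tmp_path / "t4.cvsx"
        with zipfile.ZipFile(out) as zin, \
                zipfile.ZipFile(tampered, "w") as zout:
            for name in zin.namelist():
                zout.writestr(name, zin.read(name))
            zout.writestr("smuggled.bin", b"\x00")
        with pytest.raises(ValidationFailure, match="smuggled"):
            read_cvsx(tampered)
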
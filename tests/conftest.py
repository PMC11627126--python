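"""Shared fixtures: synthetic input files and pre-built database entries.

The session database emulates the worked entry types at desk scale:

* ``emdb/emd-1832`` — single map + SFF (one channel, one frame, one lattice)
* ``emdb/emd-1273`` — map + five label masks (five lattice segmentations)
* ``idr/idr-13457537`` — OME-Zarr, 2 channels x 3 time frames, with labels
* ``custom/custom-tubhiswt`` — OME-TIFF series, 2 channels x 4 time frames
* ``empiar/empiar-11756`` — zero-cell-header tomogram + extra-data voxel
  override + two STAR-derived geometric segmentations
"""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from vsegdb.fixtures import (
    make_mask_fixture,
    make_multiscale_fixture,
    make_sff_fixture,
    make_star_fixture,
    make_volume_fixture,
)
from vsegdb.io.star import parse_star_to_geometric, write_geometric_json
from vsegdb.models import EntryKey, StarParseConfig
from vsegdb.preprocess import InputSpec, preprocess_entry

KEY_1832 = EntryKey(source_db="emdb", entry_id="emd-1832")
KEY_1273 = EntryKey(source_db="emdb", entry_id="emd-1273")
KEY_IDR = EntryKey(source_db="idr", entry_id="idr-13457537")
KEY_TUB = EntryKey(source_db="custom", entry_id="custom-tubhiswt")
KEY_EMPIAR = EntryKey(source_db="empiar", entry_id="empiar-11756")

#: First printed STAR parsing parameter set of the tomogram workflow.
STAR_CONFIG_RIBOSOMES = dict(sphere_radius=100.0, segmentation_id="ribosomes",
                             sphere_color_hex="FFFF00", pixel_size=7.84,
                             star_file_coordinate_divisor=4)


def build_inputs(root: Path) -> dict[str, Path]:
    """All raw input fixtures under one directory."""
    root.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["map_1832"] = make_volume_fixture(
        dims=(24, 24, 24), voxel_size=(2.8, 2.8, 2.8),
        out_path=root / "emd_1832.map", seed=11)
    paths["sff_1832"] = make_sff_fixture(
        root / "emd_1832.hff", dims=(24, 24, 24), segment_names=("CMG",),
        voxel_size=(2.8, 2.8, 2.8), seed=12)
    paths["map_1273"] = make_volume_fixture(
        dims=(20, 20, 20), voxel_size=(5.5, 5.5, 5.5),
        out_path=root / "emd_1273.map", seed=13)
    for i in range(1, 6):
        paths[f"mask_{i}"] = make_mask_fixture(
            dims=(20, 20, 20), n_segments=1, seed=20 + i,
            out_path=root / f"emd_1273_msk_{i}.map", voxel_size=(5.5, 5.5, 5.5))
    paths["zarr"] = make_multiscale_fixture(
        root / "13457537.zarr", flavor="omezarr", axes="tczyx",
        shape=(3, 2, 8, 16, 16), channel_labels=["DAPI", "Hyb probe"],
        unit="micrometer", scale=0.5, with_labels=True, seed=31)
    paths["tiff_first"] = make_multiscale_fixture(
        root / "tubhiswt.ome.tif", flavor="ometiff-series", axes="tczyx",
        shape=(4, 2, 4, 8, 8), unit="micrometer", scale=0.2, seed=41)
    paths["tomo"] = make_volume_fixture(
        dims=(48, 48, 24), cella_zero=True, out_path=root / "tomo_35.map",
        seed=51)
    paths["star_ribosomes"] = make_star_fixture(
        n_rows=12, out_path=root / "rln_ribosome_bin1.star", seed=52)
    paths["star_nucleosomes"] = make_star_fixture(
        n_rows=8, out_path=root / "rln_nucleosome_bin1.star", seed=53)
    geom1 = parse_star_to_geometric(
        paths["star_ribosomes"], StarParseConfig(**STAR_CONFIG_RIBOSOMES))
    paths["geom_ribosomes"] = write_geometric_json(
        geom1, root / "geometric_segmentation_input_1.json")
    geom2 = parse_star_to_geometric(
        paths["star_nucleosomes"],
        StarParseConfig(sphere_radius=100.0, segmentation_id="nucleosomes",
                        sphere_color_hex="FF0000", pixel_size=7.84,
                        star_file_coordinate_divisor=4))
    paths["geom_nucleosomes"] = write_geometric_json(
        geom2, root / "geometric_segmentation_input_2.json")
    paths["extra_data"] = root / "empiar-extra-data.json"
    paths["extra_data"].write_text(json.dumps(
        {"volume": {"voxel_size": [7.84, 7.84, 7.84]}}, indent=2))
    return paths


def build_protocol_db(db: Path, work: Path, paths: dict[str, Path]) -> None:
    preprocess_entry([InputSpec(paths["map_1832"], "map"),
                      InputSpec(paths["sff_1832"], "sff")],
                     KEY_1832, work, db)
    preprocess_entry([InputSpec(paths["map_1273"], "map")]
                     + [InputSpec(paths[f"mask_{i}"], "mask")
                        for i in range(1, 6)],
                     KEY_1273, work, db)
    preprocess_entry([InputSpec(paths["zarr"], "omezarr")], KEY_IDR, work, db)
    preprocess_entry([InputSpec(paths["tiff_first"], "ometiff_image")],
                     KEY_TUB, work, db)
    preprocess_entry([InputSpec(paths["extra_data"], "extra_data"),
                      InputSpec(paths["tomo"], "map"),
                      InputSpec(paths["geom_ribosomes"],
                                "geometric_segmentation"),
                      InputSpec(paths["geom_nucleosomes"],
                                "geometric_segmentation")],
                     KEY_EMPIAR, work, db)


@pytest.fixture(scope="session")
def input_files(tmp_path_factory) -> dict[str, Path]:
    return build_inputs(tmp_path_factory.mktemp("inputs"))


@pytest.fixture(scope="session")
def protocol_db(tmp_path_factory, input_files) -> Path:
    """A read-only database holding all five emulated entries."""
    db = tmp_path_factory.mktemp("db")
    work = tmp_path_factory.mktemp("work")
    build_protocol_db(db, work, input_files)
    return db
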
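"""EMDB-SFF (.hff, HDF5) segmentation reader.

Follows the SFF structure — a ``lattice_list`` of label grids, a
``segment_list`` whose segments carry a ``biological_annotation``
(name/description), a ``colour``, and either a ``three_d_volume`` reference
(lattice id + voxel value) or a ``mesh_list`` of triangle meshes.  Segment
names/colors become Description / SegmentAnnotation records so curated
biology in the source file survives preprocessing untouched.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import h5py
import numpy as np

from ..errors import FormatError, UnsupportedFeatureError
from ..models import (
    Description,
    DescriptionTarget,
    LabelGrid,
    LatticeSegmentation,
    MeshSegmentation,
    SegmentAnnotation,
)


def _read_str(group: h5py.Group, name: str) -> str | None:
    if name not in group:
        return None
    val = group[name][()]
    if isinstance(val, bytes):
        return val.decode("utf-8")
    return str(val)


def read_sff(path: Union[str, Path]) -> tuple[
        list[LatticeSegmentation], list[MeshSegmentation],
        tuple[list[Description], list[SegmentAnnotation]]]:
    """Read an SFF document.

    Returns lattice segmentations, mesh segmentations, and the annotation
    fragment (descriptions, segment annotations) carried by the file.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "transform_list" in f:
            raise UnsupportedFeatureError(
                "SFF transform_list is not supported; grids must be axis-aligned")
        if "segment_list" not in f:
            raise FormatError(f"{path.name}: missing segment_list")

        voxel_size = tuple(float(v) for v in f.attrs.get("voxel_size", (1.0, 1.0, 1.0)))

        lattices_raw: dict[str, np.ndarray] = {}
        if "lattice_list" in f:
            for lid, lgrp in f["lattice_list"].items():
                if "data" not in lgrp:
                    raise FormatError(f"lattice {lid}: missing data")
                lattices_raw[str(lid)] = np.asarray(lgrp["data"][()], dtype=np.int32)

        descriptions: list[Description] = []
        seg_annotations: list[SegmentAnnotation] = []
        lattice_ids_used: dict[str, set[int]] = {}
        meshes: list[MeshSegmentation] = []

        segs = sorted(f["segment_list"].keys(), key=lambda s: (len(s), s))
        if not segs:
            warnings.warn(f"{path.name}: SFF file contains zero segments",
                          stacklevel=2)
        for sid in segs:
            sgrp = f["segment_list"][sid]
            bio = sgrp.get("biological_annotation")
            name = _read_str(bio, "name") if bio is not None else None
            details = _read_str(bio, "description") if bio is not None else None
            color = None
            if "colour" in sgrp:
                color = [float(c) for c in np.asarray(sgrp["colour"][()]).ravel()[:4]]

            if "three_d_volume" in sgrp:
                vol = sgrp["three_d_volume"]
                lid = str(_read_str(vol, "lattice_id") or int(vol["lattice_id"][()]))
                value = int(vol["value"][()])
                if lid not in lattices_raw:
                    raise FormatError(f"segment {sid}: unknown lattice id {lid!r}")
                seg_id_str = f"lattice_{lid}"
                lattice_ids_used.setdefault(lid, set()).add(value)
                descriptions.append(Description(
                    id=f"desc-{seg_id_str}-{value}",
                    target_kind="lattice",
                    target=DescriptionTarget(segmentation_id=seg_id_str,
                                             segment_id=value),
                    name=name, details=details))
                if color is not None:
                    seg_annotations.append(SegmentAnnotation(
                        id=f"sa-{seg_id_str}-{value}", segment_kind="lattice",
                        segmentation_id=seg_id_str, segment_id=value, color=color))
            elif "mesh_list" in sgrp:
                mesh_segments = {}
                for i, (_mid, mgrp) in enumerate(sorted(sgrp["mesh_list"].items())):
                    verts = np.asarray(mgrp["vertices"][()], dtype=np.float64)
                    tris = np.asarray(mgrp["triangles"][()], dtype=np.int64)
                    mesh_segments[i + 1] = (verts, tris)
                seg_id_str = f"mesh_{sid}"
                meshes.append(MeshSegmentation(segmentation_id=seg_id_str,
                                               segments=mesh_segments))
                for mseg in mesh_segments:
                    descriptions.append(Description(
                        id=f"desc-{seg_id_str}-{mseg}", target_kind="mesh",
                        target=DescriptionTarget(segmentation_id=seg_id_str,
                                                 segment_id=mseg),
                        name=name, details=details))
                    if color is not None:
                        seg_annotations.append(SegmentAnnotation(
                            id=f"sa-{seg_id_str}-{mseg}", segment_kind="mesh",
                            segmentation_id=seg_id_str, segment_id=mseg,
                            color=color))

        lattices = []
        for lid in sorted(lattices_raw):
            if lid not in lattice_ids_used:
                continue  # lattice not referenced by any segment
            lattices.append(LatticeSegmentation(
                segmentation_id=f"lattice_{lid}",
                frames={0: {1: LabelGrid(labels=lattices_raw[lid])}},
                voxel_size=voxel_size))

    return lattices, meshes, (descriptions, seg_annotations)
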
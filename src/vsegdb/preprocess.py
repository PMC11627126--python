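"""Conversion of raw inputs into complete database entries.

The pipeline for ``preprocess --mode add`` is: parse every input into the
core model, build downsampling pyramids, seed annotations for segments that
arrived without any, apply extra-data overrides (voxel size, custom segment
names), assemble the metadata inventory, and write the entry to the store
in one atomic step — an error anywhere leaves the database unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import store
from .errors import ConflictError, ValidationFailure, VsegError
from .io import (
    load_geometric_json,
    read_map,
    read_mask,
    read_omezarr,
    read_ometiff_series,
    read_sff,
)
from .models import (
    AnnotationEntryId,
    ChannelAnnotation,
    Description,
    DescriptionTarget,
    EntryAnnotations,
    EntryKey,
    EntryMetadata,
    ExtraData,
    GeometricSegmentation,
    LatticeSegmentation,
    MeshSegmentation,
    MultiscaleVolume,
    SegmentAnnotation,
    grid_stats,
    validate_extra_data,
)
from .pyramid import PyramidPolicy, build_pyramid

INPUT_KINDS = ("map", "sff", "omezarr", "ometiff_image", "mask",
               "geometric_segmentation", "extra_data")

#: Fixed 10-color palette for seeded segment annotations, indexed by
#: (segment_id - 1) mod 10.  Deterministic and mutually distinguishable.
PALETTE: list[tuple[float, float, float, float]] = [
    (0.894, 0.102, 0.110, 1.0),
    (0.216, 0.494, 0.722, 1.0),
    (0.302, 0.686, 0.290, 1.0),
    (0.596, 0.306, 0.639, 1.0),
    (1.000, 0.498, 0.000, 1.0),
    (1.000, 1.000, 0.200, 1.0),
    (0.651, 0.337, 0.157, 1.0),
    (0.969, 0.506, 0.749, 1.0),
    (0.600, 0.600, 0.600, 1.0),
    (0.121, 0.471, 0.706, 1.0),
]


def palette_color(segment_id: int) -> tuple[float, float, float, float]:
    return PALETTE[(segment_id - 1) % len(PALETTE)]


@dataclass(frozen=True)
class InputSpec:
    path: Union[str, Path]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in INPUT_KINDS:
            raise VsegError(
                f"unknown input kind {self.kind!r}; expected one of {INPUT_KINDS}")


def _check_input_order(inputs: list[InputSpec]) -> None:
    extra = [i for i, s in enumerate(inputs) if s.kind == "extra_data"]
    if len(extra) > 1:
        raise VsegError("at most one extra_data input is allowed")
    if extra and extra[0] != 0:
        raise VsegError("the extra_data input must be the first input file")


# ---------------------------------------------------------------------------
# annotation seeding and extra-data application
# ---------------------------------------------------------------------------


def seed_annotations(key: EntryKey,
                     volumes: list[MultiscaleVolume],
                     lattices: list[LatticeSegmentation],
                     geometrics: list[GeometricSegmentation],
                     meshes: list[MeshSegmentation],
                     descriptions: Optional[list[Description]] = None,
                     segment_annotations: Optional[list[SegmentAnnotation]] = None,
                     ) -> EntryAnnotations:
    """Annotations document for an entry in progress.

    Records arriving from the source files (e.g. SFF biology) pass through
    untouched; every lattice/mesh segment without one receives a generic
    "Segment {label}" description and a palette color, and each geometric
    segmentation receives one description targeting the segmentation as a
    whole.  Ids are deterministic: ``desc-{segmentation_id}-{segment_id}``
    and ``sa-{segmentation_id}-{segment_id}``.
    """
    descs = {d.id: d for d in (descriptions or [])}
    sas = list(segment_annotations or [])
    covered_desc = {(d.target.segmentation_id, d.target.segment_id)
                    for d in descs.values() if d.target is not None}
    covered_sa = {(a.segmentation_id, a.segment_id) for a in sas}

    def seed(kind: str, sid: str, labels: list[int]) -> None:
        for label in labels:
            if (sid, label) not in covered_desc:
                d = Description(
                    id=f"desc-{sid}-{label}", target_kind=kind,
                    target=DescriptionTarget(segmentation_id=sid, segment_id=label),
                    name=f"Segment {label}")
                descs[d.id] = d
            if (sid, label) not in covered_sa:
                sas.append(SegmentAnnotation(
                    id=f"sa-{sid}-{label}", segment_kind=kind,
                    segmentation_id=sid, segment_id=label,
                    color=list(palette_color(label))))

    for seg in lattices:
        seed("lattice", seg.segmentation_id, sorted(seg.segment_ids))
    for seg in meshes:
        seed("mesh", seg.segmentation_id, sorted(seg.segments))
    for seg in geometrics:
        did = f"desc-{seg.segmentation_id}"
        if did not in descs:
            descs[did] = Description(
                id=did, target_kind="primitive",
                target=DescriptionTarget(segmentation_id=seg.segmentation_id),
                name=seg.segmentation_id)

    channels = [
        ChannelAnnotation(channel_id=v.channel_id,
                          color=list(palette_color(i + 1)),
                          label=v.channel_id)
        for i, v in enumerate(volumes)
    ]
    return EntryAnnotations(
        entry_id=AnnotationEntryId(source_db_name=key.source_db_name,
                                   source_db_id=key.source_db_id),
        name=key.entry_id,
        descriptions=descs,
        segment_annotations=sas,
        volume_channels_annotations=channels,
    )


def apply_extra_data(volumes: list[MultiscaleVolume],
                     lattices: list[LatticeSegmentation],
                     annotations: EntryAnnotations,
                     extra: Optional[ExtraData]) -> None:
    """Apply overrides in place; an empty document is a no-op.

    A ``voxel_size`` override replaces the header-derived value on every
    grid (scaled by the level factor on coarser levels).  A
    ``custom_segment_ids_mapping`` renames the seeded description of each
    referenced (segmentation, label) pair; unknown references warn rather
    than fail.
    """
    if extra is None:
        return
    if extra.volume and extra.volume.voxel_size:
        base = tuple(extra.volume.voxel_size)
        for vol in volumes:
            for pyr in vol.frames.values():
                for f, grid in pyr.items():
                    grid.voxel_size = tuple(v * f for v in base)
        for seg in lattices:
            seg.voxel_size = base
    if extra.segmentation and extra.segmentation.custom_segment_ids_mapping:
        known_sids = {seg.segmentation_id for seg in lattices}
        for sid, mapping in extra.segmentation.custom_segment_ids_mapping.items():
            if sid not in known_sids:
                warnings.warn(f"custom_segment_ids_mapping references unknown "
                              f"segmentation {sid!r}", stacklevel=2)
                continue
            for label_str, name in mapping.items():
                did = f"desc-{sid}-{int(label_str)}"
                if did in annotations.descriptions:
                    annotations.descriptions[did].name = name
                else:
                    warnings.warn(f"custom_segment_ids_mapping references "
                                  f"unknown label {label_str!r} of {sid!r}",
                                  stacklevel=2)


# ---------------------------------------------------------------------------
# metadata assembly
# ---------------------------------------------------------------------------


def build_metadata(key: EntryKey,
                   volumes: list[MultiscaleVolume],
                   lattices: list[LatticeSegmentation],
                   geometrics: list[GeometricSegmentation],
                   meshes: list[MeshSegmentation]) -> EntryMetadata:
    """Inventory document exactly reflecting the in-memory entry."""
    doc: dict = {
        "entry_id": {
            "source_db": key.source_db, "entry_id": key.entry_id,
            "source_db_id": key.source_db_id,
            "source_db_name": key.source_db_name,
        },
        "volumes": {"channel_ids": [], "time_frame_indices": [],
                    "sampling_levels": {}, "stats": {}},
        "segmentations": {"lattice": [], "geometric": [], "mesh": []},
    }
    if volumes:
        first = volumes[0]
        t0 = min(first.frames)
        doc["volumes"]["channel_ids"] = [v.channel_id for v in volumes]
        doc["volumes"]["time_frame_indices"] = first.time_indices()
        doc["grid"] = {"origin": list(first.frames[t0][1].origin)}
        for f, grid in sorted(first.frames[t0].items()):
            doc["volumes"]["sampling_levels"][str(f)] = {
                "dims": list(grid.dims),
                "voxel_size": list(grid.voxel_size),
            }
        for vol in volumes:
            per_level = {}
            for f in vol.level_factors():
                stacked = np.concatenate(
                    [vol.frames[t][f].values.ravel() for t in vol.time_indices()])
                per_level[str(f)] = grid_stats(stacked.reshape(1, 1, -1))
            doc["volumes"]["stats"][vol.channel_id] = per_level
    for seg in lattices:
        t0 = min(seg.frames)
        rec = {
            "segmentation_id": seg.segmentation_id,
            "time_frame_indices": seg.time_indices(),
            "segment_ids": sorted(seg.segment_ids),
            "voxel_size": list(seg.voxel_size),
            "origin": list(seg.origin),
            "sampling_levels": {
                str(f): {"dims": list(g.dims)}
                for f, g in sorted(seg.frames[t0].items())
            },
        }
        doc["segmentations"]["lattice"].append(rec)
    for seg in geometrics:
        doc["segmentations"]["geometric"].append({
            "segmentation_id": seg.segmentation_id,
            "time_frame_indices": seg.time_indices(),
        })
    for seg in meshes:
        doc["segmentations"]["mesh"].append({
            "segmentation_id": seg.segmentation_id,
            "segment_ids": sorted(seg.segments),
        })
    for kind in ("lattice", "geometric", "mesh"):
        doc["segmentations"][kind].sort(key=lambda r: r["segmentation_id"])
    return EntryMetadata(document=doc)


# ---------------------------------------------------------------------------
# the preprocess entry point
# ---------------------------------------------------------------------------


def _parse_inputs(inputs: list[InputSpec]):
    volumes: list[MultiscaleVolume] = []
    lattices: list[LatticeSegmentation] = []
    geometrics: list[GeometricSegmentation] = []
    meshes: list[MeshSegmentation] = []
    descriptions: list[Description] = []
    seg_annotations: list[SegmentAnnotation] = []
    extra: Optional[ExtraData] = None

    n_maps = 0
    for spec in inputs:
        path = Path(spec.path)
        if spec.kind == "extra_data":
            raw = json.loads(path.read_text())
            violations = validate_extra_data(raw)
            if violations:
                raise ValidationFailure(violations)
            extra = ExtraData.model_validate(raw)
        elif spec.kind == "map":
            grid = read_map(path)
            volumes.append(MultiscaleVolume(channel_id=str(n_maps),
                                            frames={0: {1: grid}}))
            n_maps += 1
        elif spec.kind == "mask":
            lattices.append(read_mask(path))
        elif spec.kind == "sff":
            lats, mshs, (descs, sas) = read_sff(path)
            lattices.extend(lats)
            meshes.extend(mshs)
            descriptions.extend(descs)
            seg_annotations.extend(sas)
        elif spec.kind == "omezarr":
            vols, lats = read_omezarr(path)
            volumes.extend(vols)
            lattices.extend(lats)
        elif spec.kind == "ometiff_image":
            volumes.extend(read_ometiff_series(path))
        elif spec.kind == "geometric_segmentation":
            geometrics.append(load_geometric_json(path))
    return volumes, lattices, geometrics, meshes, descriptions, seg_annotations, extra


def preprocess_entry(inputs: list[InputSpec], key: EntryKey,
                     working_folder: Union[str, Path],
                     db_path: Union[str, Path],
                     policy: Optional[PyramidPolicy] = None) -> Path:
    """Run the full preprocessing pipeline and store the entry.

    Refuses duplicate (source_db, entry_id) keys; a failure at any stage
    leaves the database without the new entry.
    """
    if not inputs:
        raise VsegError("at least one input is required")
    _check_input_order(inputs)
    if store.entry_exists(db_path, key):
        raise ConflictError(
            f"entry {key.source_db}/{key.entry_id} already exists in the "
            f"database; remove it first or choose a different entry id")
    Path(working_folder).mkdir(parents=True, exist_ok=True)
    policy = policy or PyramidPolicy()

    (volumes, lattices, geometrics, meshes,
     descriptions, seg_annotations, extra) = _parse_inputs(inputs)

    for vol in volumes:
        for t, pyr in vol.frames.items():
            vol.frames[t] = build_pyramid(pyr[1], policy)
    for seg in lattices:
        for t, pyr in seg.frames.items():
            seg.frames[t] = build_pyramid(pyr[1], policy)

    annotations = seed_annotations(key, volumes, lattices, geometrics, meshes,
                                   descriptions, seg_annotations)
    apply_extra_data(volumes, lattices, annotations, extra)
    metadata = build_metadata(key, volumes, lattices, geometrics, meshes)
    return store.write_entry(db_path, key, volumes, lattices, geometrics,
                             meshes, annotations, metadata)


def remove_entry(db_path: Union[str, Path], key: EntryKey) -> None:
    """Remove one entry from the database (``--mode remove``)."""
    store.remove_entry(db_path, key)
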
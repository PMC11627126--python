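"""The internal entry database on disk.

Layout::

    <root>/<source_db>/<entry_id>/
        data.zip           # payloads (see below)
        annotations.json
        metadata.json

Inside ``data.zip`` payload paths are::

    volume/{channel_id}/{time}/{factor}.map      # MRC grids
    lattice/{segmentation_id}/{time}/{factor}.map
    mesh/{segmentation_id}.json
    geometric/{segmentation_id}.json

Grids are stored as standard MRC maps so every payload stays independently
inspectable.  Archives are deflate-compressed with members sorted by path,
which makes repeated preprocessing byte-stable.
"""

from __future__ import annotations

import json
import os
import shutil
import tempfile
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import ContractError, FormatError, NotFoundError, ValidationFailure
from .io.mrc import read_map_bytes, write_map_bytes
from .io.star import geometric_to_json_doc, load_geometric_json
from .models import (
    EntryAnnotations,
    EntryKey,
    EntryMetadata,
    GeometricSegmentation,
    LabelGrid,
    LatticeSegmentation,
    MeshSegmentation,
    MultiscaleVolume,
    VolumeGrid,
    validate_annotations,
)


@dataclass
class Entry:
    """A fully materialised database entry."""

    key: EntryKey
    volumes: list[MultiscaleVolume] = field(default_factory=list)
    lattices: list[LatticeSegmentation] = field(default_factory=list)
    geometrics: list[GeometricSegmentation] = field(default_factory=list)
    meshes: list[MeshSegmentation] = field(default_factory=list)
    annotations: Optional[EntryAnnotations] = None
    metadata: Optional[EntryMetadata] = None


def entry_dir(root: Union[str, Path], key: EntryKey) -> Path:
    return Path(root) / key.source_db / key.entry_id


def entry_exists(root: Union[str, Path], key: EntryKey) -> bool:
    return (entry_dir(root, key) / "metadata.json").exists()


# ---------------------------------------------------------------------------
# payload member paths
# ---------------------------------------------------------------------------


def volume_member(channel_id: str, time: int, factor: int) -> str:
    return f"volume/{channel_id}/{time}/{factor}.map"


def lattice_member(segmentation_id: str, time: int, factor: int) -> str:
    return f"lattice/{segmentation_id}/{time}/{factor}.map"


def mesh_member(segmentation_id: str) -> str:
    return f"mesh/{segmentation_id}.json"


def geometric_member(segmentation_id: str) -> str:
    return f"geometric/{segmentation_id}.json"


def payload_members(volumes, lattices, geometrics, meshes) -> dict[str, bytes]:
    """Serialise all payloads to their zip member paths."""
    members: dict[str, bytes] = {}
    for vol in volumes:
        for t, pyr in vol.frames.items():
            for f, grid in pyr.items():
                members[volume_member(vol.channel_id, t, f)] = write_map_bytes(grid)
    for seg in lattices:
        for t, pyr in seg.frames.items():
            for f, grid in pyr.items():
                members[lattice_member(seg.segmentation_id, t, f)] = \
                    write_map_bytes(grid)
    for seg in geometrics:
        doc = geometric_to_json_doc(seg)
        members[geometric_member(seg.segmentation_id)] = (
            json.dumps(doc, indent=2, sort_keys=True) + "\n").encode()
    for seg in meshes:
        doc = {
            "segmentation_id": seg.segmentation_id,
            "segments": {
                str(sid): {"vertices": verts.tolist(),
                           "triangles": tris.tolist()}
                for sid, (verts, tris) in sorted(seg.segments.items())
            },
        }
        members[mesh_member(seg.segmentation_id)] = (
            json.dumps(doc, indent=2, sort_keys=True) + "\n").encode()
    return members


def expected_members_from_metadata(metadata: EntryMetadata) -> set[str]:
    """The payload member set implied by a metadata inventory."""
    doc = metadata.document
    out: set[str] = set()
    vols = doc.get("volumes", {})
    factors = sorted(int(k) for k in vols.get("sampling_levels", {}))
    for cid in vols.get("channel_ids", []):
        for t in vols.get("time_frame_indices", []):
            for f in factors:
                out.add(volume_member(cid, t, f))
    segs = doc.get("segmentations", {})
    for lat in segs.get("lattice", []):
        lfactors = sorted(int(k) for k in lat.get("sampling_levels", {}))
        for t in lat.get("time_frame_indices", []):
            for f in lfactors:
                out.add(lattice_member(lat["segmentation_id"], t, f))
    for geo in segs.get("geometric", []):
        out.add(geometric_member(geo["segmentation_id"]))
    for msh in segs.get("mesh", []):
        out.add(mesh_member(msh["segmentation_id"]))
    return out


def write_zip(path: Path, members: dict[str, bytes]) -> None:
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED,
                         compresslevel=6) as zf:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, members[name])


# ---------------------------------------------------------------------------
# entry write / read / list / remove
# ---------------------------------------------------------------------------


def write_entry(root: Union[str, Path], key: EntryKey,
                volumes: list[MultiscaleVolume],
                lattices: list[LatticeSegmentation],
                geometrics: list[GeometricSegmentation],
                meshes: list[MeshSegmentation],
                annotations: EntryAnnotations,
                metadata: EntryMetadata,
                overwrite: bool = False) -> Path:
    """Write a complete entry; creates the root and source dir as needed.

    The metadata inventory is checked against the payloads before anything
    touches the store; the entry directory is staged and renamed into place
    so a failure never leaves a partial entry behind.
    """
    violations = validate_annotations(annotations.model_dump(mode="json"))
    if violations:
        raise ValidationFailure(violations)
    members = payload_members(volumes, lattices, geometrics, meshes)
    expected = expected_members_from_metadata(metadata)
    if expected != set(members):
        missing = sorted(expected - set(members))[:5]
        extra = sorted(set(members) - expected)[:5]
        raise ContractError(
            f"metadata inventory does not match payloads "
            f"(missing={missing}, extra={extra})")

    dest = entry_dir(root, key)
    if dest.exists() and not overwrite:
        raise ContractError(f"entry {key.source_db}/{key.entry_id} already exists")
    dest.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=f".{key.entry_id}-",
                                    dir=dest.parent))
    try:
        write_zip(staging / "data.zip", members)
        (staging / "annotations.json").write_text(
            json.dumps(annotations.model_dump(mode="json"), indent=2,
                       sort_keys=True) + "\n")
        (staging / "metadata.json").write_text(metadata.to_json())
        if dest.exists():
            shutil.rmtree(dest)
        os.replace(staging, dest)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return dest


def read_metadata(root: Union[str, Path], key: EntryKey) -> EntryMetadata:
    path = entry_dir(root, key) / "metadata.json"
    if not path.exists():
        raise NotFoundError(f"entry {key.source_db}/{key.entry_id} not found")
    return EntryMetadata.from_json(path.read_text())


def read_annotations(root: Union[str, Path], key: EntryKey) -> EntryAnnotations:
    path = entry_dir(root, key) / "annotations.json"
    if not path.exists():
        raise NotFoundError(f"entry {key.source_db}/{key.entry_id} not found")
    return EntryAnnotations.model_validate_json(path.read_text())


def read_payload(root: Union[str, Path], key: EntryKey, member: str) -> bytes:
    zpath = entry_dir(root, key) / "data.zip"
    if not zpath.exists():
        raise NotFoundError(f"entry {key.source_db}/{key.entry_id} not found")
    with zipfile.ZipFile(zpath) as zf:
        try:
            return zf.read(member)
        except KeyError:
            raise NotFoundError(f"member {member!r} not in data.zip") from None


def _mesh_from_doc(doc: dict) -> MeshSegmentation:
    segments = {
        int(sid): (np.asarray(rec["vertices"], dtype=np.float64),
                   np.asarray(rec["triangles"], dtype=np.int64))
        for sid, rec in doc["segments"].items()
    }
    return MeshSegmentation(segmentation_id=doc["segmentation_id"],
                            segments=segments)


def read_entry(root: Union[str, Path], key: EntryKey) -> Entry:
    """Reconstruct a full entry from the store."""
    metadata = read_metadata(root, key)
    annotations = read_annotations(root, key)
    zpath = entry_dir(root, key) / "data.zip"
    doc = metadata.document
    with zipfile.ZipFile(zpath) as zf:
        def grid(member: str) -> VolumeGrid:
            try:
                return read_map_bytes(zf.read(member))
            except KeyError:
                raise FormatError(f"data.zip is missing member {member!r}") from None

        volumes = []
        vols = doc.get("volumes", {})
        factors = sorted(int(k) for k in vols.get("sampling_levels", {}))
        for cid in vols.get("channel_ids", []):
            frames = {}
            for t in vols.get("time_frame_indices", []):
                frames[t] = {f: grid(volume_member(cid, t, f)) for f in factors}
            volumes.append(MultiscaleVolume(channel_id=cid, frames=frames))

        lattices = []
        for lat in doc.get("segmentations", {}).get("lattice", []):
            lfactors = sorted(int(k) for k in lat.get("sampling_levels", {}))
            frames = {}
            for t in lat.get("time_frame_indices", []):
                frames[t] = {}
                for f in lfactors:
                    g = grid(lattice_member(lat["segmentation_id"], t, f))
                    frames[t][f] = LabelGrid(
                        labels=np.rint(g.values).astype(np.int32))
            lattices.append(LatticeSegmentation(
                segmentation_id=lat["segmentation_id"], frames=frames,
                voxel_size=tuple(lat.get("voxel_size", (0.0, 0.0, 0.0))),
                origin=tuple(lat.get("origin", (0.0, 0.0, 0.0)))))

        geometrics = []
        for geo in doc.get("segmentations", {}).get("geometric", []):
            raw = zf.read(geometric_member(geo["segmentation_id"]))
            geometrics.append(load_geometric_json(json.loads(raw)))

        meshes = []
        for msh in doc.get("segmentations", {}).get("mesh", []):
            raw = zf.read(mesh_member(msh["segmentation_id"]))
            meshes.append(_mesh_from_doc(json.loads(raw)))

    return Entry(key=key, volumes=volumes, lattices=lattices,
                 geometrics=geometrics, meshes=meshes,
                 annotations=annotations, metadata=metadata)


def list_entries(root: Union[str, Path],
                 source_db: Optional[str] = None) -> list[EntryKey]:
    """Sorted keys of every stored entry, optionally filtered by source."""
    root = Path(root)
    if not root.exists():
        warnings.warn(f"database root {root} does not exist", stacklevel=2)
        return []
    keys = []
    sources = [source_db] if source_db else sorted(
        p.name for p in root.iterdir() if p.is_dir())
    for src in sources:
        src_dir = root / src
        if not src_dir.is_dir():
            continue
        for edir in sorted(src_dir.iterdir()):
            if (edir / "metadata.json").exists():
                keys.append(EntryKey(source_db=src, entry_id=edir.name))
    return keys


def remove_entry(root: Union[str, Path], key: EntryKey) -> None:
    """Delete one entry; unknown keys raise, siblings are untouched."""
    dest = entry_dir(root, key)
    if not dest.exists():
        raise NotFoundError(f"entry {key.source_db}/{key.entry_id} not found")
    shutil.rmtree(dest)
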
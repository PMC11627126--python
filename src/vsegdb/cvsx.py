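"""Query resolution, sampling-level selection, and CVSX archives.

A CVSX file is a plain ZIP (mandatory ``.cvsx`` extension) bundling a
queried subset of one database entry: the selected grid payloads at the
selected downsampling level, the geometric/mesh documents, annotations and
metadata filtered to the selection, plus ``query.json`` (the resolved
selection, with the raw request under ``"requested"``) and ``index.json``
describing every other member of the archive.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

from pydantic import ValidationError

from . import store
from .errors import NotFoundError, ValidationFailure, VsegError
from .models import (
    DEFAULT_MAX_POINTS,
    SEGMENTATION_KINDS,
    EntryAnnotations,
    EntryKey,
    EntryMetadata,
    QueryParams,
)


# ---------------------------------------------------------------------------
# query resolution
# ---------------------------------------------------------------------------


def _parse_query(raw: Union[dict, str, bytes]) -> QueryParams:
    if isinstance(raw, (str, bytes)):
        raw = json.loads(raw)
    try:
        return QueryParams.model_validate(raw)
    except ValidationError as exc:
        missing = [str(e["loc"][0]) for e in exc.errors() if e["type"] == "missing"]
        if missing:
            raise VsegError(
                f"missing mandatory query field(s): {', '.join(missing)}") from exc
        raise VsegError(f"bad query document: {exc}") from exc


def resolve_query(raw: Union[dict, str, bytes],
                  metadata: EntryMetadata) -> dict[str, Any]:
    """Expand a raw query against an entry's inventory.

    Absent optional fields expand to everything the entry has; a given
    ``time`` restricts volumes and segmentations alike.  Unknown channels,
    times, or segmentation ids raise :class:`NotFoundError` listing the
    valid values.  Resolution is idempotent: re-resolving the resolved
    selection's scalars yields the same selection.
    """
    q = _parse_query(raw)
    doc = metadata.document

    channel_ids = metadata.channel_ids
    vol_times = metadata.volume_time_indices
    if q.channel_id is not None:
        if q.channel_id not in channel_ids:
            raise NotFoundError(
                f"channel_id {q.channel_id!r} not in entry; valid: {channel_ids}")
        channel_ids = [q.channel_id]

    lat = metadata.lattice_inventory()
    geo = metadata.geometric_inventory()
    msh = metadata.mesh_inventory()

    all_times = set(vol_times)
    for rec in lat + geo:
        all_times.update(rec.get("time_frame_indices", []))
    if q.time is not None:
        if q.time not in all_times:
            raise NotFoundError(
                f"time {q.time} not in entry; valid: {sorted(all_times)}")
        vol_times = [q.time] if q.time in vol_times else []
        lat = [r for r in lat if q.time in r.get("time_frame_indices", [])]
        geo = [r for r in geo if q.time in r.get("time_frame_indices", [])]

    kinds = list(SEGMENTATION_KINDS)
    if q.segmentation_kind is not None:
        kinds = [q.segmentation_kind]

    all_seg_ids = sorted(
        {r["segmentation_id"] for r in
         metadata.lattice_inventory() + metadata.geometric_inventory()
         + metadata.mesh_inventory()})
    if q.segmentation_id is not None:
        if q.segmentation_id not in all_seg_ids:
            raise NotFoundError(
                f"segmentation_id {q.segmentation_id!r} not in entry; "
                f"valid: {all_seg_ids}")
        lat = [r for r in lat if r["segmentation_id"] == q.segmentation_id]
        geo = [r for r in geo if r["segmentation_id"] == q.segmentation_id]
        msh = [r for r in msh if r["segmentation_id"] == q.segmentation_id]

    def seg_times(rec):
        ts = rec.get("time_frame_indices", [])
        return [q.time] if q.time is not None else ts

    selection = {
        "entry_id": q.entry_id,
        "source_db": q.source_db,
        "max_points": q.max_points,
        "channel_ids": channel_ids,
        "volume_time_indices": vol_times,
        "segmentation_kinds": kinds,
        "segmentations": {
            "lattice": [
                {"segmentation_id": r["segmentation_id"],
                 "time_indices": seg_times(r)}
                for r in lat] if "lattice" in kinds else [],
            "geometric": [
                {"segmentation_id": r["segmentation_id"],
                 "time_indices": seg_times(r)}
                for r in geo] if "geometric-segmentation" in kinds else [],
            "mesh": [
                {"segmentation_id": r["segmentation_id"]}
                for r in msh] if "mesh" in kinds else [],
        },
        "requested": q.model_dump(mode="json", exclude_none=True),
    }
    return selection


# ---------------------------------------------------------------------------
# sampling-level selection
# ---------------------------------------------------------------------------


def select_sampling_level(levels: dict[int, tuple[int, int, int]],
                          max_points: int = DEFAULT_MAX_POINTS) -> int:
    """Finest level factor whose voxel count fits under ``max_points``.

    Counts are per frame (``prod(dims)`` at each factor).  When even the
    coarsest level exceeds the budget, the coarsest is returned — a query
    always yields data.
    """
    if not levels:
        raise VsegError("no sampling levels available")
    for f in sorted(levels):
        nx, ny, nz = levels[f]
        if nx * ny * nz <= max_points:
            return f
    return max(levels)


def _levels_from_doc(levels_doc: dict[str, Any]) -> dict[int, tuple[int, int, int]]:
    return {int(f): tuple(rec["dims"]) for f, rec in levels_doc.items()}


# ---------------------------------------------------------------------------
# archive build / read
# ---------------------------------------------------------------------------


@dataclass
class CvsxArchive:
    """Parsed contents of one CVSX file."""

    query: dict[str, Any]
    index: dict[str, Any]
    annotations: EntryAnnotations
    metadata: EntryMetadata
    payloads: dict[str, bytes] = field(default_factory=dict)


def _filter_annotations(ann: EntryAnnotations, selection: dict) -> EntryAnnotations:
    sel_sids = {r["segmentation_id"]
                for kind in ("lattice", "geometric", "mesh")
                for r in selection["segmentations"][kind]}
    sel_channels = set(selection["channel_ids"])
    descs = {
        did: d for did, d in ann.descriptions.items()
        if d.target is None or d.target.segmentation_id in sel_sids
    }
    sas = [a for a in ann.segment_annotations if a.segmentation_id in sel_sids]
    chans = [c for c in ann.volume_channels_annotations
             if c.channel_id in sel_channels]
    return ann.model_copy(update={
        "descriptions": descs, "segment_annotations": sas,
        "volume_channels_annotations": chans})


def _filter_metadata(meta: EntryMetadata, selection: dict,
                     vol_factor: Optional[int],
                     lat_factors: dict[str, int]) -> EntryMetadata:
    doc = json.loads(json.dumps(meta.document))  # deep copy
    vols = doc.get("volumes", {})
    vols["channel_ids"] = list(selection["channel_ids"])
    vols["time_frame_indices"] = list(selection["volume_time_indices"])
    if vol_factor is not None:
        vols["sampling_levels"] = {
            str(vol_factor): vols["sampling_levels"][str(vol_factor)]}
        vols["stats"] = {
            cid: {str(vol_factor): st[str(vol_factor)]}
            for cid, st in vols.get("stats", {}).items()
            if cid in set(selection["channel_ids"])}
    segs = doc.get("segmentations", {})
    sel = selection["segmentations"]
    sel_lat = {r["segmentation_id"]: r for r in sel["lattice"]}
    sel_geo = {r["segmentation_id"]: r for r in sel["geometric"]}
    sel_msh = {r["segmentation_id"] for r in sel["mesh"]}
    new_lat = []
    for rec in segs.get("lattice", []):
        sid = rec["segmentation_id"]
        if sid not in sel_lat:
            continue
        rec = dict(rec)
        rec["time_frame_indices"] = list(sel_lat[sid]["time_indices"])
        f = lat_factors[sid]
        rec["sampling_levels"] = {str(f): rec["sampling_levels"][str(f)]}
        new_lat.append(rec)
    segs["lattice"] = new_lat
    segs["geometric"] = [
        dict(rec, time_frame_indices=list(sel_geo[rec["segmentation_id"]]
                                          ["time_indices"]))
        for rec in segs.get("geometric", [])
        if rec["segmentation_id"] in sel_geo]
    segs["mesh"] = [rec for rec in segs.get("mesh", [])
                    if rec["segmentation_id"] in sel_msh]
    return EntryMetadata(document=doc)


def build_cvsx(db_path: Union[str, Path], raw_query: Union[dict, str, bytes],
               out_path: Union[str, Path]) -> Path:
    """Resolve a query against the store and pack the selection."""
    out_path = Path(out_path)
    if out_path.suffix != ".cvsx":
        raise VsegError(f"output file must have the mandatory .cvsx extension, "
                        f"got {out_path.name!r}")
    q = _parse_query(raw_query)
    key = EntryKey(source_db=q.source_db, entry_id=q.entry_id)
    metadata = store.read_metadata(db_path, key)
    annotations = store.read_annotations(db_path, key)
    selection = resolve_query(raw_query, metadata)

    vol_levels = metadata.volume_levels()
    vol_factor = (select_sampling_level(vol_levels, q.max_points)
                  if vol_levels else None)
    lat_factors: dict[str, int] = {}
    for rec in metadata.lattice_inventory():
        lat_factors[rec["segmentation_id"]] = select_sampling_level(
            _levels_from_doc(rec["sampling_levels"]), q.max_points)

    members: dict[str, bytes] = {}
    index_entries: list[dict[str, Any]] = []

    for cid in selection["channel_ids"]:
        for t in selection["volume_time_indices"]:
            member = store.volume_member(cid, t, vol_factor)
            members[member] = store.read_payload(db_path, key, member)
            index_entries.append({
                "path": member, "role": "volume", "channel_id": cid,
                "time": t, "level_factor": vol_factor, "format": "mrc"})
    for rec in selection["segmentations"]["lattice"]:
        sid = rec["segmentation_id"]
        for t in rec["time_indices"]:
            member = store.lattice_member(sid, t, lat_factors[sid])
            members[member] = store.read_payload(db_path, key, member)
            index_entries.append({
                "path": member, "role": "lattice", "segmentation_id": sid,
                "time": t, "level_factor": lat_factors[sid], "format": "mrc"})
    for rec in selection["segmentations"]["geometric"]:
        sid = rec["segmentation_id"]
        member = store.geometric_member(sid)
        members[member] = store.read_payload(db_path, key, member)
        index_entries.append({"path": member, "role": "geometric",
                              "segmentation_id": sid, "format": "json"})
    for rec in selection["segmentations"]["mesh"]:
        sid = rec["segmentation_id"]
        member = store.mesh_member(sid)
        members[member] = store.read_payload(db_path, key, member)
        index_entries.append({"path": member, "role": "mesh",
                              "segmentation_id": sid, "format": "json"})

    ann = _filter_annotations(annotations, selection)
    meta = _filter_metadata(metadata, selection, vol_factor, lat_factors)

    members["annotations.json"] = (json.dumps(
        ann.model_dump(mode="json"), indent=2, sort_keys=True) + "\n").encode()
    members["metadata.json"] = meta.to_json().encode()
    members["query.json"] = (json.dumps(selection, indent=2, sort_keys=True)
                             + "\n").encode()
    for name, role in (("annotations.json", "annotations"),
                       ("metadata.json", "metadata"),
                       ("query.json", "query")):
        index_entries.append({"path": name, "role": role, "format": "json"})
    index = {"members": sorted(index_entries, key=lambda e: e["path"])}
    members["index.json"] = (json.dumps(index, indent=2, sort_keys=True)
                             + "\n").encode()

    store.write_zip(out_path, members)
    return out_path


_REQUIRED_JSON = ("index.json", "query.json", "annotations.json", "metadata.json")


def read_cvsx(path: Union[str, Path]) -> CvsxArchive:
    """Read and validate a CVSX archive.

    The index must describe every non-index member exactly once and every
    listed member must exist; any mismatch is a validation failure naming
    the member.
    """
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())
        missing = [m for m in _REQUIRED_JSON if m not in names]
        if missing:
            raise ValidationFailure(
                [f"archive is missing member {m}" for m in missing])
        index = json.loads(zf.read("index.json"))
        listed = [e["path"] for e in index.get("members", [])]
        problems = []
        if len(listed) != len(set(listed)):
            dupes = sorted({p for p in listed if listed.count(p) > 1})
            problems += [f"index lists member {p} more than once" for p in dupes]
        for p in listed:
            if p not in names:
                problems.append(f"index lists member {p} absent from the archive")
        for n in sorted(names - {"index.json"}):
            if n not in listed:
                problems.append(f"member {n} is not described by the index")
        if problems:
            raise ValidationFailure(problems)

        query = json.loads(zf.read("query.json"))
        annotations = EntryAnnotations.model_validate_json(
            zf.read("annotations.json"))
        metadata = EntryMetadata.from_json(zf.read("metadata.json"))
        payloads = {n: zf.read(n) for n in names
                    if n not in set(_REQUIRED_JSON)}
    return CvsxArchive(query=query, index=index, annotations=annotations,
                       metadata=metadata, payloads=payloads)
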
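"""OME-Zarr (OME NGFF) multiscale image reader.

Only the highest-resolution dataset of the source pyramid is consumed; the
preprocessor rebuilds its own downsampling pyramid so one kernel governs
every entry regardless of provenance.  Axis metadata must be a subset of
``t, c, z, y, x``; scale coordinate transformations are converted to an Å
voxel size (missing units are assumed Å, with a warning).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import zarr

from ..errors import FormatError, UnsupportedFeatureError
from ..models import (
    UM_TO_ANGSTROM,
    LabelGrid,
    LatticeSegmentation,
    MultiscaleVolume,
    VolumeGrid,
)

_KNOWN_AXES = ("t", "c", "z", "y", "x")

_UNIT_TO_ANGSTROM = {
    "angstrom": 1.0,
    "nanometer": 10.0,
    "micrometer": UM_TO_ANGSTROM,
    "millimeter": 1.0e7,
    "picometer": 1.0e-2,
}


def _axis_unit_scale(axis: dict) -> float:
    unit = axis.get("unit")
    if unit is None:
        warnings.warn(
            f"axis {axis.get('name')!r} has no unit; assuming angstrom",
            stacklevel=3)
        return 1.0
    if unit not in _UNIT_TO_ANGSTROM:
        warnings.warn(f"unknown unit {unit!r}; assuming angstrom", stacklevel=3)
        return 1.0
    return _UNIT_TO_ANGSTROM[unit]


def _parse_multiscale(group: "zarr.Group"):
    attrs = dict(group.attrs)
    ms = attrs.get("multiscales")
    if not ms:
        raise FormatError("missing multiscales metadata")
    ms0 = ms[0]
    axes = ms0.get("axes", [])
    names = [a["name"] for a in axes]
    for n in names:
        if n not in _KNOWN_AXES:
            raise UnsupportedFeatureError(f"unknown axis name {n!r}")
    ds0 = ms0["datasets"][0]  # full resolution only
    arr = np.asarray(group[ds0["path"]][:])
    scale = None
    for tr in ds0.get("coordinateTransformations", []):
        if tr.get("type") == "scale":
            scale = tr["scale"]
    voxel = {}
    for i, name in enumerate(names):
        if name in ("x", "y", "z"):
            s = scale[i] if scale is not None else 1.0
            voxel[name] = float(s) * _axis_unit_scale(axes[i])
    voxel_size = tuple(voxel.get(a, 1.0) for a in ("x", "y", "z"))
    return names, arr, voxel_size, attrs


def _normalize_tczyx(names: list[str], arr: np.ndarray) -> np.ndarray:
    """Permute/expand to a full (t, c, z, y, x) array."""
    perm = [names.index(n) for n in _KNOWN_AXES if n in names]
    arr = np.transpose(arr, perm)
    present = [n for n in _KNOWN_AXES if n in names]
    for i, n in enumerate(_KNOWN_AXES):
        if n not in present:
            arr = np.expand_dims(arr, i)
    return arr


def _frame_to_xyz(frame_zyx: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.transpose(frame_zyx, (2, 1, 0)))


def read_omezarr(path: Union[str, Path]) -> tuple[
        list[MultiscaleVolume], list[LatticeSegmentation]]:
    """Read an OME-Zarr group into per-channel volumes plus label lattices.

    Channel ids come from ``omero`` channel labels when present, else the
    channel index as a string.  A ``labels`` subgroup yields one lattice
    segmentation per label image, named after the label image.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"{path} is not an OME-Zarr directory")
    root = zarr.open_group(str(path), mode="r")
    names, arr, voxel_size, attrs = _parse_multiscale(root)
    arr5 = _normalize_tczyx(names, arr)
    nt, nc = arr5.shape[:2]

    channel_labels = None
    omero = attrs.get("omero")
    if omero and omero.get("channels"):
        channel_labels = [c.get("label") or str(i)
                          for i, c in enumerate(omero["channels"])]
        if len(channel_labels) != nc:
            warnings.warn("omero channel count does not match data; "
                          "falling back to indices", stacklevel=2)
            channel_labels = None
    if channel_labels is None:
        channel_labels = [str(i) for i in range(nc)]

    volumes = []
    for ci, cid in enumerate(channel_labels):
        frames = {}
        for t in range(nt):
            grid = VolumeGrid(values=_frame_to_xyz(arr5[t, ci]).astype(np.float64),
                              voxel_size=voxel_size)
            frames[t] = {1: grid}
        volumes.append(MultiscaleVolume(channel_id=str(cid), frames=frames))

    lattices = []
    if "labels" in root:
        lab_root = root["labels"]
        lab_names = sorted(lab_root.group_keys())
        for lname in lab_names:
            lnames, larr, lvoxel, _ = _parse_multiscale(lab_root[lname])
            larr5 = _normalize_tczyx(lnames, larr)
            if larr5.shape[1] != 1:
                raise UnsupportedFeatureError(
                    f"label image {lname!r} has a channel axis")
            lframes = {}
            for t in range(larr5.shape[0]):
                lab = LabelGrid(labels=_frame_to_xyz(larr5[t, 0]).astype(np.int32))
                lframes[t] = {1: lab}
            lattices.append(LatticeSegmentation(segmentation_id=lname,
                                                frames=lframes,
                                                voxel_size=lvoxel))
    return volumes, lattices
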
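"""OME-TIFF image-series reader.

A series may span several files (one per channel/time point, as produced by
common acquisition software).  Channel and time structure is recovered from
the embedded OME-XML dimension metadata; when the XML does not reference
companion files explicitly, files in the same directory matching the
``<prefix>_C{n}_TP{m}`` naming pattern are taken as the series.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

from ..errors import FormatError
from ..models import MultiscaleVolume, VolumeGrid

_OME_NS = "{http://www.openmicroscopy.org/Schemas/OME/2016-06}"
_SERIES_RE = re.compile(r"^(?P<prefix>.+)_C(?P<c>\d+)_TP(?P<t>\d+)\.ome\.tiff?$")


def _pixels_meta(ome_xml: str) -> dict:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError as exc:
        raise FormatError(f"bad OME-XML: {exc}") from exc
    pixels = root.find(f"{_OME_NS}Image/{_OME_NS}Pixels")
    if pixels is None:
        raise FormatError("OME-XML lacks an Image/Pixels element")
    meta = {k: pixels.get(k) for k in
            ("SizeX", "SizeY", "SizeZ", "SizeC", "SizeT",
             "PhysicalSizeX", "PhysicalSizeY", "PhysicalSizeZ",
             "PhysicalSizeXUnit", "PhysicalSizeYUnit", "PhysicalSizeZUnit")}
    meta["files"] = sorted({
        td.get("FileName")
        for td in pixels.findall(f"{_OME_NS}TiffData/{_OME_NS}UUID")
        if td.get("FileName")
    })
    return meta


_UNIT_TO_A = {"Å": 1.0, "A": 1.0, "angstrom": 1.0,
              "nm": 10.0, "nanometer": 10.0,
              "µm": 1.0e4, "um": 1.0e4, "micrometer": 1.0e4,
              "mm": 1.0e7, "millimeter": 1.0e7,
              "pm": 1.0e-2, "picometer": 1.0e-2}


def _voxel_size(meta: dict) -> tuple[float, float, float]:
    out = []
    for ax in ("X", "Y", "Z"):
        size = meta.get(f"PhysicalSize{ax}")
        if size is None:
            out.append(1.0)
            continue
        unit = meta.get(f"PhysicalSize{ax}Unit") or "µm"
        factor = _UNIT_TO_A.get(unit)
        if factor is None:
            warnings.warn(f"unknown physical unit {unit!r}; assuming angstrom",
                          stacklevel=3)
            factor = 1.0
        out.append(float(size) * factor)
    return tuple(out)


def _read_single(path: Path) -> np.ndarray:
    """Read one file as a (z, y, x) stack."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
    arr = np.asarray(arr)
    # squeeze non-spatial singleton axes, then coerce to ZYX
    keep = [i for i, a in enumerate(axes) if a in "ZYX"]
    if len(keep) != arr.ndim:
        extra = [i for i in range(arr.ndim) if i not in keep]
        if any(arr.shape[i] != 1 for i in extra):
            raise FormatError(
                f"{path.name}: unexpected non-singleton axes {axes!r}")
        arr = arr.squeeze(axis=tuple(extra))
        axes = "".join(a for a in axes if a in "ZYX")
    if arr.ndim == 2:
        arr = arr[None]
        axes = "Z" + axes
    perm = [axes.index(a) for a in "ZYX"]
    return np.transpose(arr, perm)


def read_ometiff_series(first_file: Union[str, Path]) -> list[MultiscaleVolume]:
    """Read an OME-TIFF series starting from any of its member files."""
    first = Path(first_file)
    if not first.exists():
        raise FormatError(f"{first} does not exist")
    with tifffile.TiffFile(first) as tf:
        if not tf.is_ome or tf.ome_metadata is None:
            raise FormatError(f"{first.name}: missing OME-XML metadata")
        meta = _pixels_meta(tf.ome_metadata)

    # resolve the member files of the series
    members: dict[tuple[int, int], Path] = {}
    if meta["files"] and len(meta["files"]) > 1:
        for fname in meta["files"]:
            fpath = first.parent / fname
            if not fpath.exists():
                raise FormatError(f"series member listed in OME-XML is absent: "
                                  f"{fname}")
            m = _SERIES_RE.match(fname)
            if not m:
                raise FormatError(f"cannot place series member {fname!r} "
                                  "(no C{n}_TP{m} pattern)")
            members[(int(m.group("c")), int(m.group("t")))] = fpath
    else:
        m = _SERIES_RE.match(first.name)
        if m:
            pattern = re.compile(
                rf"^{re.escape(m.group('prefix'))}_C(\d+)_TP(\d+)\.ome\.tiff?$")
            for cand in sorted(first.parent.iterdir()):
                cm = pattern.match(cand.name)
                if cm:
                    members[(int(cm.group(1)), int(cm.group(2)))] = cand
        else:
            members[(0, 0)] = first

    voxel_size = _voxel_size(meta)
    channels = sorted({c for c, _ in members})
    times = sorted({t for _, t in members})
    volumes = []
    for ci, c in enumerate(channels):
        frames = {}
        for ti, t in enumerate(times):
            key = (c, t)
            if key not in members:
                raise FormatError(f"series is ragged: missing file for "
                                  f"channel {c}, time point {t}")
            zyx = _read_single(members[key])
            xyz = np.ascontiguousarray(np.transpose(zyx, (2, 1, 0)))
            frames[ti] = {1: VolumeGrid(values=xyz.astype(np.float64),
                                        voxel_size=voxel_size)}
        volumes.append(MultiscaleVolume(channel_id=str(ci), frames=frames))
    return volumes
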
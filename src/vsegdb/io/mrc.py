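"""Minimal MRC2014 / CCP4 map codec.

Covers the modes seen in EMDB practice: 0 (int8), 1 (int16), 2 (float32)
and 6 (uint16), little-endian on disk.  The reader honours the crs→xyz axis
permutation (``mapc``/``mapr``/``maps``) and derives the voxel size as
``cella / m``; a zeroed unit cell yields voxel size 0, which is preserved —
not rejected — so an extra-data override can repair it downstream.

The writer always emits mode-2 (float32) for scalar data, an integer mode
for label data, and the canonical ``mapc,mapr,maps = 1,2,3`` ordering.
"""

from __future__ import annotations

import io
import struct
from pathlib import Path
from typing import Union

import numpy as np

from ..errors import FormatError
from ..models import LabelGrid, LatticeSegmentation, VolumeGrid

HEADER_SIZE = 1024

_MODE_DTYPES = {
    0: np.dtype("<i1"),
    1: np.dtype("<i2"),
    2: np.dtype("<f4"),
    6: np.dtype("<u2"),
}

_HDR = struct.Struct(
    "<"
    "3i"  # nx ny nz (columns, rows, sections)
    "i"  # mode
    "3i"  # nxstart nystart nzstart
    "3i"  # mx my mz
    "3f"  # cella
    "3f"  # cellb
    "3i"  # mapc mapr maps
    "3f"  # dmin dmax dmean
    "i"  # ispg
    "i"  # nsymbt
)


def _read_header(buf: bytes):
    if len(buf) < HEADER_SIZE:
        raise FormatError(
            f"truncated map: need a {HEADER_SIZE}-byte header, got {len(buf)} bytes"
        )
    fields = _HDR.unpack_from(buf, 0)
    (nx, ny, nz, mode, nxs, nys, nzs, mx, my, mz,
     ca, cb, cc, *_rest) = fields[:13] + (None,)
    mapc, mapr, maps = fields[16:19]
    origin = struct.unpack_from("<3f", buf, 49 * 4)
    map_id = buf[52 * 4 : 52 * 4 + 4]
    if map_id not in (b"MAP ", b"\x00\x00\x00\x00"):
        raise FormatError(f"field MAP: bad identifier {map_id!r}")
    if mode not in _MODE_DTYPES:
        raise FormatError(f"field MODE: unsupported mode {mode}")
    if min(nx, ny, nz) < 1:
        raise FormatError(f"field NX/NY/NZ: non-positive dims ({nx}, {ny}, {nz})")
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise FormatError(f"field MAPC/MAPR/MAPS: bad axis codes ({mapc},{mapr},{maps})")
    return {
        "ncrs": (nx, ny, nz),
        "mode": mode,
        "nstart": (nxs, nys, nzs),
        "m": (mx, my, mz),
        "cella": (ca, cb, cc),
        "crs_axes": (mapc, mapr, maps),
        "origin": origin,
        "nsymbt": fields[23],
    }


def read_map_bytes(buf: bytes) -> VolumeGrid:
    """Decode map bytes into a canonically-ordered :class:`VolumeGrid`."""
    h = _read_header(buf)
    dtype = _MODE_DTYPES[h["mode"]]
    nc, nr, ns = h["ncrs"]
    start = HEADER_SIZE + h["nsymbt"]
    count = nc * nr * ns
    data = np.frombuffer(buf, dtype=dtype, count=count, offset=start)
    if data.size < count:
        raise FormatError(
            f"truncated map data: expected {count} voxels, got {data.size}"
        )
    disk = data.reshape(ns, nr, nc)  # C order: sections, rows, columns
    # axis codes of disk.T's axes are (mapc, mapr, maps); permute to (x, y, z)
    codes = h["crs_axes"]
    perm = [codes.index(ax + 1) for ax in range(3)]
    values = np.transpose(disk.T, perm).astype(np.float64)

    voxel_size = tuple(
        (c / m) if (c > 0 and m > 0) else 0.0
        for c, m in zip(h["cella"], h["m"])
    )
    if any(abs(o) > 0 for o in h["origin"]):
        origin = tuple(float(o) for o in h["origin"])
    else:
        # legacy CCP4 convention: origin from start indices, in crs order
        nstart_xyz = [0, 0, 0]
        for pos, code in enumerate(codes):
            nstart_xyz[code - 1] = h["nstart"][pos]
        origin = tuple(float(n * v) for n, v in zip(nstart_xyz, voxel_size))
    return VolumeGrid(values=np.ascontiguousarray(values), voxel_size=voxel_size,
                      origin=origin)


def read_map(path: Union[str, Path]) -> VolumeGrid:
    """Read an MRC/CCP4 map file; see :func:`read_map_bytes`."""
    return read_map_bytes(Path(path).read_bytes())


def write_map_bytes(grid: Union[VolumeGrid, LabelGrid]) -> bytes:
    """Encode a grid as an MRC2014 map (mode 2 floats, mode 1/6 for labels)."""
    if isinstance(grid, LabelGrid):
        arr = grid.labels
        maxlab = int(arr.max(initial=0))
        if maxlab <= np.iinfo(np.int16).max and int(arr.min(initial=0)) >= np.iinfo(np.int16).min:
            mode, data = 1, arr.astype("<i2")
        elif maxlab <= np.iinfo(np.uint16).max:
            mode, data = 6, arr.astype("<u2")
        else:
            mode, data = 2, arr.astype("<f4")
        voxel_size = (0.0, 0.0, 0.0)
        origin = (0.0, 0.0, 0.0)
    else:
        mode, data = 2, grid.values.astype("<f4")
        voxel_size = grid.voxel_size
        origin = grid.origin

    nx, ny, nz = data.shape
    cella = tuple(v * n for v, n in zip(voxel_size, (nx, ny, nz)))
    fdata = data.astype(np.float64)
    out = io.BytesIO()
    out.write(_HDR.pack(
        nx, ny, nz, mode,
        0, 0, 0,
        nx, ny, nz,
        *[float(c) for c in cella],
        90.0, 90.0, 90.0,
        1, 2, 3,
        float(fdata.min()), float(fdata.max()), float(fdata.mean()),
        1, 0,
    ))
    pos = out.tell()
    out.write(b"\x00" * (49 * 4 - pos))
    out.write(struct.pack("<3f", *[float(o) for o in origin]))
    out.write(b"MAP ")
    out.write(b"\x44\x44\x00\x00")  # little-endian machine stamp
    out.write(struct.pack("<f", float(fdata.std())))
    out.write(b"\x00" * (HEADER_SIZE - out.tell()))
    # disk layout: sections, rows, columns == z, y, x for mapc,mapr,maps=1,2,3
    out.write(np.ascontiguousarray(data.T).tobytes())
    return out.getvalue()


def write_map(grid: Union[VolumeGrid, LabelGrid], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_bytes(write_map_bytes(grid))
    return path


_INT_TOLERANCE = 1e-6


def labels_from_grid(grid: VolumeGrid) -> LabelGrid:
    """Exact-cast a scalar grid to integer labels (tolerance 1e-6)."""
    rounded = np.rint(grid.values)
    if np.abs(grid.values - rounded).max(initial=0.0) > _INT_TOLERANCE:
        raise FormatError("mask voxels are not integral within tolerance 1e-06")
    if rounded.min(initial=0) < 0:
        raise FormatError("mask contains negative labels")
    return LabelGrid(labels=rounded.astype(np.int32))


def read_mask(path: Union[str, Path], segmentation_id: str | None = None
              ) -> LatticeSegmentation:
    """Read a label mask map as a single-frame, full-resolution segmentation.

    The segmentation id defaults to the file stem (``emd_1273_msk_1.map`` →
    ``emd_1273_msk_1``).  An all-zero mask is legal and yields an empty
    segment set with a warning.
    """
    import warnings

    path = Path(path)
    grid = read_map(path)
    labels = labels_from_grid(grid)
    if not labels.label_set():
        warnings.warn(f"mask {path.name} contains no nonzero labels", stacklevel=2)
    sid = segmentation_id or path.name.rsplit(".", 1)[0]
    return LatticeSegmentation(
        segmentation_id=sid,
        frames={0: {1: labels}},
        voxel_size=grid.voxel_size,
        origin=grid.origin,
    )
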
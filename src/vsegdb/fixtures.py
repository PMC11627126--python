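"""Deterministic synthetic fixtures for every supported input kind.

Every generator is byte-deterministic given (parameters, seed), which keeps
round-trip tests and end-to-end protocol emulations fully offline: the
worked database entries (an EMDB-style map + SFF pair, an IDR-style
multi-channel OME-Zarr time series, an OME-TIFF series, a tomogram with
STAR-derived particle spheres and a zeroed map header, a map with five
label masks) are emulated at desk scale instead of downloaded.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np
import tifffile
import zarr

from .errors import VsegError
from .io.mrc import write_map
from .models import LabelGrid, VolumeGrid

__all__ = [
    "make_volume_fixture",
    "make_mask_fixture",
    "make_star_fixture",
    "make_multiscale_fixture",
    "make_sff_fixture",
]


def _blob_field(dims: Sequence[int], rng: np.random.Generator,
                n_blobs: int = 3) -> np.ndarray:
    """Sum of random anisotropic Gaussian blobs on the grid, values ~[0, 1]."""
    nx, ny, nz = dims
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    field = np.zeros(dims, dtype=np.float64)
    for _ in range(n_blobs):
        cx, cy, cz = (rng.uniform(0.2, 0.8) * np.array([nx, ny, nz]))
        sx, sy, sz = rng.uniform(0.08, 0.25, 3) * np.array([nx, ny, nz])
        field += np.exp(-(((ix - cx) / sx) ** 2 + ((iy - cy) / sy) ** 2
                          + ((iz - cz) / sz) ** 2))
    peak = field.max()
    return field / peak if peak > 0 else field


def make_volume_fixture(dims: Sequence[int] = (32, 32, 32),
                        voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
                        pattern: str = "gaussian-blob",
                        cella_zero: bool = False,
                        seed: int = 0,
                        out_path: Union[str, Path] = "volume.map",
                        constant: float = 1.0) -> Path:
    """Write a synthetic MRC volume.

    ``cella_zero`` zeroes the unit cell in the header, reproducing the
    broken-header condition of tomograms whose voxel size must be supplied
    through an extra-data override.
    """
    rng = np.random.default_rng(seed)
    dims = tuple(int(d) for d in dims)
    if pattern == "gaussian-blob":
        values = _blob_field(dims, rng)
    elif pattern == "gradient":
        values = np.add.outer(
            np.add.outer(np.linspace(0, 1, dims[0]), np.linspace(0, 1, dims[1])),
            np.linspace(0, 1, dims[2])) / 3.0
    elif pattern == "constant":
        values = np.full(dims, float(constant))
    else:
        raise VsegError(f"unknown pattern {pattern!r}")
    vs = (0.0, 0.0, 0.0) if cella_zero else tuple(float(v) for v in voxel_size)
    return write_map(VolumeGrid(values=values, voxel_size=vs), out_path)


def make_mask_fixture(dims: Sequence[int] = (32, 32, 32),
                      n_segments: int = 2,
                      seed: int = 0,
                      out_path: Union[str, Path] = "mask.map",
                      voxel_size: Sequence[float] = (1.0, 1.0, 1.0)) -> Path:
    """Write a label mask with exactly ``n_segments`` compact spherical blobs."""
    dims = tuple(int(d) for d in dims)
    if n_segments > int(np.prod(dims)):
        raise VsegError(f"{n_segments} segments cannot fit in {dims} voxels")
    rng = np.random.default_rng(seed)
    labels = np.zeros(dims, dtype=np.int32)
    ix, iy, iz = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    for seg in range(1, n_segments + 1):
        for _attempt in range(100):
            center = rng.uniform(0.15, 0.85, 3) * np.array(dims)
            radius = rng.uniform(0.08, 0.2) * min(dims)
            sphere = ((ix - center[0]) ** 2 + (iy - center[1]) ** 2
                      + (iz - center[2]) ** 2) <= radius ** 2
            fresh = sphere & (labels == 0)
            if fresh.any():
                labels[fresh] = seg
                break
        else:  # guarantee the label exists even on a crowded grid
            free = np.argwhere(labels == 0)
            labels[tuple(free[0])] = seg
    grid = LabelGrid(labels=labels)
    # voxel geometry rides in the header via a VolumeGrid-like cell
    path = Path(out_path)
    from .io.mrc import write_map_bytes

    raw = bytearray(write_map_bytes(grid))
    # stamp the unit cell so the mask carries a voxel size like real masks
    import struct

    cella = tuple(float(v) * d for v, d in zip(voxel_size, dims))
    struct.pack_into("<3f", raw, 10 * 4, *cella)
    path.write_bytes(bytes(raw))
    return path


def make_star_fixture(n_rows: int = 10,
                      coordinate_range: tuple[float, float] = (0.0, 4000.0),
                      seed: int = 0,
                      out_path: Union[str, Path] = "particles.star",
                      multiple_of: Optional[int] = 4) -> Path:
    """Write a particle table with rlnCoordinateX/Y/Z columns.

    With ``multiple_of`` set, coordinates are drawn on that integer lattice
    so divide-then-scale center arithmetic is exact in floating point.
    """
    rng = np.random.default_rng(seed)
    lo, hi = coordinate_range
    if multiple_of:
        coords = rng.integers(int(lo) // multiple_of,
                              max(int(hi) // multiple_of, 1),
                              size=(n_rows, 3)) * multiple_of
        coords = coords.astype(float)
    else:
        coords = rng.uniform(lo, hi, size=(n_rows, 3))
    lines = [
        "",
        "data_particles",
        "",
        "loop_",
        "_rlnCoordinateX #1",
        "_rlnCoordinateY #2",
        "_rlnCoordinateZ #3",
        "_rlnAngleRot #4",
    ]
    for row in coords:
        rot = rng.uniform(-180, 180)
        lines.append(f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f} {rot:.6f}")
    path = Path(out_path)
    path.write_text("\n".join(lines) + "\n")
    return path


def make_multiscale_fixture(out_path: Union[str, Path],
                            flavor: str = "omezarr",
                            axes: str = "tczyx",
                            shape: Sequence[int] = (3, 2, 8, 16, 16),
                            channel_labels: Optional[Sequence[str]] = None,
                            unit: str = "micrometer",
                            scale: float = 0.5,
                            with_labels: bool = False,
                            seed: int = 0) -> Path:
    """Write an OME-Zarr group or an OME-TIFF series.

    ``axes``/``shape`` describe the source array (axis names from t,c,z,y,x
    in that order).  For the zarr flavor, ``with_labels`` adds a ``labels``
    subgroup holding one small label image.  For the tiff flavor a file
    ``<stem>_C{c}_TP{t}.ome.tif`` is written per channel/time point and the
    first file's path is returned.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    if len(axes) != len(shape):
        raise VsegError("axes and shape must have equal length")
    data = rng.random(shape).astype(np.float32)
    out_path = Path(out_path)

    if flavor == "omezarr":
        root = zarr.open_group(str(out_path), mode="w", zarr_format=2)
        axis_meta = []
        ms_scale = []
        for name in axes:
            if name in "xyz":
                axis_meta.append({"name": name, "type": "space", "unit": unit})
                ms_scale.append(scale)
            elif name == "t":
                axis_meta.append({"name": name, "type": "time"})
                ms_scale.append(1.0)
            else:
                axis_meta.append({"name": name, "type": "channel"})
                ms_scale.append(1.0)
        root.attrs["multiscales"] = [{
            "version": "0.4", "axes": axis_meta,
            "datasets": [{"path": "0", "coordinateTransformations": [
                {"type": "scale", "scale": ms_scale}]}],
        }]
        if channel_labels is not None:
            root.attrs["omero"] = {
                "channels": [{"label": lab} for lab in channel_labels]}
        arr = root.create_array("0", shape=shape, dtype="f4",
                                chunks=shape)
        arr[:] = data
        if with_labels:
            spatial = [n for n in axes if n in "tzyx"]
            lshape = tuple(s for n, s in zip(axes, shape) if n in "tzyx")
            labels_grp = root.create_group("labels")
            labels_grp.attrs["labels"] = ["seg"]
            seg = labels_grp.create_group("seg")
            seg.attrs["multiscales"] = [{
                "version": "0.4",
                "axes": [a for a in axis_meta if a["name"] in "tzyx"],
                "datasets": [{"path": "0", "coordinateTransformations": [
                    {"type": "scale",
                     "scale": [s for n, s in zip(axes, ms_scale)
                               if n in "tzyx"]}]}],
            }]
            lab_data = (rng.random(lshape) > 0.7).astype(np.int32)
            # carve a second label so the lattice has two segments
            lab_data[lab_data.astype(bool) & (rng.random(lshape) > 0.5)] = 2
            larr = seg.create_array("0", shape=lshape, dtype="i4",
                                    chunks=lshape)
            larr[:] = lab_data
            del spatial
        return out_path

    if flavor == "ometiff-series":
        if "y" not in axes or "x" not in axes:
            raise VsegError("tiff flavor needs y and x axes")
        nt = shape[axes.index("t")] if "t" in axes else 1
        nc = shape[axes.index("c")] if "c" in axes else 1
        full = data
        # normalize to (t, c, z, y, x)
        for i, name in enumerate("tczyx"):
            if name not in axes:
                full = np.expand_dims(full, i)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        stem = out_path.name
        for suffix in (".ome.tif", ".ome.tiff"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
        first = None
        for c in range(nc):
            for t in range(nt):
                fpath = out_path.parent / f"{stem}_C{c}_TP{t}.ome.tif"
                tifffile.imwrite(
                    fpath, full[t, c], photometric="minisblack",
                    metadata={"axes": "ZYX",
                              "PhysicalSizeX": scale, "PhysicalSizeXUnit": unit,
                              "PhysicalSizeY": scale, "PhysicalSizeYUnit": unit,
                              "PhysicalSizeZ": scale, "PhysicalSizeZUnit": unit})
                if first is None:
                    first = fpath
        return first

    raise VsegError(f"unknown flavor {flavor!r}")


def make_sff_fixture(out_path: Union[str, Path],
                     dims: Sequence[int] = (24, 24, 24),
                     segment_names: Sequence[str] = ("CMG",),
                     with_mesh: bool = False,
                     voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
                     seed: int = 0) -> Path:
    """Write a synthetic EMDB-SFF-style HDF5 segmentation.

    One lattice with one labelled region per entry of ``segment_names``
    (labels 1..n), each segment carrying a biological name and a color;
    optionally one extra mesh segment (a tetrahedron).
    """
    rng = np.random.default_rng(seed)
    dims = tuple(int(d) for d in dims)
    labels = np.zeros(dims, dtype=np.int32)
    ix, iy, iz = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    for value in range(1, len(segment_names) + 1):
        center = rng.uniform(0.2, 0.8, 3) * np.array(dims)
        radius = rng.uniform(0.1, 0.2) * min(dims)
        sphere = ((ix - center[0]) ** 2 + (iy - center[1]) ** 2
                  + (iz - center[2]) ** 2) <= radius ** 2
        labels[sphere & (labels == 0)] = value

    out_path = Path(out_path)
    with h5py.File(out_path, "w") as f:
        f.attrs["voxel_size"] = [float(v) for v in voxel_size]
        lat = f.create_group("lattice_list").create_group("0")
        lat.create_dataset("data", data=labels, compression="gzip")
        seg_list = f.create_group("segment_list")
        for value, name in enumerate(segment_names, start=1):
            sgrp = seg_list.create_group(str(value))
            bio = sgrp.create_group("biological_annotation")
            bio.create_dataset("name", data=name)
            bio.create_dataset("description",
                               data=f"synthetic segment emulating {name}")
            sgrp.create_dataset("colour", data=rng.uniform(0, 1, 3).tolist()
                                + [1.0])
            vol = sgrp.create_group("three_d_volume")
            vol.create_dataset("lattice_id", data="0")
            vol.create_dataset("value", data=value)
        if with_mesh:
            sgrp = seg_list.create_group(str(len(segment_names) + 1))
            bio = sgrp.create_group("biological_annotation")
            bio.create_dataset("name", data="synthetic mesh segment")
            sgrp.create_dataset("colour", data=[0.5, 0.5, 0.5, 1.0])
            mesh = sgrp.create_group("mesh_list").create_group("0")
            mesh.create_dataset("vertices", data=np.array(
                [[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float))
            mesh.create_dataset("triangles", data=np.array(
                [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]], dtype=np.int64))
    return out_path
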
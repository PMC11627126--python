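"""Multiscale downsampling pyramids.

Each level halves every axis (level factor 1, 2, 4, ...).  Scalar grids are
reduced by the 2×2×2 block mean; label grids by block majority vote with
ties broken toward the smallest label (background 0 participates like any
other label).  Edge blocks on odd-sized axes hold fewer than 8 voxels and
are reduced over the voxels they actually contain, so level-f dims are
exactly ``ceil(dims/f)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .models import LabelGrid, LabelPyramid, Pyramid, VolumeGrid


@dataclass
class PyramidPolicy:
    """Bounds on pyramid depth.

    Downsampling stops once every dim is at most ``stop_dim`` or the level
    factor reaches ``max_level_factor``.  ``min_level_factor`` drops
    intermediate coarse levels below it (full resolution is always kept).
    """

    min_level_factor: int = 1
    max_level_factor: int = 64
    stop_dim: int = 32

    def __post_init__(self) -> None:
        for f in (self.min_level_factor, self.max_level_factor):
            if f < 1 or (f & (f - 1)):
                raise ValueError(f"level factors must be powers of two, got {f}")
        if self.min_level_factor > self.max_level_factor:
            raise ValueError("min_level_factor must be <= max_level_factor")


def downsample_block_mean(block: np.ndarray) -> float:
    """Arithmetic mean of an up-to-2×2×2 scalar block."""
    block = np.asarray(block, dtype=np.float64)
    if block.size == 0:
        raise ValueError("empty block")
    return float(block.mean())


def downsample_block_majority(block: np.ndarray) -> int:
    """Most frequent label of an up-to-2×2×2 block; ties → smallest label."""
    block = np.asarray(block).ravel()
    if block.size == 0:
        raise ValueError("empty block")
    labels, counts = np.unique(block, return_counts=True)
    return int(labels[np.argmax(counts)])  # unique() is sorted → first max wins


def _halve_mean(values: np.ndarray) -> np.ndarray:
    nx, ny, nz = values.shape
    ox, oy, oz = -(-nx // 2), -(-ny // 2), -(-nz // 2)
    padded = np.full((ox * 2, oy * 2, oz * 2), np.nan)
    padded[:nx, :ny, :nz] = values
    blocks = padded.reshape(ox, 2, oy, 2, oz, 2)
    return np.nanmean(blocks, axis=(1, 3, 5))


def _halve_majority(labels: np.ndarray) -> np.ndarray:
    nx, ny, nz = labels.shape
    ox, oy, oz = -(-nx // 2), -(-ny // 2), -(-nz // 2)
    uniq, inv = np.unique(labels, return_inverse=True)
    inv = inv.reshape(labels.shape)
    n_out = ox * oy * oz
    counts = np.zeros((n_out, len(uniq)), dtype=np.int32)
    cell = (
        np.arange(ox)[:, None, None] * (oy * oz)
        + np.arange(oy)[None, :, None] * oz
        + np.arange(oz)[None, None, :]
    )
    for dx in range(2):
        for dy in range(2):
            for dz in range(2):
                sub = inv[dx::2, dy::2, dz::2]
                cells = cell[: sub.shape[0], : sub.shape[1], : sub.shape[2]]
                np.add.at(counts, (cells.ravel(), sub.ravel()), 1)
    # argmax returns the first maximum; uniq is ascending → smallest label wins
    winner = uniq[np.argmax(counts, axis=1)]
    return winner.reshape(ox, oy, oz).astype(labels.dtype)


def _level_factors(dims: tuple[int, int, int], policy: PyramidPolicy) -> list[int]:
    factors = [1]
    f = 1
    cur = dims
    while f < policy.max_level_factor and any(d > policy.stop_dim for d in cur):
        f *= 2
        cur = tuple(-(-d // 2) for d in cur)
        factors.append(f)
    return factors


def build_pyramid(grid: Union[VolumeGrid, LabelGrid],
                  policy: PyramidPolicy | None = None
                  ) -> Union[Pyramid, LabelPyramid]:
    """Full pyramid for one grid, keyed by level factor."""
    policy = policy or PyramidPolicy()
    is_labels = isinstance(grid, LabelGrid)
    dims = grid.dims
    factors = _level_factors(dims, policy)

    levels: dict[int, Union[VolumeGrid, LabelGrid]] = {1: grid}
    prev = grid.labels if is_labels else grid.values
    for f in factors[1:]:
        prev = _halve_majority(prev) if is_labels else _halve_mean(prev)
        if is_labels:
            levels[f] = LabelGrid(labels=prev)
        else:
            levels[f] = VolumeGrid(
                values=prev,
                voxel_size=tuple(v * f for v in grid.voxel_size),
                origin=grid.origin,
            )
    keep = {f for f in levels if f == 1 or policy.min_level_factor <= f}
    return {f: g for f, g in levels.items() if f in keep}
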
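"""RELION-style STAR particle tables → geometric (sphere) segmentations.

Only the subset of STAR needed for particle tables is handled: one or more
``data_`` blocks with ``loop_`` column headers (``_rlnCoordinateX`` etc.)
and whitespace-separated rows.  Particle positions are converted to Å as

    center = (coordinate / star_file_coordinate_divisor) * pixel_size

so bin-1 coordinates paired with a bin-4 tomogram (divisor 4, pixel size
7.84 Å) land on the binned grid.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Union

from ..errors import FormatError, ParseError
from ..models import GeometricSegmentation, SpherePrimitive, StarParseConfig

_COORD_RE = {
    "x": re.compile(r"CoordinateX$", re.IGNORECASE),
    "y": re.compile(r"CoordinateY$", re.IGNORECASE),
    "z": re.compile(r"CoordinateZ$", re.IGNORECASE),
}


def read_star_table(path: Union[str, Path]) -> tuple[list[str], list[list[str]]]:
    """Parse the first loop block of a STAR file into (columns, rows)."""
    lines = Path(path).read_text().splitlines()
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    header_done = False
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            if header_done and rows:
                break  # only the first populated block
            continue
        if line == "loop_":
            in_loop, header_done = True, False
            columns, rows = [], []
            continue
        if in_loop and line.startswith("_"):
            if header_done:
                raise ParseError(f"column header {line!r} after data rows began")
            columns.append(line.split()[0].lstrip("_"))
            continue
        if in_loop and columns:
            header_done = True
            vals = line.split()
            if len(vals) != len(columns):
                raise ParseError(
                    f"row has {len(vals)} fields, expected {len(columns)}: {line!r}"
                )
            rows.append(vals)
    if not columns:
        raise ParseError("no loop_ block with column headers found")
    return columns, rows


def _coordinate_columns(columns: list[str]) -> dict[str, int]:
    out = {}
    for axis, pat in _COORD_RE.items():
        hits = [i for i, c in enumerate(columns) if pat.search(c)]
        if not hits:
            raise FormatError(f"missing coordinate column for axis {axis.upper()} "
                              f"(expected a *Coordinate{axis.upper()} column)")
        out[axis] = hits[0]
    return out


def parse_star_to_geometric(star_path: Union[str, Path],
                            config: StarParseConfig,
                            time: int = 0) -> GeometricSegmentation:
    """One sphere per particle row, centers converted to Å per the config."""
    columns, rows = read_star_table(star_path)
    idx = _coordinate_columns(columns)
    color = config.color_rgba()
    scale = config.pixel_size / config.star_file_coordinate_divisor
    spheres = []
    for i, row in enumerate(rows):
        center = tuple(float(row[idx[a]]) * scale for a in ("x", "y", "z"))
        spheres.append(SpherePrimitive(id=i, center=center,
                                       radius=config.sphere_radius, color=color))
    if not spheres:
        warnings.warn(f"{Path(star_path).name}: no particle rows; "
                      "writing an empty segmentation", stacklevel=2)
    return GeometricSegmentation(segmentation_id=config.segmentation_id,
                                 frames={time: spheres})


# ---------------------------------------------------------------------------
# the geometric-segmentation input JSON dialect
# ---------------------------------------------------------------------------


def geometric_to_json_doc(seg: GeometricSegmentation) -> dict:
    return {
        "segmentation_id": seg.segmentation_id,
        "time_frames": {
            str(t): [
                {
                    "id": s.id,
                    "center": [float(c) for c in s.center],
                    "radius": float(s.radius),
                    "color": [float(c) for c in s.color],
                }
                for s in spheres
            ]
            for t, spheres in sorted(seg.frames.items())
        },
    }


def write_geometric_json(seg: GeometricSegmentation, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(geometric_to_json_doc(seg), indent=2, sort_keys=True)
                    + "\n")
    return path


def load_geometric_json(source: Union[str, Path, dict]) -> GeometricSegmentation:
    if isinstance(source, dict):
        doc = source
    else:
        try:
            doc = json.loads(Path(source).read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"geometric segmentation JSON: {exc}") from exc
    try:
        frames = {
            int(t): [
                SpherePrimitive(id=int(s["id"]),
                                center=tuple(float(c) for c in s["center"]),
                                radius=float(s["radius"]),
                                color=tuple(float(c) for c in s.get(
                                    "color", (1.0, 1.0, 1.0, 1.0))))
                for s in spheres
            ]
            for t, spheres in doc["time_frames"].items()
        }
        return GeometricSegmentation(segmentation_id=doc["segmentation_id"],
                                     frames=frames)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"bad geometric segmentation document: {exc}") from exc
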
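"""Domain types shared by every module.

In-memory grids are numpy arrays of shape ``(nx, ny, nz)`` indexed
``[ix, iy, iz]`` — x is the fastest-varying axis everywhere in the toolkit;
readers permute their on-disk layouts into this convention.  All spatial
quantities are in Ångström; readers convert (1 µm = 1e4 Å).

Annotation and extra-data documents are validated against pydantic models
(`EntryAnnotations`, `ExtraData`); :func:`validate_annotations` /
:func:`validate_extra_data` return human-readable violation lists instead of
raising, so callers can report every problem at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ParseError

RGBA = tuple[float, float, float, float]

#: Spatial unit conversion: micrometres to Ångström.
UM_TO_ANGSTROM = 1.0e4

#: Table-1 default for max_points (effectively "no limit" for desk-scale grids).
DEFAULT_MAX_POINTS = 1_000_000_000_000

SEGMENTATION_KINDS = ("lattice", "mesh", "geometric-segmentation")


# ---------------------------------------------------------------------------
# grids and volumes
# ---------------------------------------------------------------------------


def grid_stats(values: np.ndarray) -> dict[str, float]:
    """(min, max, mean, sd) of a scalar grid, as plain floats."""
    v = np.asarray(values, dtype=np.float64)
    return {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std()),
    }


@dataclass
class VolumeGrid:
    """One scalar lattice with its voxel geometry.

    ``voxel_size`` components of 0 mark an invalid header (e.g. a map whose
    cell dimensions are zeroed) pending an extra-data override; they are
    preserved, not rejected.
    """

    values: np.ndarray  # float array, shape (nx, ny, nz)
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"grid must be 3D, got ndim={self.values.ndim}")
        if any(s < 1 for s in self.values.shape):
            raise ValueError(f"grid dims must be >= 1, got {self.values.shape}")
        if any(c < 0 for c in self.voxel_size):
            raise ValueError(f"voxel_size must be >= 0, got {self.voxel_size}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(d) for d in self.values.shape)  # type: ignore[return-value]

    @property
    def voxel_size_valid(self) -> bool:
        return all(c > 0 for c in self.voxel_size)

    @property
    def stats(self) -> dict[str, float]:
        return grid_stats(self.values)


@dataclass
class LabelGrid:
    """Non-negative integer lattice; 0 is background."""

    labels: np.ndarray  # int array, shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label grid must hold integers")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(d) for d in self.labels.shape)  # type: ignore[return-value]

    def label_set(self) -> set[int]:
        """Distinct nonzero labels present in the grid."""
        u = np.unique(self.labels)
        return {int(x) for x in u if x != 0}


# pyramid: level_factor (1, 2, 4, ...) -> grid
Pyramid = dict[int, VolumeGrid]
LabelPyramid = dict[int, LabelGrid]


@dataclass
class MultiscaleVolume:
    """Per-channel pyramid of scalar grids, one pyramid per time frame."""

    channel_id: str
    frames: dict[int, Pyramid]  # time index -> {factor: VolumeGrid}

    def time_indices(self) -> list[int]:
        return sorted(self.frames)

    def level_factors(self) -> list[int]:
        first = self.frames[min(self.frames)]
        return sorted(first)


@dataclass
class LatticeSegmentation:
    """Segmentation stored as an integer label grid aligned to the volume."""

    segmentation_id: str
    frames: dict[int, LabelPyramid]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def time_indices(self) -> list[int]:
        return sorted(self.frames)

    def level_factors(self) -> list[int]:
        return sorted(self.frames[min(self.frames)])

    @property
    def segment_ids(self) -> set[int]:
        """Union of nonzero labels at full resolution across frames."""
        out: set[int] = set()
        for pyr in self.frames.values():
            out |= pyr[1].label_set()
        return out


@dataclass
class SpherePrimitive:
    id: int
    center: tuple[float, float, float]  # Å
    radius: float  # Å
    color: RGBA = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be > 0")
        if any(not (0.0 <= c <= 1.0) for c in self.color):
            raise ValueError("color components must be in [0, 1]")


@dataclass
class GeometricSegmentation:
    """Segmentation expressed as shape primitives (spheres), per time frame."""

    segmentation_id: str
    frames: dict[int, list[SpherePrimitive]]

    def __post_init__(self) -> None:
        for t, spheres in self.frames.items():
            ids = [s.id for s in spheres]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate sphere ids in frame {t}")

    def time_indices(self) -> list[int]:
        return sorted(self.frames)


@dataclass
class MeshSegmentation:
    """Triangle meshes per segment id."""

    segmentation_id: str
    # segment_id -> (vertices [N,3] Å, triangles [M,3] vertex indices)
    segments: dict[int, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        for sid, (verts, tris) in self.segments.items():
            verts = np.asarray(verts, dtype=np.float64).reshape(-1, 3)
            tris = np.asarray(tris, dtype=np.int64).reshape(-1, 3)
            if tris.size and tris.max() >= len(verts):
                raise ValueError(
                    f"segment {sid}: triangle index {tris.max()} out of range "
                    f"for {len(verts)} vertices"
                )
            self.segments[sid] = (verts, tris)


@dataclass
class StarParseConfig:
    """Parameters of the STAR-table → sphere conversion."""

    sphere_radius: float  # Å
    segmentation_id: str
    sphere_color_hex: str = "FFFFFF"
    pixel_size: float = 1.0  # Å per (binned) pixel
    star_file_coordinate_divisor: float = 1.0

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be > 0")
        if self.star_file_coordinate_divisor <= 0:
            raise ValueError("star_file_coordinate_divisor must be > 0")
        self.color_rgba()  # validate eagerly

    def color_rgba(self) -> RGBA:
        h = self.sphere_color_hex.lstrip("#")
        if len(h) != 6:
            raise ValueError(f"expected 6 hex digits, got {self.sphere_color_hex!r}")
        try:
            r, g, b = (int(h[i : i + 2], 16) / 255.0 for i in (0, 2, 4))
        except ValueError as exc:
            raise ValueError(f"bad color hex {self.sphere_color_hex!r}") from exc
        return (r, g, b, 1.0)


# ---------------------------------------------------------------------------
# annotation document model
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ExternalReference(_Strict):
    resource: Optional[str] = None
    accession: Optional[str] = None
    label: Optional[str] = None
    description: Optional[str] = None


class DetailsObject(_Strict):
    format: Literal["text", "markdown"]
    text: str


class DescriptionTarget(_Strict):
    segmentation_id: str
    segment_id: Optional[int] = None


class Description(_Strict):
    """Semantic annotation record for a segment or for the entry as a whole."""

    id: str
    target_kind: Literal["lattice", "mesh", "primitive", "entry"]
    target: Optional[DescriptionTarget] = None
    name: Optional[str] = None
    details: Optional[Union[str, DetailsObject]] = None
    external_references: list[ExternalReference] = Field(default_factory=list)
    is_hidden: bool = False
    time: Optional[int] = None

    @model_validator(mode="after")
    def _target_required_unless_entry(self) -> "Description":
        if self.target_kind != "entry" and self.target is None:
            raise ValueError("target is required unless target_kind is 'entry'")
        return self


def _check_rgba(v: Any) -> list[float]:
    vals = [float(x) for x in v]
    if len(vals) != 4:
        raise ValueError("color must have 4 components (RGBA)")
    if any(not (0.0 <= x <= 1.0) for x in vals):
        raise ValueError("color components must be in [0, 1]")
    return vals


class SegmentAnnotation(_Strict):
    """Rendering annotation (color) for one segment at an optional time."""

    id: str
    segment_kind: Literal["lattice", "mesh", "primitive"]
    segmentation_id: str
    segment_id: int
    color: list[float]
    time: Optional[int] = None

    @field_validator("color")
    @classmethod
    def _rgba(cls, v: Any) -> list[float]:
        return _check_rgba(v)


class ChannelAnnotation(_Strict):
    channel_id: str
    color: list[float]
    label: Optional[str] = None

    @field_validator("color")
    @classmethod
    def _rgba(cls, v: Any) -> list[float]:
        return _check_rgba(v)


class AnnotationEntryId(_Strict):
    source_db_name: str
    source_db_id: str


class EntryAnnotations(_Strict):
    """The annotations.json document."""

    entry_id: AnnotationEntryId
    name: Optional[str] = None
    descriptions: dict[str, Description] = Field(default_factory=dict)
    segment_annotations: list[SegmentAnnotation] = Field(default_factory=list)
    volume_channels_annotations: list[ChannelAnnotation] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consistency(self) -> "EntryAnnotations":
        for key, desc in self.descriptions.items():
            if desc.id != key:
                raise ValueError(f"description key {key!r} != its id {desc.id!r}")
        seen = set()
        for sa in self.segment_annotations:
            k = (sa.segment_kind, sa.segmentation_id, sa.segment_id, sa.time)
            if k in seen:
                raise ValueError(f"duplicate segment annotation for {k}")
            seen.add(k)
        return self


class ExtraVolume(_Strict):
    voxel_size: Optional[list[float]] = None

    @field_validator("voxel_size")
    @classmethod
    def _three_positive(cls, v):
        if v is None:
            return v
        if len(v) != 3:
            raise ValueError("voxel_size needs exactly 3 components")
        if any(x <= 0 for x in v):
            raise ValueError("voxel_size components must be > 0")
        return [float(x) for x in v]


class ExtraSegmentation(_Strict):
    # segmentation_id -> {label-string: name}
    custom_segment_ids_mapping: Optional[dict[str, dict[str, str]]] = None


class ExtraData(_Strict):
    """Optional overrides applied during preprocessing; every field optional."""

    volume: Optional[ExtraVolume] = None
    segmentation: Optional[ExtraSegmentation] = None


# ---------------------------------------------------------------------------
# validation entry points
# ---------------------------------------------------------------------------


def _parse_doc(doc: Any) -> Any:
    if isinstance(doc, (str, bytes)):
        try:
            return json.loads(doc)
        except json.JSONDecodeError as exc:
            raise ParseError(f"not valid JSON: {exc}") from exc
    return doc


def _violations(model: type[BaseModel], doc: Any) -> list[str]:
    from pydantic import ValidationError

    data = _parse_doc(doc)
    try:
        model.model_validate(data)
    except ValidationError as exc:
        out = []
        for err in exc.errors():
            path = "/" + "/".join(str(p) for p in err["loc"])
            out.append(f"{path}: {err['msg']}")
        return sorted(out)
    return []


def validate_annotations(doc: Any) -> list[str]:
    """Violations of the annotations model; empty list means valid.

    Accepts a parsed document or JSON text; unparseable text raises
    :class:`ParseError` (distinct from validation failure).
    """
    return _violations(EntryAnnotations, doc)


def validate_extra_data(doc: Any) -> list[str]:
    """Violations of the extra-data model; empty list means valid."""
    return _violations(ExtraData, doc)


# ---------------------------------------------------------------------------
# keys, metadata, queries, settings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntryKey:
    source_db: str
    entry_id: str
    source_db_id: str = ""
    source_db_name: str = ""

    def __post_init__(self) -> None:
        if not self.source_db:
            raise ValueError("source_db must be non-empty")
        if not self.entry_id:
            raise ValueError("entry_id must be non-empty")
        object.__setattr__(self, "source_db", self.source_db.lower())
        if not self.source_db_id:
            object.__setattr__(self, "source_db_id", self.entry_id)
        if not self.source_db_name:
            object.__setattr__(self, "source_db_name", self.source_db)


class QueryParams(BaseModel):
    """Raw query document; ``None`` means "all available" per the defaults."""

    model_config = ConfigDict(extra="forbid")

    entry_id: str
    source_db: str
    segmentation_kind: Optional[Literal["mesh", "lattice", "geometric-segmentation"]] = None
    time: Optional[int] = None
    channel_id: Optional[str] = None
    segmentation_id: Optional[str] = None
    max_points: int = DEFAULT_MAX_POINTS


@dataclass
class ServerSettings:
    host: str = "0.0.0.0"
    port: int = 9000
    db_path: str = "preprocessor/temp/test_db"

    def __post_init__(self) -> None:
        if not (1 <= self.port <= 65535):
            raise ValueError(f"port must be in [1, 65535], got {self.port}")

    @classmethod
    def from_env(cls, environ=None) -> "ServerSettings":
        import os

        env = os.environ if environ is None else environ
        return cls(
            host=env.get("VSEGDB_HOST", cls.host),
            port=int(env.get("VSEGDB_PORT", cls.port)),
            db_path=env.get("VSEGDB_DB_PATH", cls.db_path),
        )


@dataclass
class EntryMetadata:
    """Inventory of one stored entry, mirrored by metadata.json.

    ``document`` is the canonical JSON-ready dict; helper accessors below
    read the pieces other modules need.
    """

    document: dict[str, Any] = field(default_factory=dict)

    # -- accessors -----------------------------------------------------
    @property
    def channel_ids(self) -> list[str]:
        return list(self.document.get("volumes", {}).get("channel_ids", []))

    @property
    def volume_time_indices(self) -> list[int]:
        return list(self.document.get("volumes", {}).get("time_frame_indices", []))

    def volume_levels(self) -> dict[int, tuple[int, int, int]]:
        """level_factor -> dims for the volume grids."""
        out = {}
        for k, v in self.document.get("volumes", {}).get("sampling_levels", {}).items():
            out[int(k)] = tuple(v["dims"])
        return out

    def lattice_inventory(self) -> list[dict[str, Any]]:
        return list(self.document.get("segmentations", {}).get("lattice", []))

    def geometric_inventory(self) -> list[dict[str, Any]]:
        return list(self.document.get("segmentations", {}).get("geometric", []))

    def mesh_inventory(self) -> list[dict[str, Any]]:
        return list(self.document.get("segmentations", {}).get("mesh", []))

    def to_json(self) -> str:
        return json.dumps(self.document, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: Union[str, bytes]) -> "EntryMetadata":
        try:
            return cls(document=json.loads(text))
        except json.JSONDecodeError as exc:
            raise ParseError(f"metadata is not valid JSON: {exc}") from exc
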
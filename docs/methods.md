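# Methods

## Data model

An **entry** is the unit of storage: the preprocessed form of one deposited
dataset, keyed by `(source_db, entry_id)`.  It holds

* per-channel, per-time-frame **volume pyramids** — float grids with voxel
  geometry (voxel size and origin in Å);
* **segmentations** of three kinds: *lattice* (integer label grids aligned
  to the volume, 0 = background), *geometric* (sphere primitives with
  center/radius/color, e.g. particle picks), and *mesh* (triangle meshes
  per segment);
* an **annotations document** separating rendering information (segment
  and channel colors) from biology (named descriptions with optional
  plain-text or markdown details and external references);
* a **metadata inventory** listing channels, time frames, sampling levels,
  grid geometry, per-channel value statistics, and every segmentation with
  its segment ids.

Conventions, applied by every reader: spatial unit is Å (µm × 10⁴, nm ×
10); in-memory grids are numpy arrays indexed `[x, y, z]` with x fastest;
time frames are 0-based consecutive integers; channel ids are strings even
when numeric.  Annotation and description ids are deterministic
(`desc-{segmentation_id}-{segment_id}`, `sa-...`), which makes repeated
preprocessing byte-stable and fixtures reproducible.

The annotations and extra-data schemas are authored here as pydantic
models; `validate_annotations` / `validate_extra_data` return a list of
violations (path + rule) rather than raising, and a syntactically
unparseable document is a distinct parse error.  Field-for-field parity
with any external schema file is not claimed; the narrative fields
(name, `details {format, text}`, external references, segment
annotations, channel annotations, `volume.voxel_size`,
`segmentation.custom_segment_ids_mapping`) are implemented.

## Downsampling pyramids

Every grid is stored at level factors 1, 2, 4, ... where level *f* has
dims `ceil(dims₁ / f)` per axis.  The kernel is fixed per grid kind:

* **scalar grids** — 2×2×2 block mean; edge blocks on odd axes average
  only the voxels they contain.  For dims divisible by the factor this
  conserves the global mean exactly (to 1e-12 in tests).
* **label grids** — 2×2×2 majority vote; ties break to the smallest
  label, and background 0 participates like any label.  Consequence: the
  label set at any coarser level is a subset of the full-resolution set.

These are the simplest order-independent choices; fancier kernels
(Gaussian prefilter, area-weighted vote) were deliberately not used
because payloads must stay exact integers for labels and cheap to verify.

Pyramid depth is bounded by a policy: downsampling stops once every axis
is at most `stop_dim` (default 32) or the factor reaches
`max_level_factor` (default 64); full resolution is always retained, and
`min_level_factor` can drop intermediate coarse levels.  The defaults
keep a desk-scale grid's pyramid within ~15% storage overhead of the base
level.  Limits are expressed as level *factors*, not level indices.

## Ingestion rules

* **MRC/CCP4 maps** — modes 0/1/2/6, little-endian; the crs→xyz axis
  permutation (`mapc/mapr/maps`) is honoured; voxel size is `cella / m`.
  A zeroed unit cell (seen in some deposited tomograms) yields voxel size
  0, flagged invalid but not rejected, so an extra-data override can
  repair it.  Origin comes from the MRC2014 origin words, else from the
  start indices times the voxel size.
* **Masks** — maps whose voxels are integers (tolerance 1e-6); distinct
  nonzero values become segment ids; the segmentation id defaults to the
  file stem.
* **EMDB-SFF** — HDF5 following the SFF structure (`lattice_list`,
  `segment_list` with `biological_annotation`, `colour`,
  `three_d_volume`/`mesh_list`).  Source names, descriptions and colors
  pass through to the annotations untouched.  Files carrying a
  `transform_list` are refused as unsupported rather than silently
  mis-placed.
* **OME-Zarr** — axes must be a subset of t,c,z,y,x; only the
  highest-resolution dataset of a source pyramid is read, because one
  downsampling rule (ours) should govern all entries; scale transforms
  convert to Å; channel ids come from omero channel labels when present;
  a `labels` subgroup yields lattice segmentations.
* **OME-TIFF series** — channel/time structure from the embedded OME-XML;
  multi-file series resolve via OME-XML file references with a
  `_C{n}_TP{m}` filename-pattern fallback.
* **STAR particle tables** — first populated `loop_` block; coordinate
  columns matched as `*CoordinateX/Y/Z` case-insensitively.  Sphere
  centers are `(coordinate / star_file_coordinate_divisor) × pixel_size`
  Å.  The user-supplied `pixel_size` is authoritative even when a target
  map provides its own voxel size — divide-then-scale is what maps bin-1
  picks onto a binned tomogram (divisor 4, pixel 7.84 Å for a 1.96 Å
  bin-4 reconstruction).
* Absent unit metadata anywhere is treated as Å with a logged warning
  (fail-soft, visible).

## Preprocessing pipeline

`preprocess --mode add` parses all inputs, builds pyramids, seeds
annotations, applies extra data, assembles metadata, and writes the entry.
Ordering details that matter:

* the extra-data JSON, when present, must be the first input (it is
  checked up front);
* annotations are seeded *before* extra data is applied, because
  `custom_segment_ids_mapping` renames the seeded descriptions; unknown
  mapping references warn instead of failing;
* a `voxel_size` override replaces the header-derived value on every grid
  and metadata record, scaled by the level factor on coarser levels;
* segments without source annotations get `Segment {label}` descriptions
  and colors from a fixed 10-color palette indexed by
  `(segment_id − 1) mod 10`;
* the entry directory is staged and renamed into place: a failure at any
  stage leaves the database without the new entry, and duplicate keys are
  refused with the first entry intact.

Determinism: preprocessing the same inputs twice into fresh databases
yields byte-identical `metadata.json`, `annotations.json` and `data.zip`
(sorted zip members, fixed timestamps, deflate level 6).

## Query resolution and CVSX

Query documents have two mandatory fields (`entry_id`, `source_db`); the
optional fields default to "everything": all channels, all time frames,
all segmentation kinds and ids, `max_points = 10¹²`.  A given `time`
restricts volumes **and** segmentations to that frame; segmentation
filters never restrict volumes.  Unknown inventory values produce
not-found errors listing the valid values.

`select_sampling_level` picks the smallest (finest) factor whose per-frame
voxel count is at most `max_points`, falling back to the coarsest level
when nothing fits, independently for volume and lattice grids; geometric
and mesh payloads are never downsampled.  The chosen factor *f* therefore
satisfies `count(f) ≤ max_points < count(f/2)` whenever a finer level
exists.

A CVSX archive is a plain ZIP with a mandatory `.cvsx` extension holding
exactly the selected payloads plus four JSON members: `query.json` (the
resolved selection, with the raw request under `"requested"` — archives
are self-documenting), `index.json` (describing every other member),
and annotations/metadata filtered to the selection.  `read_cvsx`
validates the index against the actual member list in both directions.
Payload encoding inside CVSX mirrors the store (MRC grids, JSON
sphere/mesh documents); compatibility with any particular viewer's
archive dialect is a non-goal.

## Annotation editing

Edit operations are pure functions on the parsed document, addressed by
RFC 6901 JSON pointers.  Search splits the query on whitespace and
matches nodes whose key or string leaf contains *all* keywords
case-insensitively; numeric and boolean leaves are not searched.  Commit
is write-temp-then-rename, validating first, so the stored file is always
either the old or the new complete document.  One deliberate exception:
the CLI's `retype`/`append` steps store drafts without full-model
validation, because the editing workflow passes through states (an empty
`details` object, a `format` without `text`) that the final document
model forbids; the pipeline itself only ever produces valid documents.

## Server

The API is a thin read-only layer over the store (stdlib HTTP server,
threaded): entry listing, byte-equal metadata/annotations, and grid
payloads at the level selected for the request's `max_points`.  Defaults
are host 0.0.0.0, port 9000, database path `preprocessor/temp/test_db`,
overridable programmatically, by CLI flags, or via `VSEGDB_HOST` /
`VSEGDB_PORT` / `VSEGDB_DB_PATH`.  The route inventory beyond the `/v1`
prefix is defined by this package and described at `/docs`.

## Synthetic fixtures and their limits

The fixture module generates deterministic stand-ins for the workflow's
entry types: Gaussian-blob/gradient/constant maps (optionally with a
zeroed unit cell), compact-blob label masks, particle tables with
lattice-aligned coordinates (multiples of 4 by default so divide-then-
scale arithmetic is exact), OME-Zarr groups with channel labels and a
labels subgroup, OME-TIFF series, and SFF-style HDF5 segmentations.

Test problem sizes are desk-scale by design: grids of 20³–64³ voxels,
2–3 channels, 3–4 time frames, ≤ 12 particles.  They exercise every
format path, the pyramid arithmetic, and the query/packing logic exactly,
but they do not emulate full-size repository data: no multi-gigabyte
grids, no deep source pyramids, no acquisition noise or anisotropic
point-spread, no exotic MRC modes, and SFF fixtures follow this package's
HDF5 dialect rather than any byte-level reference.  Passing tests
therefore demonstrate correctness of the transformations and containers,
not performance at archive scale.

## Known limitations

* Single-process store ownership; no concurrent writers.
* No Amira/Segger/IMOD readers; no SFF shape primitives or software
  lists; no remote-archive fetching.
* Query `time` is a single integer, not a range or list.
* Desk-scale processing only: grids are materialised in memory, with no
  streaming or out-of-core path.
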
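# vsegdb

Server-side toolkit for managing and sharing large volumetric microscopy
and cryo-ET datasets together with their segmentations and biological
annotations.

Modern imaging repositories hold electron-density maps, tomograms,
multi-channel time-series images, and segmentations in many dialects
(MRC/CCP4 maps, integer label masks, EMDB-SFF HDF5, OME-Zarr/NGFF,
OME-TIFF series, RELION STAR particle tables).  Interactive web viewers
need none of that heterogeneity: they need one entry per dataset, with
every grid available at several resolutions, plus machine-readable
annotations.  `vsegdb` is the preprocessing and query side of that
pipeline:

* **Preprocessor** — converts any mix of the supported inputs into one
  database entry: canonical Å-unit grids, a downsampling pyramid per grid
  (2×2×2 block mean for intensities, majority vote with smallest-label
  tie-break for label lattices), seeded or source-derived annotations, and
  a metadata inventory.  Extra-data JSON can override a broken header voxel
  size or rename generic segment labels.
* **Internal database** — a plain directory: one subdirectory per source
  database (`emdb`, `idr`, ...), one directory per entry holding
  `data.zip` (MRC grid payloads plus JSON mesh/sphere documents),
  `annotations.json`, and `metadata.json`.
* **VS toolkit** — resolves a query document (entry, channel, time frame,
  segmentation kind/id, `max_points`) against an entry's inventory, picks
  the finest pyramid level whose voxel count fits the `max_points` budget,
  and packs exactly the selected subset into a shareable `.cvsx` ZIP
  archive (`index.json`, `query.json`, annotations, metadata, payloads).
* **Annotation editor** — pure search/edit operations over
  `annotations.json` (keyword search across keys and string values, JSON
  pointer edits, type changes, field appends) with atomic, validated
  commits.
* **Server API** — a read-only HTTP API (`/v1/...`, default
  `0.0.0.0:9000`) listing entries and serving metadata, annotations and
  grid payloads at the level chosen for a `max_points` budget.
* **Fixture generators** — deterministic synthetic inputs for every
  supported format, so the whole pipeline is testable offline.

## Worked example

Build a small entry from synthetic inputs and pack a CVSX archive:

```sh
vsegdb fixtures volume --dims 24 24 24 --out emd_1832.map
vsegdb fixtures sff --dims 24 24 24 --segment-name CMG --out emd_1832.hff
vsegdb preprocess --mode add \
    --input-path emd_1832.map --input-kind map \
    --input-path emd_1832.hff --input-kind sff \
    --entry-id emd-1832 --source-db emdb \
    --working-folder temp_working_folder --db-path test_db
# -> added emdb/emd-1832 at test_db/emdb/emd-1832

echo '{"entry_id": "emd-1832", "source_db": "emdb"}' > query.json
vsegdb vs-toolkit --db_path test_db --out emd-1832.cvsx \
    --json-params-path query.json
# -> wrote emd-1832.cvsx
```

The entry has one volume channel, one time frame and one lattice
segmentation, so the archive holds two MRC payloads
(`volume/0/0/1.map`, `lattice/lattice_0/0/1.map`) plus the four JSON
members; `query.json` inside records the resolved selection, including
the default `max_points` of 1000000000000 (i.e. "serve full
resolution").  Drop the sibling STAR workflow in the same way:

```sh
vsegdb fixtures star --n-rows 12 --out particles.star
vsegdb parse-star --star_file_path particles.star \
    --geometric_segmentation_input_file_path geom.json \
    --sphere_radius 100.0 --segmentation_id ribosomes \
    --sphere_color_hex FFFF00 --pixel_size 7.84 \
    --star_file_coordinate_divisor 4
# -> wrote geom.json (12 spheres)
```

Each particle row becomes a sphere with center
`(coordinate / 4) × 7.84 Å` — bin-1 coordinates mapped onto a bin-4
tomogram grid — radius 100 Å and color `FFFF00`.

Serve a database locally:

```sh
vsegdb serve --db-path test_db           # http://0.0.0.0:9000/v1
curl http://localhost:9000/v1/list_entries/emdb
```

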
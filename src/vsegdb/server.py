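"""Minimal read-only HTTP API over a database directory.

Routes (all GET, under the ``/v1`` prefix; defaults bind 0.0.0.0:9000 over
``preprocessor/temp/test_db``):

* ``/v1/list_entries`` and ``/v1/list_entries/{source_db}``
* ``/v1/{source_db}/{entry_id}/metadata`` — byte-equal to the stored JSON
* ``/v1/{source_db}/{entry_id}/annotations``
* ``/v1/{source_db}/{entry_id}/volume/{channel_id}/{time}?max_points=N``
* ``/v1/{source_db}/{entry_id}/segmentation/lattice/{segmentation_id}/{time}?max_points=N``
* ``/v1/{source_db}/{entry_id}/segmentation/geometric/{segmentation_id}``
* ``/v1/{source_db}/{entry_id}/segmentation/mesh/{segmentation_id}``
* ``/docs`` — machine-readable description of the routes above

Grid payloads are served as MRC bodies at the downsampling level selected
for the requested ``max_points`` budget.  Every response is a pure function
of the store; the server holds no mutable state.
"""

from __future__ import annotations

import json
import threading
from dataclasses import asdict
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Optional, Union
from urllib.parse import parse_qs, unquote, urlparse

from . import store
from .cvsx import _levels_from_doc, select_sampling_level
from .errors import NotFoundError
from .models import DEFAULT_MAX_POINTS, EntryKey, ServerSettings

_API_DOCS = {
    "title": "volumetric/segmentation entry database API",
    "version": "v1",
    "routes": [
        {"path": "/v1/list_entries", "method": "GET",
         "description": "all entry keys in the database"},
        {"path": "/v1/list_entries/{source_db}", "method": "GET",
         "description": "entry keys for one source database"},
        {"path": "/v1/{source_db}/{entry_id}/metadata", "method": "GET",
         "description": "stored metadata.json"},
        {"path": "/v1/{source_db}/{entry_id}/annotations", "method": "GET",
         "description": "stored annotations.json"},
        {"path": "/v1/{source_db}/{entry_id}/volume/{channel_id}/{time}",
         "method": "GET", "query": {"max_points": "int, optional"},
         "description": "MRC volume grid at the selected downsampling level"},
        {"path": "/v1/{source_db}/{entry_id}/segmentation/lattice/"
                 "{segmentation_id}/{time}",
         "method": "GET", "query": {"max_points": "int, optional"},
         "description": "MRC label grid at the selected downsampling level"},
        {"path": "/v1/{source_db}/{entry_id}/segmentation/geometric/"
                 "{segmentation_id}", "method": "GET",
         "description": "geometric segmentation JSON"},
        {"path": "/v1/{source_db}/{entry_id}/segmentation/mesh/"
                 "{segmentation_id}", "method": "GET",
         "description": "mesh segmentation JSON"},
    ],
}


class _Handler(BaseHTTPRequestHandler):
    server_version = "vsegdb/2.0"

    def log_message(self, fmt, *args):  # quiet by default
        pass

    # -- helpers -------------------------------------------------------
    def _send(self, status: int, body: bytes,
              content_type: str = "application/json") -> None:
        self.send_response(status)
        self.send_header("Content-Type", content_type)
        self.send_header("Content-Length", str(len(body)))
        self.send_header("Access-Control-Allow-Origin", "*")
        self.end_headers()
        self.wfile.write(body)

    def _json(self, status: int, obj) -> None:
        self._send(status, (json.dumps(obj, indent=2, sort_keys=True) + "\n")
                   .encode())

    def _not_found(self, message: str) -> None:
        self._json(404, {"error": message})

    # -- routing -------------------------------------------------------
    def do_GET(self) -> None:  # noqa: N802  (stdlib handler naming)
        try:
            self._route()
        except NotFoundError as exc:
            self._not_found(str(exc))
        except Exception as exc:  # pragma: no cover - defensive
            self._json(500, {"error": str(exc)})

    def _route(self) -> None:
        url = urlparse(self.path)
        parts = [unquote(p) for p in url.path.split("/") if p]
        qs = parse_qs(url.query)
        db = self.server.db_path  # type: ignore[attr-defined]

        if parts == ["docs"]:
            return self._json(200, _API_DOCS)
        if not parts or parts[0] != "v1":
            return self._not_found(f"unknown route {url.path!r}")
        parts = parts[1:]

        if parts and parts[0] == "list_entries":
            source = parts[1] if len(parts) > 1 else None
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                keys = store.list_entries(db, source)
            return self._json(200, [asdict(k) for k in keys])

        if len(parts) >= 3:
            key = EntryKey(source_db=parts[0], entry_id=parts[1])
            rest = parts[2:]
            if rest == ["metadata"]:
                path = store.entry_dir(db, key) / "metadata.json"
                if not path.exists():
                    raise NotFoundError(f"entry {key.entry_id} not found")
                return self._send(200, path.read_bytes())
            if rest == ["annotations"]:
                path = store.entry_dir(db, key) / "annotations.json"
                if not path.exists():
                    raise NotFoundError(f"entry {key.entry_id} not found")
                return self._send(200, path.read_bytes())
            max_points = int(qs.get("max_points", [DEFAULT_MAX_POINTS])[0])
            if rest[0] == "volume" and len(rest) == 3:
                meta = store.read_metadata(db, key)
                factor = select_sampling_level(meta.volume_levels(), max_points)
                member = store.volume_member(rest[1], int(rest[2]), factor)
                body = store.read_payload(db, key, member)
                return self._send(200, body, "application/octet-stream")
            if rest[0] == "segmentation" and len(rest) >= 3:
                seg_kind, sid = rest[1], rest[2]
                if seg_kind == "lattice" and len(rest) == 4:
                    meta = store.read_metadata(db, key)
                    rec = next((r for r in meta.lattice_inventory()
                                if r["segmentation_id"] == sid), None)
                    if rec is None:
                        raise NotFoundError(f"lattice {sid!r} not found")
                    factor = select_sampling_level(
                        _levels_from_doc(rec["sampling_levels"]), max_points)
                    member = store.lattice_member(sid, int(rest[3]), factor)
                    return self._send(200, store.read_payload(db, key, member),
                                      "application/octet-stream")
                if seg_kind == "geometric" and len(rest) == 3:
                    return self._send(
                        200, store.read_payload(db, key,
                                                store.geometric_member(sid)))
                if seg_kind == "mesh" and len(rest) == 3:
                    return self._send(
                        200, store.read_payload(db, key,
                                                store.mesh_member(sid)))
        self._not_found(f"unknown route {url.path!r}")


class EntryServer(ThreadingHTTPServer):
    """HTTP server bound to the configured host/port over one database."""

    daemon_threads = True

    def __init__(self, settings: Optional[ServerSettings] = None):
        self.settings = settings or ServerSettings()
        self.db_path = Path(self.settings.db_path)
        super().__init__((self.settings.host, self.settings.port), _Handler)

    @property
    def bound_port(self) -> int:
        return self.server_address[1]

    def serve_background(self) -> threading.Thread:
        thread = threading.Thread(target=self.serve_forever, daemon=True)
        thread.start()
        return thread


def serve(settings: Optional[ServerSettings] = None) -> None:
    """Blocking entry point used by the CLI."""
    server = EntryServer(settings)
    try:
        server.serve_forever()
    finally:
        server.server_close()
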
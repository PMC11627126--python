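"""Search and structured editing of an entry's annotations document.

All operations are pure: they take a parsed JSON document, return a new
one, and never mutate their input.  Locations are RFC 6901 JSON pointers
(``/descriptions/desc-x-1/name``).  Search matches nodes whose key or
string value contains *all* whitespace-separated keywords,
case-insensitively; numbers and booleans are not searched.
"""

from __future__ import annotations

import copy
import json
import os
import tempfile
from pathlib import Path
from typing import Any, Union

from .errors import ConflictError, NotFoundError, ValidationFailure
from .models import EntryKey, validate_annotations

_EMPTY = {"string": "", "object": {}, "list": [], "number": 0,
          "boolean": False, "null": None}


def escape_token(token: str) -> str:
    return token.replace("~", "~0").replace("/", "~1")


def _unescape(token: str) -> str:
    return token.replace("~1", "/").replace("~0", "~")


def _tokens(pointer: str) -> list[str]:
    if pointer == "":
        return []
    if not pointer.startswith("/"):
        raise NotFoundError(f"bad JSON pointer {pointer!r} (must start with '/')")
    return [_unescape(t) for t in pointer.split("/")[1:]]


def _resolve_parent(doc: Any, pointer: str) -> tuple[Any, Union[str, int]]:
    tokens = _tokens(pointer)
    if not tokens:
        raise NotFoundError("cannot edit the document root")
    node = doc
    for tok in tokens[:-1]:
        node = _step(node, tok, pointer)
    last = tokens[-1]
    # validate the leaf exists (for edit/retype)
    return node, last


def _step(node: Any, token: str, pointer: str) -> Any:
    if isinstance(node, dict):
        if token not in node:
            raise NotFoundError(f"pointer {pointer!r}: key {token!r} not found")
        return node[token]
    if isinstance(node, list):
        try:
            idx = int(token)
            return node[idx]
        except (ValueError, IndexError):
            raise NotFoundError(
                f"pointer {pointer!r}: bad list index {token!r}") from None
    raise NotFoundError(f"pointer {pointer!r}: cannot descend into a leaf")


def resolve_pointer(doc: Any, pointer: str) -> Any:
    node = doc
    for tok in _tokens(pointer):
        node = _step(node, tok, pointer)
    return node


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def search_annotations(doc: Any, query: str) -> list[str]:
    """Pointers to every node matching all keywords, sorted by path."""
    keywords = [k.lower() for k in query.split()]
    if not keywords:
        return []
    hits: list[str] = []

    def matches(text: str) -> bool:
        low = text.lower()
        return all(k in low for k in keywords)

    def walk(node: Any, pointer: str) -> None:
        if isinstance(node, dict):
            for key, val in node.items():
                child = pointer + "/" + escape_token(str(key))
                if matches(str(key)):
                    hits.append(child)
                walk(val, child)
        elif isinstance(node, list):
            for i, val in enumerate(node):
                walk(val, f"{pointer}/{i}")
        elif isinstance(node, str):
            if matches(node):
                hits.append(pointer)

    walk(doc, "")
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------


def _set(doc: Any, pointer: str, value: Any, must_exist: bool = True) -> Any:
    new = copy.deepcopy(doc)
    parent, last = _resolve_parent(new, pointer)
    if isinstance(parent, dict):
        if must_exist and last not in parent:
            raise NotFoundError(f"pointer {pointer!r}: key {last!r} not found")
        parent[last] = value
    elif isinstance(parent, list):
        try:
            parent[int(last)] = value
        except (ValueError, IndexError):
            raise NotFoundError(
                f"pointer {pointer!r}: bad list index {last!r}") from None
    else:
        raise NotFoundError(f"pointer {pointer!r}: parent is a leaf")
    return new


def edit_at_pointer(doc: Any, pointer: str, value: Any,
                    validate: bool = True) -> Any:
    """Replace the value at ``pointer``; the rest of the document is untouched.

    When ``validate`` is set (the default for annotations documents) the
    result must still satisfy the annotations model, otherwise the edit is
    rejected with the violations.
    """
    resolve_pointer(doc, pointer)  # not-found check before any work
    new = _set(doc, pointer, value)
    if validate:
        violations = validate_annotations(new)
        if violations:
            raise ValidationFailure(violations)
    return new


def retype_at_pointer(doc: Any, pointer: str, kind: str) -> Any:
    """Replace the node with the empty value of ``kind`` (object → {} ...)."""
    if kind not in _EMPTY:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_EMPTY)}")
    resolve_pointer(doc, pointer)
    return _set(doc, pointer, copy.deepcopy(_EMPTY[kind]))


def append_field(doc: Any, pointer: str, key: str, value: Any) -> Any:
    """Add ``key`` to the object at ``pointer``; existing keys conflict."""
    target = resolve_pointer(doc, pointer)
    if not isinstance(target, dict):
        raise NotFoundError(f"pointer {pointer!r} does not resolve to an object")
    if key in target:
        raise ConflictError(f"key {key!r} already exists at {pointer!r}")
    new = copy.deepcopy(doc)
    resolve_pointer(new, pointer)[key] = value
    return new


# ---------------------------------------------------------------------------
# commit
# ---------------------------------------------------------------------------


def commit_annotations(db_path: Union[str, Path], key: EntryKey,
                       doc: Any, validate: bool = True) -> Path:
    """Atomically replace annotations.json for one entry.

    The document is validated first; on failure nothing is written.  The
    replacement is write-temp-then-rename, so a concurrent reader sees the
    old or the new file, never a partial one.  ``validate=False`` stores a
    draft mid-edit state (e.g. a retyped-but-not-yet-filled details object)
    that a later commit is expected to repair.
    """
    if validate:
        violations = validate_annotations(doc)
        if violations:
            raise ValidationFailure(violations)
    from .store import entry_dir

    target = entry_dir(db_path, key) / "annotations.json"
    if not target.parent.exists():
        raise NotFoundError(f"entry {key.source_db}/{key.entry_id} not found")
    text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    fd, tmp = tempfile.mkstemp(dir=target.parent, prefix=".annotations-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, target)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return target
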
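"""Portable, self-describing archives for whole libraries.

A saved library is a single ZIP file with a ``manifest.json`` at the root
and one payload file per record.  The manifest records, per entry, the
record's name, role, type labels, metadata, the codec used and a SHA-256
checksum of the payload bytes, plus library-level description/info and
version stamps (format version, tool version, platform note), so an
archive remains auditable long after the session that produced it.

Three codecs cover the payload space:

``tabular-csv``
    DataFrames, written as UTF-8 CSV with a JSON sidecar of column types
    (including categorical level order) so values and dtypes round-trip
    exactly; floats are written in shortest-representation text.
``structured-text``
    JSON-representable structures (mappings, sequences, scalars) plus
    registered record types such as :class:`~ammlib.core.OpaquePayload`,
    written as tagged JSON.  Fully portable.
``native-blob``
    Anything else, pickled.  Flagged non-portable in the manifest; on a
    platform that cannot unpickle it, loading surfaces the raw bytes with
    a warning instead of failing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import os
import pickle
import platform
import sys
import tempfile
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd

from .core import AmLibrary, AmRecord, MetadataMap, OpaquePayload, ROLES

try:
    from importlib.metadata import version as _dist_version

    _tool_version = _dist_version("ammlib")
except Exception:  # pragma: no cover - distribution metadata unavailable
    _tool_version = "0+unknown"

__all__ = [
    "ArchiveError",
    "NotAnArchiveError",
    "IntegrityError",
    "VersionError",
    "SerializationError",
    "ArchiveManifest",
    "ManifestEntry",
    "save_library",
    "load_library",
    "register_structured_type",
]

FORMAT_VERSION = "1.0"
_SUPPORTED_VERSIONS = {"1.0"}
MANIFEST_NAME = "manifest.json"
CODECS = ("tabular-csv", "structured-text", "native-blob")


class ArchiveError(Exception):
    """Base class for archive I/O failures."""


class NotAnArchiveError(ArchiveError):
    """The file is not a library archive (no manifest)."""


class IntegrityError(ArchiveError):
    """A payload's bytes do not match the checksum in the manifest."""


class VersionError(ArchiveError):
    """The archive declares an unsupported format version."""


class SerializationError(ArchiveError):
    """A payload could not be serialized by any codec."""


# -- structured-text codec registry ------------------------------------------

_TAG = "__ammlib_type__"
_registry: dict[str, tuple[type, Callable[[Any], dict], Callable[[dict], Any]]] = {}


def register_structured_type(name: str, cls: type,
                             encode: Callable[[Any], dict],
                             decode: Callable[[dict], Any]) -> None:
    """Register a type for lossless tagged-JSON serialization."""
    _registry[name] = (cls, encode, decode)


register_structured_type(
    "OpaquePayload", OpaquePayload,
    lambda p: {"class_label": p.class_label,
               "origin_package": p.origin_package,
               "content": _to_jsonable(dict(p.content))},
    lambda d: OpaquePayload(d["class_label"], d["origin_package"],
                            tuple(d["content"].items())),
)


def _to_jsonable(obj: Any) -> Any:
    """Recursively encode *obj* into tagged JSON-compatible structures.

    Raises TypeError when an object has no lossless text representation,
    which routes the payload to the native-blob codec instead.
    """
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        encoded = [_to_jsonable(v) for v in obj]
        if isinstance(obj, tuple):
            return {_TAG: "tuple", "items": encoded}
        return encoded
    if isinstance(obj, dict):
        if not all(isinstance(k, str) for k in obj):
            raise TypeError("only string-keyed mappings are text-representable")
        if _TAG in obj:
            raise TypeError("mapping collides with the codec tag")
        return {k: _to_jsonable(v) for k, v in obj.items()}
    for name, (cls, encode, _) in _registry.items():
        if isinstance(obj, cls):
            return {_TAG: name, "value": encode(obj)}
    raise TypeError(f"{type(obj).__name__} is not text-representable")


def _from_jsonable(obj: Any) -> Any:
    if isinstance(obj, list):
        return [_from_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        tag = obj.get(_TAG)
        if tag == "tuple":
            return tuple(_from_jsonable(v) for v in obj["items"])
        if tag is not None:
            if tag not in _registry:
                raise SerializationError(f"unknown structured type tag {tag!r}")
            _, _, decode = _registry[tag]
            return decode(_from_jsonable(obj["value"]))
        return {k: _from_jsonable(v) for k, v in obj.items()}
    return obj


# -- tabular codec -----------------------------------------------------------


def _frame_to_csv(frame: pd.DataFrame) -> tuple[bytes, bytes]:
    """CSV bytes plus a JSON sidecar describing column types."""
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    columns = []
    for name in frame.columns:
        col = frame[name]
        spec: dict[str, Any] = {"name": str(name), "dtype": str(col.dtype)}
        if isinstance(col.dtype, pd.CategoricalDtype):
            spec["dtype"] = "category"
            spec["categories"] = [str(c) for c in col.cat.categories]
        columns.append(spec)
    sidecar = json.dumps({"columns": columns}, indent=1).encode("utf-8")
    return buf.getvalue().encode("utf-8"), sidecar


def _frame_from_csv(data: bytes, sidecar: bytes) -> pd.DataFrame:
    spec = json.loads(sidecar.decode("utf-8"))
    names = [c["name"] for c in spec["columns"]]
    frame = pd.read_csv(io.BytesIO(data), dtype=str,
                        keep_default_na=False, na_values=[""])
    frame = frame[names] if list(frame.columns) != names else frame
    for col in spec["columns"]:
        name, dtype = col["name"], col["dtype"]
        if dtype == "category":
            frame[name] = pd.Categorical(frame[name],
                                         categories=col.get("categories"))
        elif dtype == "object":
            pass
        else:
            frame[name] = frame[name].astype(dtype)
    return frame


# -- manifest ----------------------------------------------------------------


@dataclass
class ManifestEntry:
    name: str
    role: str
    payload_class: str
    origin_package: str | None
    codec: str
    payload_path: str
    checksum: str
    metadata: dict[str, str]
    sidecar_path: str | None = None
    sidecar_checksum: str | None = None
    portable: bool = True


@dataclass
class ArchiveManifest:
    """Self-describing index of a saved library."""

    format_version: str
    created: str
    tool_version: str
    platform_note: str
    description: str
    info: dict[str, str]
    entries: list[ManifestEntry] = field(default_factory=list)

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=1, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "ArchiveManifest":
        raw = json.loads(text)
        entries = [ManifestEntry(**e) for e in raw.pop("entries", [])]
        return cls(entries=entries, **raw)


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _encode_payload(name: str, record: AmRecord) -> tuple[str, bytes, bytes | None, bool]:
    """(codec, payload bytes, sidecar bytes or None, portable flag)."""
    payload = record.payload
    if isinstance(payload, pd.DataFrame):
        data, sidecar = _frame_to_csv(payload)
        return "tabular-csv", data, sidecar, True
    try:
        encoded = _to_jsonable(payload)
    except TypeError:
        pass
    else:
        data = json.dumps(encoded, indent=1, ensure_ascii=False).encode("utf-8")
        return "structured-text", data, None, True
    try:
        return "native-blob", pickle.dumps(payload), None, False
    except Exception as exc:
        raise SerializationError(
            f"record {name!r} could not be serialized by any codec: {exc}"
        ) from exc


def _decode_payload(entry: ManifestEntry, data: bytes,
                    sidecar: bytes | None) -> Any:
    if entry.codec == "tabular-csv":
        if sidecar is None:
            raise IntegrityError(
                f"entry {entry.name!r}: tabular payload missing its type sidecar")
        return _frame_from_csv(data, sidecar)
    if entry.codec == "structured-text":
        return _from_jsonable(json.loads(data.decode("utf-8")))
    if entry.codec == "native-blob":
        try:
            return pickle.loads(data)
        except Exception:
            warnings.warn(
                f"entry {entry.name!r}: native-blob payload could not be "
                f"restored on this platform; surfacing raw bytes",
                stacklevel=3)
            return data
    raise VersionError(f"entry {entry.name!r}: unknown codec {entry.codec!r}")


# -- save / load -------------------------------------------------------------


def save_library(library: AmLibrary, path: str | os.PathLike) -> ArchiveManifest:
    """Write *library* to a single-file archive at *path*, atomically.

    Returns the manifest that was embedded in the archive.  The archive is
    first written to a temporary file in the destination directory and
    moved into place, so a failed save never leaves a half-written file.
    """
    import datetime as _dt

    entries: list[ManifestEntry] = []
    blobs: list[tuple[str, bytes]] = []
    for role in ROLES:
        for name, record in library.collection(role).items():
            codec, data, sidecar, portable = _encode_payload(name, record)
            ext = {"tabular-csv": "csv", "structured-text": "json",
                   "native-blob": "pkl"}[codec]
            payload_path = f"payloads/{role}_{name}.{ext}"
            sidecar_path = None
            sidecar_sum = None
            blobs.append((payload_path, data))
            if sidecar is not None:
                sidecar_path = payload_path + "-types.json"
                sidecar_sum = _sha256(sidecar)
                blobs.append((sidecar_path, sidecar))
            entries.append(ManifestEntry(
                name=name, role=role,
                payload_class=record.payload_class,
                origin_package=record.origin_package,
                codec=codec, payload_path=payload_path,
                checksum=_sha256(data),
                metadata=record.metadata.to_dict(),
                sidecar_path=sidecar_path,
                sidecar_checksum=sidecar_sum,
                portable=portable,
            ))
    manifest = ArchiveManifest(
        format_version=FORMAT_VERSION,
        created=_dt.datetime.now().isoformat(timespec="seconds"),
        tool_version=_tool_version,
        platform_note=(f"python {platform.python_version()} "
                       f"({platform.python_implementation()}, {sys.platform})"),
        description=library.description,
        info=library.info.to_dict(),
        entries=entries,
    )
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".amml.part")
    try:
        with os.fdopen(fd, "wb") as handle:
            with zipfile.ZipFile(handle, "w", zipfile.ZIP_DEFLATED) as zf:
                zf.writestr(MANIFEST_NAME, manifest.to_json())
                for blob_path, blob in blobs:
                    zf.writestr(blob_path, blob)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return manifest


def read_manifest(path: str | os.PathLike) -> ArchiveManifest:
    """Read and parse the manifest of an archive without loading payloads."""
    try:
        zf = zipfile.ZipFile(os.fspath(path))
    except (zipfile.BadZipFile, FileNotFoundError, IsADirectoryError) as exc:
        raise NotAnArchiveError(f"{path}: not a library archive: {exc}") from exc
    with zf:
        if MANIFEST_NAME not in zf.namelist():
            raise NotAnArchiveError(f"{path}: no {MANIFEST_NAME} at archive root")
        manifest = ArchiveManifest.from_json(zf.read(MANIFEST_NAME).decode("utf-8"))
    if manifest.format_version not in _SUPPORTED_VERSIONS:
        raise VersionError(
            f"{path}: unsupported format version {manifest.format_version!r} "
            f"(supported: {sorted(_SUPPORTED_VERSIONS)})")
    return manifest


def load_library(path: str | os.PathLike) -> AmLibrary:
    """Reconstruct a library from an archive written by :func:`save_library`.

    Every payload's checksum is verified against the manifest before
    decoding; record order follows the manifest.
    """
    manifest = read_manifest(path)
    library = AmLibrary(manifest.description)
    library.info = MetadataMap(manifest.info)
    with zipfile.ZipFile(os.fspath(path)) as zf:
        names = set(zf.namelist())
        for entry in manifest.entries:
            if entry.payload_path not in names:
                raise IntegrityError(
                    f"entry {entry.name!r}: payload {entry.payload_path!r} "
                    f"missing from archive")
            data = zf.read(entry.payload_path)
            if _sha256(data) != entry.checksum:
                raise IntegrityError(
                    f"entry {entry.name!r}: checksum mismatch for "
                    f"{entry.payload_path!r}")
            sidecar = None
            if entry.sidecar_path is not None:
                if entry.sidecar_path not in names:
                    raise IntegrityError(
                        f"entry {entry.name!r}: sidecar "
                        f"{entry.sidecar_path!r} missing from archive")
                sidecar = zf.read(entry.sidecar_path)
                if (entry.sidecar_checksum is not None
                        and _sha256(sidecar) != entry.sidecar_checksum):
                    raise IntegrityError(
                        f"entry {entry.name!r}: checksum mismatch for "
                        f"{entry.sidecar_path!r}")
            payload = _decode_payload(entry, data, sidecar)
            record = AmRecord(
                role=entry.role, payload=payload,
                payload_class=entry.payload_class,
                origin_package=entry.origin_package,
                metadata=MetadataMap(entry.metadata),
            )
            if entry.role == "model":
                library.insert(models={entry.name: record})
            else:
                library.insert(data={entry.name: record})
    return library
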
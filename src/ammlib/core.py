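"""Core container types for a model/data/metadata library.

An :class:`AmLibrary` is a single portable object that stores analysis
inputs ("data" records), analysis outputs ("model" records), and free-form
key-value metadata about each, so that the state of knowledge produced by
an analysis can be archived, searched, and revisited later.  The design
mirrors the bookkeeping needs of adaptive management, where models of a
managed system are updated as monitoring data accumulate and every
generation of model must remain retrievable alongside the data that
produced it.

Records are opaque: the library never inspects or validates a payload
beyond detecting its type label, its row/column counts when tabular, and
an optional self-declared producing tool.  Relationships between records
are expressed purely through reserved metadata keys ("data" names the
input dataset of a model, "prior" names the model used as a prior) and are
deliberately not checked for referential integrity -- a link may name a
record that lives in another library, or nowhere yet.
"""

from __future__ import annotations

import copy
import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "AmLibraryError",
    "DuplicateKeyError",
    "DuplicateNameError",
    "NotFoundError",
    "InvalidSelectorError",
    "MetadataMap",
    "AmRecord",
    "AmLibrary",
    "LibrarySummary",
    "OpaquePayload",
    "sanitize_name",
    "create_library",
    "describe",
    "edit_info",
    "make_record",
    "insert_records",
    "remove_record",
    "list_names",
    "get_record",
    "record_meta",
    "summarize",
    "payloads_equal",
]

# -- module configuration ----------------------------------------------------

#: Default character width at which summary listings truncate metadata values.
DEFAULT_TRUNCATION_WIDTH = 60

#: Timestamp format used for the automatic creation-date metadata.
TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"

#: Reserved metadata key carrying a record's creation timestamp.
RECORD_DATE_KEY = "date"

#: Reserved info key carrying a library's creation timestamp.
LIBRARY_DATE_KEY = "date.created"

#: Reserved metadata key linking a model to its input dataset (by name).
DATA_LINK_KEY = "data"

#: Reserved metadata key linking a posterior model to its prior (by name).
PRIOR_LINK_KEY = "prior"

ROLES = ("model", "data")


def _now() -> str:
    return _dt.datetime.now().strftime(TIMESTAMP_FORMAT)


# -- errors ------------------------------------------------------------------


class AmLibraryError(Exception):
    """Base class for library bookkeeping errors."""


class DuplicateKeyError(AmLibraryError, ValueError):
    """A metadata mapping was given the same key twice."""


class DuplicateNameError(AmLibraryError, ValueError):
    """A record name is already present in the target collection."""


class NotFoundError(AmLibraryError, KeyError):
    """A name or index did not resolve to a stored record or metadata key."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message flat
        return self.args[0] if self.args else ""


class InvalidSelectorError(AmLibraryError, ValueError):
    """A selector is malformed (e.g. index 0 or negative in a 1-based API)."""


# -- names and metadata ------------------------------------------------------

_INVALID_NAME_CHARS = re.compile(r"[^A-Za-z0-9._]")


def sanitize_name(name: str) -> str:
    """Coerce *name* to a valid record identifier.

    Invalid characters are replaced with ``.`` and a name that starts with
    a digit (or a dot followed by a digit, or is empty) is prefixed with
    ``X``, in the style of R's ``make.names``.
    """
    name = _INVALID_NAME_CHARS.sub(".", str(name))
    if not name or name[0].isdigit() or re.match(r"^\.\d", name):
        name = "X" + name
    return name


class MetadataMap:
    """Ordered key -> text mapping with null-sentinel deletion.

    Keys are unique non-empty strings; values are stored as text (non-text
    inputs are rendered with ``str``).  Updating a key with ``None``
    deletes it.  Reserved keys ("data", "prior", "date", "date.created")
    are stored verbatim like any other key -- no referential validation.
    """

    def __init__(self, entries: Mapping[str, Any] | Iterable[tuple[str, Any]] | None = None):
        self._entries: dict[str, str] = {}
        if entries is not None:
            items = entries.items() if isinstance(entries, Mapping) else list(entries)
            seen: set[str] = set()
            for key, value in items:
                if key in seen:
                    raise DuplicateKeyError(f"duplicate metadata key: {key!r}")
                seen.add(key)
                self.set(key, value)

    def set(self, key: str, value: Any) -> None:
        if not isinstance(key, str) or not key:
            raise DuplicateKeyError(f"metadata keys must be non-empty text, got {key!r}")
        if value is None:
            self._entries.pop(key, None)
        else:
            self._entries[key] = str(value)

    def update(self, updates: Mapping[str, Any]) -> None:
        for key, value in updates.items():
            self.set(key, value)

    def get(self, key: str, default: str | None = None) -> str | None:
        return self._entries.get(key, default)

    def __getitem__(self, key: str) -> str:
        try:
            return self._entries[key]
        except KeyError:
            raise NotFoundError(f"metadata key not found: {key!r}") from None

    def __contains__(self, key: object) -> bool:
        return key in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def keys(self):
        return self._entries.keys()

    def values(self):
        return self._entries.values()

    def items(self):
        return self._entries.items()

    def to_dict(self) -> dict[str, str]:
        return dict(self._entries)

    def copy(self) -> "MetadataMap":
        return MetadataMap(self._entries)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MetadataMap):
            return self._entries == other._entries
        if isinstance(other, Mapping):
            return self._entries == dict(other)
        return NotImplemented

    def __repr__(self) -> str:
        return f"MetadataMap({self._entries!r})"


# -- payloads ----------------------------------------------------------------


@dataclass(frozen=True)
class OpaquePayload:
    """A stand-in payload for an object produced by an external tool.

    Used when the real object (e.g. a fitted occupancy model from another
    statistical environment) cannot or need not be materialised: the label
    and origin are preserved for the library's bookkeeping while the
    content is an arbitrary mapping.
    """

    class_label: str
    origin_package: str | None = None
    content: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def build(cls, class_label: str, origin_package: str | None = None,
              **content: Any) -> "OpaquePayload":
        return cls(class_label, origin_package, tuple(content.items()))

    def as_dict(self) -> dict[str, Any]:
        return dict(self.content)


def _detect_payload_class(payload: Any) -> str:
    label = getattr(payload, "class_label", None)
    if isinstance(label, str) and label:
        return label
    return type(payload).__name__


def _detect_origin(payload: Any) -> str | None:
    origin = getattr(payload, "origin_package", None)
    if isinstance(origin, str) and origin:
        return origin
    return None


def _tabular_shape(payload: Any) -> tuple[int, int] | None:
    if isinstance(payload, pd.DataFrame):
        return payload.shape
    return None


def payloads_equal(a: Any, b: Any) -> bool:
    """Deep equality that understands tabular payloads."""
    if isinstance(a, pd.DataFrame) or isinstance(b, pd.DataFrame):
        if not (isinstance(a, pd.DataFrame) and isinstance(b, pd.DataFrame)):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False,
                                          check_categorical=False)
        except AssertionError:
            return False
        return True
    return bool(a == b)


# -- records -----------------------------------------------------------------


@dataclass
class AmRecord:
    """One stored item: an opaque payload plus its descriptive metadata.

    ``role`` is ``"model"`` for analysis outputs and ``"data"`` for
    analysis inputs.  ``payload_class`` labels the payload's original
    type; ``origin_package`` names the producing tool when the payload
    self-declares one (otherwise ``None``, displayed as NA).  Metadata
    always contains a creation timestamp after construction.
    """

    role: str
    payload: Any
    payload_class: str
    origin_package: str | None
    metadata: MetadataMap

    def shape(self) -> tuple[int, int] | None:
        """(nrows, ncols) for tabular payloads, else None."""
        return _tabular_shape(self.payload)

    def copy(self) -> "AmRecord":
        return AmRecord(self.role, copy.deepcopy(self.payload),
                        self.payload_class, self.origin_package,
                        self.metadata.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmRecord):
            return NotImplemented
        return (self.role == other.role
                and self.payload_class == other.payload_class
                and self.origin_package == other.origin_package
                and self.metadata == other.metadata
                and payloads_equal(self.payload, other.payload))


def make_record(role: str, payload: Any,
                metadata: Mapping[str, Any] | MetadataMap | None = None,
                *, payload_class: str | None = None,
                origin_package: str | None = None) -> AmRecord:
    """Wrap *payload* into an :class:`AmRecord` with metadata.

    The payload is deep-copied so later edits to the caller's object never
    mutate the stored record.  A creation timestamp is added under the
    reserved key ``"date"`` unless the caller supplied one (a user value
    for the reserved key wins over the automatic value).
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}, got {role!r}")
    meta = metadata.copy() if isinstance(metadata, MetadataMap) else MetadataMap(metadata)
    if RECORD_DATE_KEY not in meta:
        meta.set(RECORD_DATE_KEY, _now())
    return AmRecord(
        role=role,
        payload=copy.deepcopy(payload),
        payload_class=payload_class or _detect_payload_class(payload),
        origin_package=origin_package or _detect_origin(payload),
        metadata=meta,
    )


# -- the library -------------------------------------------------------------


class AmLibrary:
    """A four-part container: description, info, model records, data records.

    Record names are unique within each of the two collections, insertion
    order is preserved, and positional indices in the public interface are
    1-based (they shift after removals, which is why links between records
    use names, never indices).
    """

    def __init__(self, description: str = "",
                 info: Mapping[str, Any] | MetadataMap | None = None):
        self.description = str(description)
        self.info = info.copy() if isinstance(info, MetadataMap) else MetadataMap(info)
        if LIBRARY_DATE_KEY not in self.info:
            self.info.set(LIBRARY_DATE_KEY, _now())
        self._records: dict[str, dict[str, AmRecord]] = {"model": {}, "data": {}}

    # collection views -------------------------------------------------

    @property
    def models(self) -> dict[str, AmRecord]:
        return self._records["model"]

    @property
    def data(self) -> dict[str, AmRecord]:
        return self._records["data"]

    def collection(self, role: str) -> dict[str, AmRecord]:
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        return self._records[role]

    # record operations ------------------------------------------------

    def insert(self, models: Mapping[str, AmRecord] | None = None,
               data: Mapping[str, AmRecord] | None = None) -> "AmLibrary":
        """Append named records to the end of the matching collections.

        Records must be named; names are sanitized to valid identifiers.
        A name already present in the target collection is rejected rather
        than silently overwritten -- overwriting would destroy provenance.
        """
        for role, batch in (("model", models), ("data", data)):
            if not batch:
                continue
            staged: dict[str, AmRecord] = {}
            for name, record in batch.items():
                if not name:
                    raise InvalidSelectorError(
                        f"every inserted {role} record must have a name")
                if not isinstance(record, AmRecord):
                    raise TypeError(
                        f"records must be AmRecord instances; wrap payloads "
                        f"with make_record (got {type(record).__name__})")
                clean = sanitize_name(name)
                if clean in self._records[role] or clean in staged:
                    raise DuplicateNameError(
                        f"a {role} record named {clean!r} already exists")
                if record.role != role:
                    raise ValueError(
                        f"record {clean!r} has role {record.role!r}, "
                        f"cannot insert into the {role} collection")
                staged[clean] = record
            self._records[role].update(staged)
        return self

    def _resolve(self, role: str, selector: str | int) -> str:
        names = list(self.collection(role))
        if isinstance(selector, bool):
            raise InvalidSelectorError(f"invalid {role} selector: {selector!r}")
        if isinstance(selector, int):
            if selector < 1:
                raise InvalidSelectorError(
                    f"indices are 1-based; got {selector}")
            if selector > len(names):
                raise NotFoundError(
                    f"{role} index {selector} out of range (1..{len(names)})")
            return names[selector - 1]
        if selector not in self._records[role]:
            raise NotFoundError(f"no {role} record named {selector!r}")
        return selector

    def remove(self, role: str, selector: str | int) -> "AmLibrary":
        """Remove one record; subsequent positional indices shift down."""
        name = self._resolve(role, selector)
        del self._records[role][name]
        return self

    def names(self, role: str) -> list[str]:
        return list(self.collection(role))

    def get(self, role: str, selector: str | int,
            with_metadata: bool = False) -> Any:
        """Check out a record's payload (the library is left unchanged).

        With ``with_metadata=True`` a two-part ``{"data": payload,
        "metadata": MetadataMap}`` result is returned.
        """
        record = self._records[role][self._resolve(role, selector)]
        payload = copy.deepcopy(record.payload)
        if with_metadata:
            return {"data": payload, "metadata": record.metadata.copy()}
        return payload

    def record(self, role: str, selector: str | int) -> AmRecord:
        """The stored record itself (internal bookkeeping access)."""
        return self._records[role][self._resolve(role, selector)]

    def meta(self, role: str, name: str | int | None = None,
             updates: Mapping[str, Any] | None = None):
        """View or edit record metadata.

        Without a name, returns ``{record name: MetadataMap}`` for the
        whole collection.  With a name, returns that record's metadata;
        *updates* (upserts, with ``None`` deleting a key) require a name.
        """
        if name is None:
            if updates is not None:
                raise InvalidSelectorError(
                    "metadata updates require a record name")
            return {n: r.metadata.copy() for n, r in self.collection(role).items()}
        record = self._records[role][self._resolve(role, name)]
        if updates is not None:
            record.metadata.update(updates)
        return record.metadata.copy()

    # info / description ----------------------------------------------

    def set_description(self, text: str) -> str:
        self.description = str(text)
        return self.description

    def edit_info(self, updates: Mapping[str, Any] | None = None,
                  select_key: str | None = None) -> MetadataMap:
        """View or edit library-level info.

        ``select_key`` narrows the view to one entry; *updates* upserts
        pairs, deleting keys whose value is ``None``.  Returns the
        resulting info (or the selected entry as a one-key map).
        """
        if updates is not None:
            self.info.update(updates)
        if select_key is not None:
            if select_key not in self.info:
                raise NotFoundError(f"info key not found: {select_key!r}")
            return MetadataMap({select_key: self.info[select_key]})
        return self.info.copy()

    # comparisons ------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmLibrary):
            return NotImplemented
        return (self.description == other.description
                and self.info == other.info
                and self.names("model") == other.names("model")
                and self.names("data") == other.names("data")
                and all(self.models[n] == other.models[n] for n in self.models)
                and all(self.data[n] == other.data[n] for n in self.data))

    def copy(self) -> "AmLibrary":
        lib = AmLibrary(self.description, self.info)
        lib.info = self.info.copy()
        for role in ROLES:
            lib._records[role] = {n: r.copy() for n, r in self._records[role].items()}
        return lib

    def __repr__(self) -> str:
        return (f"<AmLibrary {len(self.models)} models, "
                f"{len(self.data)} datasets: {self.description[:40]!r}>")

    def __str__(self) -> str:
        return summarize(self).render(with_metadata=False)


# -- summaries ---------------------------------------------------------------


@dataclass
class LibrarySummary:
    """A rendered-friendly snapshot of a library's contents.

    Row/column fields are ``None`` (shown as NA) for non-tabular payloads;
    metadata values longer than the truncation width are truncated with an
    ellipsis in the listing only -- stored values are untouched.
    """

    description: str
    info: dict[str, str]
    model_rows: list[dict[str, Any]]
    data_rows: list[dict[str, Any]]
    model_meta: dict[str, dict[str, str]]
    data_meta: dict[str, dict[str, str]]
    truncation_width: int = DEFAULT_TRUNCATION_WIDTH

    def render(self, with_metadata: bool = True) -> str:
        lines = ["Description:", f"  {self.description}", "Info:"]
        for key, value in self.info.items():
            lines.append(f"  {key}: {value}")
        lines.append("Models:")
        if not self.model_rows:
            lines.append("  --- There are no models ---")
        else:
            for row in self.model_rows:
                pkg = row["origin_package"] or "NA"
                lines.append(f"  {row['index']} {row['name']} "
                             f"[{row['payload_class']}] package={pkg}")
        lines.append("Data:")
        if not self.data_rows:
            lines.append("  --- There are no datasets ---")
        else:
            for row in self.data_rows:
                pkg = row["origin_package"] or "NA"
                nr = "NA" if row["nrows"] is None else row["nrows"]
                nc = "NA" if row["ncols"] is None else row["ncols"]
                lines.append(f"  {row['index']} {row['name']} "
                             f"[{row['payload_class']}] rows={nr} cols={nc} "
                             f"package={pkg}")
        if with_metadata:
            for title, meta in (("Model metadata", self.model_meta),
                                ("Data metadata", self.data_meta)):
                if meta:
                    lines.append(f"--- {title} ---")
                    for name, entries in meta.items():
                        lines.append(f"[{name}]")
                        for key, value in entries.items():
                            lines.append(f"  {key}: {value}")
        return "\n".join(lines)


def _truncate(value: str, width: int) -> str:
    return value if len(value) <= width else value[: width - 1] + "…"


def summarize(library: AmLibrary,
              truncation_width: int = DEFAULT_TRUNCATION_WIDTH) -> LibrarySummary:
    """Build an abbreviated snapshot: indexed listings + truncated metadata."""
    if truncation_width < 2:
        raise ValueError("truncation_width must be at least 2")
    model_rows, data_rows = [], []
    for i, (name, rec) in enumerate(library.models.items(), start=1):
        model_rows.append({"index": i, "name": name,
                           "payload_class": rec.payload_class,
                           "origin_package": rec.origin_package})
    for i, (name, rec) in enumerate(library.data.items(), start=1):
        shape = rec.shape()
        data_rows.append({"index": i, "name": name,
                          "payload_class": rec.payload_class,
                          "nrows": None if shape is None else int(shape[0]),
                          "ncols": None if shape is None else int(shape[1]),
                          "origin_package": rec.origin_package})
    model_meta = {n: {k: _truncate(v, truncation_width)
                      for k, v in r.metadata.items()}
                  for n, r in library.models.items()}
    data_meta = {n: {k: _truncate(v, truncation_width)
                     for k, v in r.metadata.items()}
                 for n, r in library.data.items()}
    return LibrarySummary(library.description, library.info.to_dict(),
                          model_rows, data_rows, model_meta, data_meta,
                          truncation_width)


# -- functional aliases ------------------------------------------------------
# Thin wrappers exposing the operations as plain functions, for callers who
# prefer a functional surface over the methods above.


def create_library(description: str = "",
                   info: Mapping[str, Any] | None = None) -> AmLibrary:
    """Create an empty library with a description and info metadata."""
    return AmLibrary(description, info)


def describe(library: AmLibrary, new_text: str | None = None) -> str:
    """Return the library description, first replacing it if *new_text* given."""
    if new_text is not None:
        library.set_description(new_text)
    return library.description


def edit_info(library: AmLibrary, updates: Mapping[str, Any] | None = None,
              select_key: str | None = None) -> MetadataMap:
    return library.edit_info(updates, select_key)


def insert_records(library: AmLibrary,
                   models: Mapping[str, AmRecord] | None = None,
                   data: Mapping[str, AmRecord] | None = None) -> AmLibrary:
    return library.insert(models=models, data=data)


def remove_record(library: AmLibrary, role: str,
                  selector: str | int) -> AmLibrary:
    return library.remove(role, selector)


def list_names(library: AmLibrary, role: str) -> list[str]:
    return library.names(role)


def get_record(library: AmLibrary, role: str, selector: str | int,
               with_metadata: bool = False) -> Any:
    return library.get(role, selector, with_metadata)


def record_meta(library: AmLibrary, role: str,
                name: str | int | None = None,
                updates: Mapping[str, Any] | None = None):
    return library.meta(role, name, updates)
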
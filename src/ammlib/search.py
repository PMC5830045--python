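"""Pattern search, link-preserving subsetting, and splitting of libraries.

Search matches a regular expression against each record's name, metadata
keys, and metadata values (payload internals are never searched).  After
matching, one pass of link closure is applied so models travel with their
input data: a matched dataset pulls in every model whose reserved "data"
metadata key names it, and a matched model pulls in the dataset its "data"
key names.  Closure is deliberately single-step -- applying it twice adds
nothing -- and follows only the "data" key by default; an opt-in flag also
follows "prior" links between models.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable

from .core import (
    DATA_LINK_KEY,
    PRIOR_LINK_KEY,
    AmLibrary,
    AmRecord,
    NotFoundError,
)

__all__ = ["grep_library", "subset_library", "split_library"]

SCOPES = ("all", "model", "data")


def _compile(pattern: str, case_insensitive: bool) -> re.Pattern:
    flags = re.IGNORECASE if case_insensitive else 0
    try:
        return re.compile(pattern, flags)
    except re.error as exc:
        raise ValueError(f"invalid regular expression {pattern!r}: {exc}") from exc


def _record_matches(name: str, record: AmRecord, rx: re.Pattern) -> bool:
    if rx.search(name):
        return True
    for key, value in record.metadata.items():
        if rx.search(key) or rx.search(value):
            return True
    return False


def _build_from(source: AmLibrary, model_names: Iterable[str],
                data_names: Iterable[str]) -> AmLibrary:
    """New library with the same description/info and copies of the named
    records, in the source's order."""
    out = AmLibrary(source.description)
    out.info = source.info.copy()
    wanted_m, wanted_d = set(model_names), set(data_names)
    out.insert(
        models={n: r.copy() for n, r in source.models.items() if n in wanted_m},
        data={n: r.copy() for n, r in source.data.items() if n in wanted_d},
    )
    return out


def _close_links(source: AmLibrary, models: set[str], data: set[str],
                 follow_prior: bool) -> tuple[set[str], set[str]]:
    """One closure pass over the "data" (and optionally "prior") links."""
    closed_m, closed_d = set(models), set(data)
    # matched model -> the dataset its "data" key names (when present)
    for name in models:
        linked = source.models[name].metadata.get(DATA_LINK_KEY)
        if linked is not None and linked in source.data:
            closed_d.add(linked)
    # matched dataset -> every model citing it through its "data" key
    for name, record in source.models.items():
        if record.metadata.get(DATA_LINK_KEY) in data:
            closed_m.add(name)
    if follow_prior:
        for name in models:
            linked = source.models[name].metadata.get(PRIOR_LINK_KEY)
            if linked is not None and linked in source.models:
                closed_m.add(linked)
        for name, record in source.models.items():
            if record.metadata.get(PRIOR_LINK_KEY) in models:
                closed_m.add(name)
    return closed_m, closed_d


def grep_library(pattern: str, library: AmLibrary, scope: str = "all",
                 case_insensitive: bool = False,
                 follow_prior: bool = False) -> AmLibrary:
    """Search a library and return the matches as a new library.

    The pattern is tested against record names, metadata keys and metadata
    values of the records in *scope* ("all", "model" or "data"); matched
    records plus their one-step link closure are returned in a new library
    carrying the source's description and info.  The source is untouched.
    """
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    rx = _compile(pattern, case_insensitive)
    models: set[str] = set()
    data: set[str] = set()
    if scope in ("all", "model"):
        models = {n for n, r in library.models.items() if _record_matches(n, r, rx)}
    if scope in ("all", "data"):
        data = {n for n, r in library.data.items() if _record_matches(n, r, rx)}
    models, data = _close_links(library, models, data, follow_prior)
    return _build_from(library, models, data)


def subset_library(library: AmLibrary,
                   selectors: Iterable[str | int | tuple[str, str | int]],
                   ) -> AmLibrary:
    """Select records by name/index, keeping each model's linked dataset.

    A bare name or 1-based index is resolved against the models first and
    then the data (a collision resolves to the model, with a warning); a
    ``(role, selector)`` tuple is unambiguous.  Selected models pull in
    the dataset named by their "data" metadata key when it exists in the
    source.  Description and info are copied to the result.
    """
    models: set[str] = set()
    data: set[str] = set()
    for sel in selectors:
        if isinstance(sel, tuple):
            role, inner = sel
            name = library._resolve(role, inner)
            (models if role == "model" else data).add(name)
            continue
        try:
            name = library._resolve("model", sel)
        except NotFoundError:
            data.add(library._resolve("data", sel))
        else:
            models.add(name)
            try:
                library._resolve("data", sel)
            except NotFoundError:
                pass
            else:
                warnings.warn(
                    f"selector {sel!r} matches both a model and a dataset; "
                    f"keeping the model (use a (role, selector) tuple to "
                    f"disambiguate)", stacklevel=2)
    # keep the data with the models
    for name in set(models):
        linked = library.models[name].metadata.get(DATA_LINK_KEY)
        if linked is not None and linked in library.data:
            data.add(linked)
    return _build_from(library, models, data)


def split_library(library: AmLibrary, pattern: str,
                  case_insensitive: bool = False,
                  follow_prior: bool = False,
                  ) -> dict[str, AmLibrary]:
    """Partition a library into the records matching *pattern* and the rest.

    ``extracted`` is exactly ``grep_library(pattern, library, "all")``;
    ``remainder`` is a copy of the source with every extracted record
    removed.  Together they partition the source's record sets (disjoint
    and exhaustive).  The source itself is untouched.
    """
    extracted = grep_library(pattern, library, "all",
                             case_insensitive=case_insensitive,
                             follow_prior=follow_prior)
    taken_m = set(extracted.names("model"))
    taken_d = set(extracted.names("data"))
    remainder = _build_from(
        library,
        (n for n in library.names("model") if n not in taken_m),
        (n for n in library.names("data") if n not in taken_d),
    )
    return {"extracted": extracted, "remainder": remainder}
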
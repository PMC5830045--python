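"""Seeded synthetic covariate tables from per-variable distribution specs.

Each covariate is described by a :class:`CovariateSpec` -- a distribution
family, its parameters, an integer seed of its own, and optional rounding.
Columns are drawn independently, so a table is reproducible column by
column: the same spec and seed always regenerate the identical column
regardless of which other covariates are requested alongside it.  An
optional trailing integer column named ``"yr"`` marks the (single) season
the covariates describe.

Specs can be built in code, from a plain mapping, or loaded from a
YAML/JSON file::

    unif1: {dist: uniform, min: 0, max: 10, seed: 334, round: 0}
    norm1: {dist: normal, mean: 10, sd: 2, seed: 10, round: 1}
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CovariateSpec",
    "simulate_covariates",
    "specs_from_mapping",
    "load_specs",
    "DISTRIBUTIONS",
]

#: Canonical family -> accepted aliases (function-style names included).
_ALIASES = {
    "uniform": {"uniform", "unif", "runif"},
    "normal": {"normal", "norm", "rnorm", "gaussian"},
    "beta": {"beta", "rbeta"},
    "binomial": {"binomial", "binom", "bin", "rbinom"},
    "bernoulli": {"bernoulli", "bern", "rbern"},
}
DISTRIBUTIONS = tuple(_ALIASES)

_PARAM_NAMES = {
    "uniform": ("min", "max"),
    "normal": ("mean", "sd"),
    "beta": ("shape1", "shape2"),
    "binomial": ("size", "prob"),
    "bernoulli": ("prob",),
}

_DEFAULTS = {
    "uniform": {"min": 0.0, "max": 1.0},
    "normal": {"mean": 0.0, "sd": 1.0},
    "beta": {},
    "binomial": {},
    "bernoulli": {},
}


def _normalize_dist(dist: Any, spec_name: str) -> str:
    if callable(dist):
        dist = getattr(dist, "__name__", str(dist))
    dist = str(dist).lower()
    for family, aliases in _ALIASES.items():
        if dist in aliases:
            return family
    raise ValueError(
        f"spec {spec_name!r}: unknown distribution {dist!r} "
        f"(expected one of {sorted(a for s in _ALIASES.values() for a in s)})")


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: distribution family, parameters, seed, rounding.

    Parameters
    ----------
    name : column name (must be unique within a table request)
    dist : family or alias -- uniform (min, max), normal (mean, sd),
        beta (shape1, shape2), binomial (size, prob), bernoulli (prob);
        a callable's ``__name__`` is also accepted ("rbeta" etc.)
    params : the family's parameters
    seed : integer seed for this column's own generator
    round_digits : round drawn values to this many decimals (None = exact)
    """

    name: str
    dist: str
    params: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    round_digits: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "dist", _normalize_dist(self.dist, self.name))
        params = {**_DEFAULTS[self.dist], **dict(self.params)}
        allowed = set(_PARAM_NAMES[self.dist]) | ({"size"} if self.dist == "bernoulli" else set())
        unknown = set(params) - allowed
        if unknown:
            raise ValueError(
                f"spec {self.name!r}: unknown parameter(s) {sorted(unknown)} "
                f"for {self.dist} (expected {_PARAM_NAMES[self.dist]})")
        missing = [p for p in _PARAM_NAMES[self.dist] if p not in params]
        if missing:
            raise ValueError(
                f"spec {self.name!r}: missing parameter(s) {missing} "
                f"for {self.dist}")
        self._validate(params)
        object.__setattr__(self, "params", params)
        if self.round_digits is not None and (
                not isinstance(self.round_digits, int) or self.round_digits < 0):
            raise ValueError(
                f"spec {self.name!r}: round_digits must be a non-negative "
                f"integer, got {self.round_digits!r}")

    def _validate(self, p: Mapping[str, float]) -> None:
        name = self.name
        if self.dist == "uniform" and not p["min"] <= p["max"]:
            raise ValueError(f"spec {name!r}: requires min <= max")
        if self.dist == "normal" and not p["sd"] > 0:
            raise ValueError(f"spec {name!r}: requires sd > 0")
        if self.dist == "beta" and not (p["shape1"] > 0 and p["shape2"] > 0):
            raise ValueError(f"spec {name!r}: requires shape1, shape2 > 0")
        if self.dist in ("binomial", "bernoulli"):
            if not 0 <= p["prob"] <= 1:
                raise ValueError(f"spec {name!r}: requires 0 <= prob <= 1")
        if self.dist == "binomial":
            if p["size"] < 0 or int(p["size"]) != p["size"]:
                raise ValueError(f"spec {name!r}: requires integer size >= 0")
        if self.dist == "bernoulli" and p.get("size", 1) != 1:
            raise ValueError(f"spec {name!r}: bernoulli size must be 1")

    def draw(self, n: int) -> np.ndarray:
        """Draw *n* values from this covariate's own seeded generator."""
        rng = np.random.default_rng(self.seed)
        p = self.params
        if self.dist == "uniform":
            values = rng.uniform(p["min"], p["max"], n)
        elif self.dist == "normal":
            values = rng.normal(p["mean"], p["sd"], n)
        elif self.dist == "beta":
            values = rng.beta(p["shape1"], p["shape2"], n)
        elif self.dist == "binomial":
            values = rng.binomial(int(p["size"]), p["prob"], n).astype(np.int64)
        else:  # bernoulli = binomial with a single trial
            values = rng.binomial(1, p["prob"], n).astype(np.int64)
        if self.round_digits is not None:
            values = np.round(values, self.round_digits)
        return values


def simulate_covariates(specs: Sequence[CovariateSpec], n: int,
                        add_year: bool = False, year: int = 1) -> pd.DataFrame:
    """Generate an n-row covariate table, one column per spec in order.

    With ``add_year=True`` a final integer column ``"yr"`` holding the
    constant *year* is appended.
    """
    if n < 1:
        raise ValueError(f"n must be a positive count, got {n}")
    names = [s.name for s in specs]
    seen: set[str] = set()
    for name in names + (["yr"] if add_year else []):
        if name in seen:
            raise ValueError(f"duplicate column name {name!r}")
        seen.add(name)
    table = {spec.name: spec.draw(n) for spec in specs}
    if add_year:
        table["yr"] = np.full(n, int(year), dtype=np.int64)
    return pd.DataFrame(table)


def specs_from_mapping(mapping: Mapping[str, Mapping[str, Any]],
                       ) -> list[CovariateSpec]:
    """Build specs from ``{column name: {dist: ..., <params>, seed, round}}``.

    The per-column mapping mixes the distribution parameters with the
    ``dist``, ``seed`` and ``round`` (or ``round_digits``) keys, matching
    the shape of a config file.
    """
    specs = []
    for name, raw in mapping.items():
        raw = dict(raw)
        dist = raw.pop("dist", None)
        if dist is None:
            raise ValueError(f"spec {name!r}: missing 'dist'")
        seed = raw.pop("seed", 0)
        round_digits = raw.pop("round_digits", raw.pop("round", None))
        specs.append(CovariateSpec(name=name, dist=dist, params=raw,
                                   seed=seed, round_digits=round_digits))
    return specs


def load_specs(path: str | os.PathLike) -> list[CovariateSpec]:
    """Load covariate specs from a YAML or JSON file."""
    with open(os.fspath(path), "r", encoding="utf-8") as handle:
        mapping = yaml.safe_load(handle)
    if not isinstance(mapping, Mapping):
        raise ValueError(f"{path}: expected a mapping of column specs")
    return specs_from_mapping(mapping)
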
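"""Exact-arithmetic metabolic network representation.

A metabolic network is a stoichiometry matrix N over metabolites x reactions,
with every coefficient an exact rational, plus the annotations needed for
conversion analysis: which metabolites are internal (steady-state balanced)
versus external, and whether each external metabolite can be consumed
(input), produced (output), or both.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction

from ._rational import ZERO, Vec, frac, normalize_ray


class Direction(str, enum.Enum):
    """Allowed net flow of an external metabolite across the system boundary."""

    INPUT = "input"
    OUTPUT = "output"
    BOTH = "both"


class Origin(str, enum.Enum):
    MODEL = "model"
    VIRTUAL_SPLIT_IN = "virtual_split_in"
    VIRTUAL_SPLIT_OUT = "virtual_split_out"
    VIRTUAL_TAG = "virtual_tag"
    VIRTUAL_HIDE = "virtual_hide"
    VIRTUAL = "virtual"


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    is_internal: bool = True
    direction: Direction | None = None
    origin: Origin = Origin.MODEL

    def __post_init__(self):
        if not self.is_internal and self.direction is None:
            raise ValueError(f"external metabolite {self.id!r} needs a direction")


@dataclass(frozen=True)
class Reaction:
    """A reaction column: metabolite id -> rational coefficient.

    Negative coefficients are consumed, positive produced.  Zero entries are
    never stored.
    """

    id: str
    stoichiometry: dict[str, Fraction]
    reversible: bool = False
    origin: Origin = Origin.MODEL

    def __post_init__(self):
        clean = {m: frac(c) for m, c in self.stoichiometry.items() if frac(c) != 0}
        if not clean:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")
        object.__setattr__(self, "stoichiometry", clean)

    def negated(self, new_id: str) -> "Reaction":
        return Reaction(
            id=new_id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            origin=self.origin,
        )


class NetworkError(ValueError):
    """Inconsistent or malformed network model."""


@dataclass
class MetabolicNetwork:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    #: provenance of preprocessing transforms: split/hide/tag bookkeeping
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise NetworkError("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise NetworkError("duplicate reaction ids")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise NetworkError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def metabolite_index(self, mid: str) -> int:
        return self.metabolite_ids.index(mid)

    @property
    def internal_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.is_internal]

    @property
    def external_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.is_internal]

    # -- stoichiometry ---------------------------------------------------
    def column(self, reaction: Reaction) -> Vec:
        return tuple(reaction.stoichiometry.get(m.id, ZERO) for m in self.metabolites)

    @property
    def N(self) -> list[Vec]:
        """Stoichiometry matrix as a list of columns (one per reaction)."""
        return [self.column(r) for r in self.reactions]

    def N_rows(self) -> list[Vec]:
        cols = self.N
        return [tuple(col[i] for col in cols) for i in range(len(self.metabolites))]

    def internal_rows(self) -> list[Vec]:
        cols = self.N
        return [
            tuple(col[i] for col in cols)
            for i, m in enumerate(self.metabolites)
            if m.is_internal
        ]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            metadata=dict(self.metadata),
        )

    def with_metabolite(self, mid: str, **changes) -> "MetabolicNetwork":
        """Return a copy with one metabolite's fields replaced."""
        net = self.copy()
        net.metabolites = [
            replace(m, **changes) if m.id == mid else m for m in net.metabolites
        ]
        return net


@dataclass(frozen=True)
class Conversion:
    """A net rate-of-change vector over a network's metabolite ordering."""

    metabolite_ids: tuple[str, ...]
    values: Vec
    network_ref: str = ""

    def __post_init__(self):
        if len(self.metabolite_ids) != len(self.values):
            raise ValueError("conversion dimension mismatch")

    def __getitem__(self, mid: str) -> Fraction:
        return self.values[self.metabolite_ids.index(mid)]

    def as_dict(self) -> dict[str, Fraction]:
        return {m: v for m, v in zip(self.metabolite_ids, self.values) if v != 0}

    def normalized(self) -> "Conversion":
        return Conversion(self.metabolite_ids, normalize_ray(self.values), self.network_ref)
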
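"""Pluggable compound lookup (the Finder interface).

A backend answers structure/name/formula/mass/identifier queries with
:class:`CompoundHit` records.  The bundled :class:`FixtureBackend` is a
pure, offline backend over a JSON list of records and is the one used in
tests; live REST clients (PubChem, ChEBI, ...) can be added by
implementing the same interface — no core change is required.

Block metadata resolution is local-first: a block structure is looked up
in the selected container before any backend is asked.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Protocol

from .chem import canonical_generic_smiles
from .formula import Formula

if TYPE_CHECKING:  # pragma: no cover
    from .database import Container

__all__ = [
    "CompoundHit",
    "Query",
    "FinderBackend",
    "FixtureBackend",
    "FinderError",
    "ResolvedBlock",
    "find",
    "resolve_block_metadata",
]

log = logging.getLogger(__name__)

_FACETS = ("name", "formula", "mass", "identifier", "smiles")


class FinderError(RuntimeError):
    """Backend failure (network, malformed response) — distinct from 'no hits'."""


@dataclass(frozen=True)
class CompoundHit:
    """One candidate compound returned by a backend."""

    name: str | None = None
    smiles: str | None = None
    formula: Formula | None = None
    mass: float | None = None
    database: str | None = None   # e.g. "CID", "CSID", "CHEBI"
    identifier: str | None = None

    def __post_init__(self):
        if not (self.name or self.smiles):
            raise ValueError("a hit needs at least a name or a SMILES")

    @property
    def reference(self) -> str | None:
        """Rendered as in block references, e.g. ``CID: 602``."""
        if self.database and self.identifier:
            return f"{self.database}: {self.identifier}"
        return None


@dataclass(frozen=True)
class Query:
    """Exactly one search facet must be set; mass queries take a tolerance."""

    name: str | None = None
    formula: str | Formula | None = None
    mass: float | None = None
    tolerance: float = 0.001  # Da, for mass queries
    identifier: str | None = None
    smiles: str | None = None

    def __post_init__(self):
        facets = [f for f in _FACETS if getattr(self, f) is not None]
        if len(facets) != 1:
            raise ValueError(
                f"exactly one query facet required, got {facets or 'none'}")

    @property
    def facet(self) -> str:
        return next(f for f in _FACETS if getattr(self, f) is not None)


class FinderBackend(Protocol):
    """Interface every lookup backend implements."""

    #: facets this backend can answer
    capabilities: frozenset[str]

    def search(self, query: Query) -> list[CompoundHit]: ...


class FixtureBackend:
    """Offline backend over an in-memory (or JSON-file) record list.

    Matching is by canonical generic SMILES, case-insensitive name
    containment is NOT used — names match case-insensitively but exactly —
    Hill formula string, identifier, or mass within the query tolerance.
    Pure: identical queries always return identical results.
    """

    capabilities = frozenset(_FACETS)

    def __init__(self, hits: list[CompoundHit]):
        self.hits = list(hits)

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureBackend":
        records = json.loads(Path(path).read_text(encoding="utf-8"))
        hits = []
        for r in records:
            hits.append(CompoundHit(
                name=r.get("name"), smiles=r.get("smiles"),
                formula=Formula.parse(r["formula"]) if r.get("formula") else None,
                mass=r.get("mass"), database=r.get("database"),
                identifier=r.get("identifier")))
        return cls(hits)

    def _hit_formula(self, hit: CompoundHit) -> Formula | None:
        if hit.formula is not None:
            return hit.formula
        if hit.smiles:
            from .chem import formula_of, parse_smiles
            return formula_of(parse_smiles(hit.smiles))
        return None

    def search(self, query: Query) -> list[CompoundHit]:
        facet = query.facet
        out: list[CompoundHit] = []
        if facet == "smiles":
            key = canonical_generic_smiles(query.smiles)
            for h in self.hits:
                if h.smiles and canonical_generic_smiles(h.smiles) == key:
                    out.append(h)
        elif facet == "name":
            key = query.name.strip().lower()
            out = [h for h in self.hits if h.name and h.name.lower() == key]
        elif facet == "formula":
            f = (query.formula if isinstance(query.formula, Formula)
                 else Formula.parse(query.formula))
            for h in self.hits:
                hf = self._hit_formula(h)
                if hf is not None and hf == f:
                    out.append(h)
        elif facet == "mass":
            for h in self.hits:
                m = h.mass
                if m is None:
                    hf = self._hit_formula(h)
                    m = hf.monoisotopic_mass if hf is not None else None
                if m is not None and abs(m - query.mass) <= query.tolerance:
                    out.append(h)
        elif facet == "identifier":
            out = [h for h in self.hits if h.identifier == query.identifier]
        return out


def find(query: Query, backend: FinderBackend) -> list[CompoundHit]:
    """Run *query* against *backend*; empty list means no hits."""
    if query.facet not in backend.capabilities:
        raise FinderError(
            f"backend {type(backend).__name__} cannot search by {query.facet}")
    return backend.search(query)


@dataclass
class ResolvedBlock:
    """Metadata attached to a block structure after lookup."""

    name: str | None = None
    acronym: str | None = None
    losses: list[Formula] = field(default_factory=list)
    references: list[tuple[str, str]] = field(default_factory=list)
    source: str = "none"  # local | finder | none


def resolve_block_metadata(block_smiles: str, container: "Container | None",
                           backend: FinderBackend | None) -> ResolvedBlock:
    """Local-first metadata lookup for a block structure.

    The container is matched by canonical generic SMILES and wins over any
    backend hit.  Backend errors degrade to the no-match path with a
    logged warning; an unmatched block comes back with ``source='none'``
    and the caller synthesizes an acronym.
    """
    key = canonical_generic_smiles(block_smiles)
    if container is not None:
        for blk in container.blocks:
            if blk.smiles and canonical_generic_smiles(blk.smiles) == key:
                return ResolvedBlock(
                    name=blk.name, acronym=blk.acronym,
                    losses=list(blk.losses),
                    references=list(blk.references), source="local")
    if backend is not None:
        try:
            hits = find(Query(smiles=key), backend)
        except FinderError as exc:
            log.warning("finder backend failed for %s: %s", key, exc)
            hits = []
        if hits:
            h = hits[0]
            refs = []
            if h.database and h.identifier:
                refs.append((h.database, h.identifier))
            return ResolvedBlock(name=h.name, references=refs, source="finder")
    return ResolvedBlock()
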
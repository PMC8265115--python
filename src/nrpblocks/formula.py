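"""Molecular formulas as element-count maps.

A :class:`Formula` is an immutable mapping from element symbol to a
positive count, rendered canonically in Hill order (C first, then H, then
all other elements alphabetically; without carbon, strictly alphabetical).
Residue and molecular formulas of building blocks, neutral losses and
terminal modifications are all carried as ``Formula`` values, and every
monoisotopic mass in the package is derived from one.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

from .elements import mass_of_element

__all__ = ["Formula", "FormulaError", "monoisotopic_mass"]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string or invalid formula arithmetic."""


class Formula(Mapping[str, int]):
    """Element -> count map with arithmetic and Hill-order rendering.

    Zero counts are dropped on construction; negative counts are an error.
    Instances are hashable and compare by content.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for sym, n in source.items():
                merged[sym] = merged.get(sym, 0) + int(n)
        for sym, n in merged.items():
            if n < 0:
                raise FormulaError(f"negative count for {sym}: {n}")
        object.__setattr__(self, "_counts",
                           {s: n for s, n in merged.items() if n != 0})

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, key: str) -> int:
        return self._counts[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("Formula is immutable")

    # -- construction ------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a plain formula string like ``C6H11NO`` or ``H2O``.

        The whole string must consist of element tokens; anything else
        (charges, parentheses, isotopes) is rejected.
        """
        text = text.strip()
        if not text:
            return cls()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise FormulaError(
                    f"cannot parse formula {text!r} at position {pos}")
            sym, digits = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    # -- rendering ---------------------------------------------------------
    def hill(self) -> str:
        """Canonical Hill-order string; parse/render round-trips."""
        parts: list[str] = []
        counts = dict(self._counts)
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else []) + sorted(
                k for k in counts if k not in ("C", "H"))
        else:
            order = sorted(counts)
        for sym in order:
            n = counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        out = dict(self._counts)
        for s, n in other.items():
            out[s] = out.get(s, 0) + n
        return Formula(out)

    def __sub__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        out = dict(self._counts)
        for s, n in other.items():
            out[s] = out.get(s, 0) - n
            if out[s] < 0:
                raise FormulaError(
                    f"subtraction would leave negative {s} count "
                    f"({self.hill()} - {other.hill()})")
        return Formula(out)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int):
            return NotImplemented
        if k < 0:
            raise FormulaError("cannot multiply formula by a negative int")
        return Formula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # -- mass --------------------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        """Sum of most-abundant-isotope masses, in Da."""
        return sum(mass_of_element(s) * n for s, n in self._counts.items())


# common deltas used throughout the block calculus
WATER = Formula(H=2, O=1)
H2 = Formula(H=2)


def monoisotopic_mass(formula: Formula | str) -> float:
    """Monoisotopic mass of *formula* (a :class:`Formula` or string) in Da."""
    if isinstance(formula, str):
        formula = Formula.parse(formula)
    return formula.monoisotopic_mass
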
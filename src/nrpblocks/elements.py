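"""Monoisotopic masses of the elements.

Single authoritative table used everywhere a mass is computed.  Values are
the masses of the most abundant natural isotope (CODATA/AME2020), in Da,
to at least six decimal places.  The table covers the elements occurring
in nonribosomal peptides, polyketides and their common adducts.
"""

from __future__ import annotations

__all__ = ["MONOISOTOPIC_MASS", "ELECTRON_MASS", "mass_of_element"]

#: element symbol -> monoisotopic mass of the most abundant isotope [Da]
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "Mg": 23.9850417,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Se": 73.9224764,
    "Br": 78.9183371,
    "I": 126.904473,
}

ELECTRON_MASS: float = 0.00054857990907


class UnknownElementError(KeyError):
    """An element symbol without an entry in the mass table."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"no monoisotopic mass for element {self.symbol!r}"


def mass_of_element(symbol: str) -> float:
    """Monoisotopic mass of one atom of *symbol* in Da."""
    try:
        return MONOISOTOPIC_MASS[symbol]
    except KeyError:
        raise UnknownElementError(symbol) from None
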
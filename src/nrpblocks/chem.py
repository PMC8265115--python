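"""SMILES parsing, molecular graphs, and canonicalization.

Thin layer over RDKit.  A :class:`MolecularGraph` keeps the parsed RDKit
molecule (atom indices preserve SMILES input order) and exposes the
atom/bond views the rest of the package works with.  Stereochemistry is
deliberately disposable here: mass spectra cannot distinguish it, so the
generic (stereo-stripped) canonical SMILES is the identity of a structure
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem
from rdkit import RDLogger

from .formula import Formula

__all__ = [
    "MolecularGraph",
    "SmilesError",
    "parse_smiles",
    "formula_of",
    "strip_stereo",
    "canonical_smiles",
    "canonical_generic_smiles",
]

RDLogger.DisableLog("rdApp.*")  # RDKit parse noise goes through exceptions instead


class SmilesError(ValueError):
    """SMILES that cannot be parsed or violates a structural precondition."""

    def __init__(self, smiles: str, reason: str):
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")
        self.smiles = smiles
        self.reason = reason


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    charge: int
    hydrogens: int  # implicit + explicit H count


@dataclass(frozen=True)
class Bond:
    index: int
    atoms: tuple[int, int]  # endpoint atom indices, low first
    order: str  # single | double | triple | aromatic


_BOND_NAMES = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


class MolecularGraph:
    """A single-component molecule as an atom/bond graph.

    Wraps an RDKit molecule; atom and bond indices are dense, 0-based and
    follow the input SMILES order.
    """

    def __init__(self, mol: Chem.Mol, smiles: str):
        self.mol = mol
        self.smiles = smiles

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(a.GetIdx(), a.GetSymbol(), a.GetFormalCharge(), a.GetTotalNumHs())
            for a in self.mol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[Bond]:
        out = []
        for b in self.mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            order = _BOND_NAMES.get(b.GetBondType())
            if order is None:
                raise SmilesError(self.smiles,
                                  f"unsupported bond type {b.GetBondType()}")
            out.append(Bond(b.GetIdx(), (min(i, j), max(i, j)), order))
        return out

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def num_bonds(self) -> int:
        return self.mol.GetNumBonds()

    @property
    def net_charge(self) -> int:
        return sum(a.GetFormalCharge() for a in self.mol.GetAtoms())

    def __repr__(self) -> str:
        return f"MolecularGraph({self.smiles!r}, atoms={self.num_atoms})"


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(smiles, "RDKit could not parse/sanitize the string")
    return mol


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a single-component SMILES into a :class:`MolecularGraph`.

    Multi-component input (dot-separated fragments) is rejected: one
    compound per decomposition.
    """
    mol = _mol_from_smiles(smiles)
    if len(Chem.GetMolFrags(mol)) != 1:
        raise SmilesError(smiles, "multi-component SMILES (contains '.')")
    return MolecularGraph(mol, smiles)


def formula_of(graph: MolecularGraph | Chem.Mol) -> Formula:
    """Molecular formula including implicit hydrogens."""
    mol = graph.mol if isinstance(graph, MolecularGraph) else graph
    counts: dict[str, int] = {}
    for a in mol.GetAtoms():
        counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        nh = a.GetTotalNumHs()
        if nh:
            counts["H"] = counts.get("H", 0) + nh
    return Formula(counts)


def strip_stereo(smiles: str) -> str:
    """Remove all stereochemical markup (@, @@, /, \\) from *smiles*.

    The heavy-atom graph and bond orders are unchanged; the result is the
    canonical generic SMILES of the molecule.
    """
    mol = _mol_from_smiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def canonical_smiles(smiles: str) -> str:
    """Deterministic canonical SMILES; a function of the molecule only."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def canonical_generic_smiles(smiles: str) -> str:
    """Canonical SMILES with stereo stripped — the block identity key."""
    return strip_stereo(smiles)
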
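"""Perception of cleavable peptide (amide) and ester bonds.

An amide candidate is a C-N single bond whose carbon carries a
double-bonded oxygen; secondary and tertiary (N-alkylated) amides both
qualify, while amides whose nitrogen sits in an aromatic ring do not (no
chain can pass through them without destroying the ring).  An ester
candidate is the C(=O)-O single bond of an ester group (the single-bonded
oxygen must connect to another carbon, which excludes free carboxyls).

A candidate is skipped when cutting it would leave a fragment of three or
fewer heavy atoms — this keeps terminal decorations such as acetyl groups
attached to their residue instead of becoming blocks of their own.  Users
can override any decision by toggling individual bonds; manual toggles are
authoritative and bypass both the pattern match and the skip rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

from .chem import MolecularGraph

__all__ = ["BondAnnotation", "BondRole", "find_cleavable_bonds", "toggle_bond"]

# acyl carbon, carbonyl O, amide N
_AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])-[NX3]")
# acyl carbon, carbonyl O, ester O, carbon on the alkoxy side
_ESTER = Chem.MolFromSmarts("[CX3](=[OX1])-[OX2]-[#6]")

#: heavy atoms at or below which a would-be fragment suppresses cleavage
SMALL_FRAGMENT_LIMIT = 3


@dataclass(frozen=True)
class BondRole:
    """Directed reading of one cleavable bond."""

    acyl_atom: int    # carbonyl carbon side
    hetero_atom: int  # amide N or ester O side
    kind: str         # "amide" | "ester" | "manual"


@dataclass
class BondAnnotation:
    """Set of cleavable bond indices plus per-bond provenance and roles.

    ``provenance`` maps every touched bond index to ``auto``,
    ``manual-added`` or ``manual-removed``; indices marked
    ``manual-removed`` are never members of ``cleavable``.
    """

    cleavable: set[int] = field(default_factory=set)
    provenance: dict[int, str] = field(default_factory=dict)
    roles: dict[int, BondRole] = field(default_factory=dict)

    def copy(self) -> "BondAnnotation":
        return BondAnnotation(set(self.cleavable), dict(self.provenance),
                              dict(self.roles))


def _fragment_sizes(mol: Chem.Mol, bond_idx: int) -> tuple[int, int]:
    """Heavy-atom counts of the two sides of *bond_idx* once removed.

    For a ring bond the graph stays connected and both sides are the whole
    molecule.
    """
    bond = mol.GetBondWithIdx(bond_idx)
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    # BFS from a, not crossing the bond
    seen = {a}
    stack = [a]
    while stack:
        cur = stack.pop()
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            j = nb.GetIdx()
            if cur == a and j == b:
                continue
            if j not in seen:
                seen.add(j)
                stack.append(j)
    if b in seen:  # ring bond: still connected
        n = mol.GetNumAtoms()
        return n, n
    return len(seen), mol.GetNumAtoms() - len(seen)


def _infer_role(mol: Chem.Mol, bond_idx: int, kind: str = "manual") -> BondRole:
    """Best-effort acyl/hetero orientation for a manually toggled bond."""
    bond = mol.GetBondWithIdx(bond_idx)
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()

    def is_acyl(atom: Chem.Atom) -> bool:
        if atom.GetSymbol() != "C":
            return False
        return any(
            nb.GetSymbol() == "O"
            and mol.GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx()).GetBondType()
            == Chem.BondType.DOUBLE
            for nb in atom.GetNeighbors()
        )

    if is_acyl(a) and not is_acyl(b):
        return BondRole(a.GetIdx(), b.GetIdx(), kind)
    if is_acyl(b) and not is_acyl(a):
        return BondRole(b.GetIdx(), a.GetIdx(), kind)
    lo, hi = sorted((a.GetIdx(), b.GetIdx()))
    return BondRole(lo, hi, kind)


def find_cleavable_bonds(graph: MolecularGraph,
                         include_esters: bool = True) -> BondAnnotation:
    """Automatically annotate cleavable amide (and optionally ester) bonds.

    Applies the small-fragment skip rule: a candidate whose hypothetical
    cleavage would yield a fragment of <= 3 heavy atoms is excluded.
    Returns an empty annotation when nothing matches.
    """
    mol = graph.mol
    ann = BondAnnotation()

    candidates: dict[int, BondRole] = {}
    for c, _o, n in mol.GetSubstructMatches(_AMIDE):
        bidx = mol.GetBondBetweenAtoms(c, n).GetIdx()
        candidates.setdefault(bidx, BondRole(c, n, "amide"))
    if include_esters:
        for c, _o, o, _c2 in mol.GetSubstructMatches(_ESTER):
            bidx = mol.GetBondBetweenAtoms(c, o).GetIdx()
            candidates.setdefault(bidx, BondRole(c, o, "ester"))

    for bidx in sorted(candidates):
        if min(_fragment_sizes(mol, bidx)) <= SMALL_FRAGMENT_LIMIT:
            continue
        ann.cleavable.add(bidx)
        ann.provenance[bidx] = "auto"
        ann.roles[bidx] = candidates[bidx]
    return ann


def toggle_bond(annotation: BondAnnotation, graph: MolecularGraph,
                bond_index: int) -> BondAnnotation:
    """Flip membership of *bond_index* in the cleavable set.

    The user is authoritative: no pattern check or skip rule is applied.
    Returns a new annotation; toggling twice restores the original set.
    """
    if not (0 <= bond_index < graph.num_bonds):
        raise IndexError(
            f"bond index {bond_index} out of range "
            f"(molecule has {graph.num_bonds} bonds)")
    out = annotation.copy()
    if bond_index in out.cleavable:
        out.cleavable.discard(bond_index)
        out.provenance[bond_index] = "manual-removed"
        out.roles.pop(bond_index, None)
    else:
        out.cleavable.add(bond_index)
        out.provenance[bond_index] = "manual-added"
        out.roles[bond_index] = _infer_role(graph.mol, bond_index)
    return out
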
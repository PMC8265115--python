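"""Splitting an annotated molecule into building blocks.

Removing the cleavable bonds leaves one connected component per block
occurrence.  Each occurrence is capped back to a free, neutral monomer:
every cleaved amide nitrogen or ester oxygen regains a hydrogen, and the
first cleaved acyl carbon regains a hydroxyl so the chain-facing carbonyl
becomes a carboxyl group.  Only one hydroxyl is invented per block — a
block cleaved on two acyl sides (e.g. the succinyl unit of
desferrioxamines) keeps its second carbonyl as a formyl group, because
mass spectrometry cannot place the extra oxygen.

Residue formulas follow the water-elimination convention: molecular
formula minus H2O for blocks with a C-terminus, minus H2 for blocks
terminated by amine groups on both sides (Hpd, putrescine), which is what
flags a structure as a polyketide downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem

from .bonds import BondAnnotation, BondRole, _infer_role, find_cleavable_bonds, toggle_bond
from .chem import MolecularGraph, formula_of, parse_smiles
from .classify import SequenceType, classify
from .formula import H2, WATER, Formula, FormulaError
from .notation import BlockSequence

__all__ = [
    "BuildingBlock",
    "BlockOccurrence",
    "BlockEdge",
    "BlockGraph",
    "DecompositionError",
    "DecompositionResult",
    "split_blocks",
    "order_blocks",
    "decompose",
]

_FREE_CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_FREE_AMINE = Chem.MolFromSmarts("[NX3;H2,H1;!$([N]C=[OX1]);!$([N]C=[NX2])]")


class DecompositionError(ValueError):
    """Molecule cannot be decomposed (charged, malformed block, ...)."""


@dataclass
class BuildingBlock:
    """A monomer: residue formula, capped structure and terminus profile.

    ``smiles`` is the canonical generic (stereo-stripped) SMILES of the
    free monomer and serves as the identity of the block everywhere;
    acronyms and names are user metadata.
    """

    acronym: str
    name: str
    residue_formula: Formula
    smiles: str
    n_termini: int
    c_termini: int
    losses: list[Formula] = field(default_factory=list)
    references: list[tuple[str, str]] = field(default_factory=list)

    @property
    def residue_mass(self) -> float:
        return self.residue_formula.monoisotopic_mass

    @property
    def molecular_formula(self) -> Formula:
        """Free-monomer formula: residue + H2O, or + H2 without a C-terminus."""
        return self.residue_formula + (WATER if self.c_termini >= 1 else H2)


@dataclass
class BlockOccurrence:
    """One fragment of the parent molecule after cleavage."""

    id: int
    atom_indices: frozenset[int]  # parent heavy-atom indices
    smiles: str                   # capped, canonical generic
    molecular_formula: Formula
    residue_formula: Formula
    c_termini: int
    n_termini: int
    cleaved_acyl: int    # cleaved bonds where this fragment held the carbonyl
    cleaved_hetero: int  # cleaved bonds entering on the N/O side
    block_index: int = -1  # filled after deduplication

    @property
    def min_atom(self) -> int:
        """Lowest parent atom index; the deterministic ordering anchor."""
        return min(self.atom_indices)


@dataclass(frozen=True)
class BlockEdge:
    """One cleaved bond, read acyl side -> amine/alkoxy side."""

    donor: int     # occurrence id holding the carbonyl carbon
    acceptor: int  # occurrence id holding the N or O
    bond_index: int
    kind: str      # amide | ester | manual


@dataclass
class BlockGraph:
    """Occurrences connected by the cleaved bonds of the parent."""

    occurrences: list[BlockOccurrence]
    edges: list[BlockEdge]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(o.id for o in self.occurrences)
        g.add_edges_from((e.donor, e.acceptor) for e in self.edges)
        return g

    def occurrence(self, occ_id: int) -> BlockOccurrence:
        return self.occurrences[occ_id]


def split_blocks(graph: MolecularGraph,
                 annotation: BondAnnotation) -> BlockGraph:
    """Cut the annotated bonds, cap the fragments, compute formulas.

    An empty annotation is allowed: the whole molecule becomes a single
    block.  The parent must be neutral and single-component.
    """
    mol = graph.mol
    if graph.net_charge != 0:
        raise DecompositionError(
            f"parent must be neutral (net charge {graph.net_charge:+d})")

    roles: dict[int, BondRole] = {}
    for bidx in sorted(annotation.cleavable):
        role = annotation.roles.get(bidx)
        roles[bidx] = role if role is not None else _infer_role(mol, bidx)

    rw = Chem.RWMol(mol)
    for bidx, role in roles.items():
        bond = mol.GetBondWithIdx(bidx)
        rw.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())

    n_orig = mol.GetNumAtoms()
    frags = Chem.GetMolFrags(rw)
    frag_of: dict[int, int] = {}
    for fi, atoms in enumerate(frags):
        for a in atoms:
            frag_of[a] = fi

    acyl_in: dict[int, list[int]] = {fi: [] for fi in range(len(frags))}
    hetero_in: dict[int, list[int]] = {fi: [] for fi in range(len(frags))}
    for bidx, role in roles.items():
        acyl_in[frag_of[role.acyl_atom]].append(role.acyl_atom)
        hetero_in[frag_of[role.hetero_atom]].append(role.hetero_atom)

    # cap: one hydroxyl on the first cleaved acyl carbon of each fragment;
    # hydrogens everywhere else (implicit, or explicit for bracket atoms)
    for fi in range(len(frags)):
        acyls = sorted(set(acyl_in[fi]))
        for rank, aidx in enumerate(acyls):
            atom = rw.GetAtomWithIdx(aidx)
            if rank == 0:
                o_idx = rw.AddAtom(Chem.Atom(8))
                rw.AddBond(aidx, o_idx, Chem.BondType.SINGLE)
                frag_of[o_idx] = fi
            elif atom.GetNoImplicit():
                atom.SetNumExplicitHs(atom.GetNumExplicitHs() + 1)
        for hidx in set(hetero_in[fi]):
            atom = rw.GetAtomWithIdx(hidx)
            if atom.GetNoImplicit():
                # one extra H per cleaved bond at this atom
                n_cuts = hetero_in[fi].count(hidx)
                atom.SetNumExplicitHs(atom.GetNumExplicitHs() + n_cuts)

    try:
        Chem.SanitizeMol(rw)
    except Exception as exc:  # valence violation after capping
        raise DecompositionError(f"capping failed: {exc}") from exc

    capped_frags = Chem.GetMolFrags(rw)
    capped_mols = Chem.GetMolFrags(rw, asMols=True, sanitizeFrags=True)
    # map capped fragments back to pre-cap fragment ids via shared atoms
    capped_to_orig = {}
    for ci, atoms in enumerate(capped_frags):
        capped_to_orig[ci] = frag_of[atoms[0]]

    occurrences: list[BlockOccurrence] = [None] * len(frags)  # type: ignore
    for ci, frag_mol in enumerate(capped_mols):
        fi = capped_to_orig[ci]
        orig_atoms = frozenset(a for a in capped_frags[ci] if a < n_orig)
        Chem.RemoveStereochemistry(frag_mol)
        smiles = Chem.MolToSmiles(frag_mol)
        molecular = formula_of(frag_mol)

        free_carboxyls = sum(
            1 for m in mol.GetSubstructMatches(_FREE_CARBOXYL)
            if set(m) <= orig_atoms)
        free_amines = sum(
            1 for m in mol.GetSubstructMatches(_FREE_AMINE)
            if set(m) <= orig_atoms)

        n_acyl = len(acyl_in[fi])
        n_hetero_n = sum(
            1 for h in hetero_in[fi] if mol.GetAtomWithIdx(h).GetSymbol() == "N")
        c_termini = n_acyl + free_carboxyls
        n_termini = n_hetero_n + free_amines
        try:
            residue = molecular - (WATER if c_termini >= 1 else H2)
        except FormulaError as exc:
            raise DecompositionError(
                f"malformed block {smiles!r}: {exc}") from exc
        occurrences[fi] = BlockOccurrence(
            id=fi, atom_indices=orig_atoms, smiles=smiles,
            molecular_formula=molecular, residue_formula=residue,
            c_termini=c_termini, n_termini=n_termini,
            cleaved_acyl=n_acyl, cleaved_hetero=len(hetero_in[fi]))

    edges = [
        BlockEdge(donor=frag_of[role.acyl_atom],
                  acceptor=frag_of[role.hetero_atom],
                  bond_index=bidx, kind=role.kind)
        for bidx, role in sorted(roles.items())
    ]
    return BlockGraph(occurrences=list(occurrences), edges=edges)


# --------------------------------------------------------------------------
# ordering


def _ring_rotation(bg: BlockGraph, g: nx.MultiGraph) -> list[int]:
    """One deterministic rotation of the cycle, N->C where directionality
    allows; starts at the occurrence with the lowest parent atom index."""
    try:
        cycle_edges = nx.find_cycle(g)
    except nx.NetworkXNoCycle:  # pragma: no cover - guarded by caller
        raise
    ring_nodes = {u for u, v, *_ in cycle_edges} | {v for u, v, *_ in cycle_edges}
    donors = {(e.donor, e.acceptor) for e in bg.edges}
    start = min(ring_nodes, key=lambda n: bg.occurrence(n).min_atom)
    neighbours = [n for n in g.neighbors(start) if n in ring_nodes and n != start]
    # prefer walking with the acyl->amine direction (upstream first)
    forward = [n for n in neighbours if (start, n) in donors]
    pool = forward or neighbours
    nxt = min(pool, key=lambda n: bg.occurrence(n).min_atom)
    order = [start, nxt]
    while len(order) < len(ring_nodes):
        prev, cur = order[-2], order[-1]
        step = [n for n in g.neighbors(cur)
                if n in ring_nodes and n != prev and n not in order]
        if not step:
            break
        order.append(min(step, key=lambda n: bg.occurrence(n).min_atom))
    return order


def _walk_path(g: nx.MultiGraph, start: int) -> list[int]:
    order = [start]
    prev = None
    cur = start
    while True:
        step = [n for n in g.neighbors(cur) if n != prev]
        if not step:
            return order
        prev, cur = cur, step[0]
        order.append(cur)


def order_blocks(bg: BlockGraph,
                 acronym_of: dict[int, str] | None = None
                 ) -> tuple[list[int], tuple[int, list[int]] | None, bool]:
    """Order occurrences N-terminus -> C-terminus.

    Returns ``(backbone ids, branch, cyclic)`` with ``branch`` as
    ``(attachment index on backbone, branch ids ordered outward)``.
    Where the chain has no unique N->C direction (two N-termini, rings)
    the occurrence containing the lowest parent atom index starts — a
    documented convention, not chemistry.  For multiply branched graphs a
    deterministic DFS order is returned with no branch split.
    """
    acronym_of = acronym_of or {}
    g = bg.to_networkx()
    nodes = list(g.nodes)
    if len(nodes) == 1:
        return [nodes[0]], None, g.number_of_edges() > 0
    donors = {(e.donor, e.acceptor) for e in bg.edges}
    cyclic = g.number_of_edges() >= g.number_of_nodes()
    branch_nodes = [n for n, d in g.degree() if d > 2]

    if not branch_nodes and not cyclic:
        ends = [n for n, d in g.degree() if d <= 1]
        starts = [e for e in ends
                  if any((e, n) in donors for n in g.neighbors(e))]
        if len(starts) == 1:
            start = starts[0]
        else:  # both ends amine-like or both acyl-like: convention
            start = min(ends, key=lambda n: bg.occurrence(n).min_atom)
        return _walk_path(g, start), None, False

    if not branch_nodes and cyclic:
        return _ring_rotation(bg, g), None, True

    if len(branch_nodes) == 1 and g.degree(branch_nodes[0]) == 3:
        b = branch_nodes[0]
        if cyclic:
            ring = _ring_rotation(bg, g)
            ring_set = set(ring)
            if b in ring_set:
                pend = [n for n in g.neighbors(b) if n not in ring_set]
                if len(pend) == 1:
                    sub = g.subgraph(n for n in nodes if n not in ring_set
                                     or n == b).copy()
                    branch_ids = _walk_path(sub, b)[1:]  # outward from b
                    return ring, (ring.index(b), branch_ids), True
            # pendant-ring arrangements the notation cannot hold
            order = list(nx.dfs_preorder_nodes(
                g, min(nodes, key=lambda n: bg.occurrence(n).min_atom)))
            return order, None, True
        # acyclic, single degree-3 node: backbone = longest path through b
        arms = []
        for nb in g.neighbors(b):
            sub = g.copy()
            others = [x for x in g.neighbors(b) if x != nb]
            for o in others:
                while sub.has_edge(b, o):
                    sub.remove_edge(b, o)
            arm = _walk_path(sub, b)[1:]
            arms.append(arm)
        best = None
        for i in range(len(arms)):
            for j in range(len(arms)):
                if i == j:
                    continue
                backbone = list(reversed(arms[i])) + [b] + arms[j]
                n_to_c = (backbone[0], backbone[1]) in donors
                key = (-len(backbone), not n_to_c,
                       tuple(acronym_of.get(n, str(n)) for n in backbone),
                       tuple(backbone))
                if best is None or key < best[0]:
                    rest = [k for k in range(len(arms)) if k not in (i, j)][0]
                    best = (key, backbone, arms[rest])
        assert best is not None
        _, backbone, branch_arm = best
        return backbone, (backbone.index(b), branch_arm), False

    # multiply branched: deterministic DFS order, no representable branch
    start = min(nodes, key=lambda n: bg.occurrence(n).min_atom)
    return list(nx.dfs_preorder_nodes(g, start)), None, cyclic


# --------------------------------------------------------------------------
# orchestration


@dataclass
class DecompositionResult:
    sequence: BlockSequence
    blocks: list[BuildingBlock]
    graph: BlockGraph
    parent_formula: Formula
    annotation: BondAnnotation

    @property
    def type(self) -> SequenceType:
        return self.sequence.type


def _synthesize_acronym(name: str | None, index: int, taken: set[str]) -> str:
    base = name[:3].capitalize() if name else f"B{index + 1}"
    acr = base
    suffix = 2
    while acr in taken:
        acr = f"{base}{suffix}"
        suffix += 1
    return acr


def decompose(smiles: str, container=None, finder=None,
              include_esters: bool = True,
              toggles: tuple[int, ...] = ()) -> DecompositionResult:
    """Full pipeline: parse, annotate, split, cap, order, classify.

    ``container`` (optional) supplies known blocks matched by canonical
    generic SMILES; ``finder`` (optional) is queried for blocks the
    container does not know.  ``toggles`` are bond indices flipped after
    automatic annotation, mirroring the interactive break-point editing.
    """
    graph = parse_smiles(smiles)
    ann = find_cleavable_bonds(graph, include_esters=include_esters)
    for t in toggles:
        ann = toggle_bond(ann, graph, t)
    bg = split_blocks(graph, ann)

    # deduplicate by structure, discovery order = first occurrence
    distinct: dict[str, int] = {}
    for occ in bg.occurrences:
        if occ.smiles not in distinct:
            distinct[occ.smiles] = len(distinct)
        occ.block_index = distinct[occ.smiles]

    from .finders import resolve_block_metadata

    taken: set[str] = set()
    if container is not None:
        taken |= {b.acronym for b in container.blocks}
    blocks: list[BuildingBlock] = []
    for smi, bi in distinct.items():
        occ = next(o for o in bg.occurrences if o.block_index == bi)
        resolved = resolve_block_metadata(smi, container, finder)
        if resolved.acronym:
            acronym = resolved.acronym
        else:
            acronym = _synthesize_acronym(resolved.name, bi, taken)
        taken.add(acronym)
        blocks.append(BuildingBlock(
            acronym=acronym, name=resolved.name or "",
            residue_formula=occ.residue_formula, smiles=smi,
            n_termini=occ.n_termini, c_termini=occ.c_termini,
            losses=list(resolved.losses), references=list(resolved.references)))

    acr_of = {o.id: blocks[o.block_index].acronym for o in bg.occurrences}
    backbone_ids, branch, cyclic = order_blocks(bg, acr_of)
    stype = classify(bg)
    seq = BlockSequence(
        backbone=[acr_of[i] for i in backbone_ids],
        branch=(branch[0], [acr_of[i] for i in branch[1]]) if branch else None,
        cyclic=cyclic, type=stype)
    return DecompositionResult(sequence=seq, blocks=blocks, graph=bg,
                               parent_formula=formula_of(graph),
                               annotation=ann)
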
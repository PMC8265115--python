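"""Condense monomers into peptide/polyketide test molecules.

The generator is the package's independent oracle: a molecule assembled
from known blocks with known topology must decompose back into exactly
those blocks.  Each linkage is a condensation — the donor's carboxyl
loses its hydroxyl, the acceptor's amine (amide) or hydroxyl (ester)
loses a hydrogen, and an acyl C-N or C-O single bond is formed.

Linkage sites default to the backbone alpha-amine and the first carboxyl;
side-chain linkages (e.g. the ornithine delta-amine carrying the branch
of pseudacyclins) are named explicitly by atom index in the block's own
SMILES.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from rdkit import Chem

from .chem import SmilesError

__all__ = ["Link", "AssemblySpec", "AssemblyError", "assemble",
           "linear_peptide", "cyclic_peptide", "random_assembly_specs"]

_CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
_AMINE = Chem.MolFromSmarts("[NX3;H2,H1;!$([N]C=[OX1]);!$([N]C=[NX2])]")
_ALPHA_AMINE = Chem.MolFromSmarts(
    "[NX3;H2,H1;!$([N]C=[OX1])][CX4][CX3](=[OX1])[OX2H1]")
_HYDROXYL = Chem.MolFromSmarts("[OX2H1][CX4]")


class AssemblyError(ValueError):
    """Incompatible or exhausted linkage sites."""


@dataclass(frozen=True)
class Link:
    """One condensation: block *donor* provides the acyl (C) side."""

    donor: int
    acceptor: int
    kind: str = "amide"  # amide | ester
    donor_site: int | None = None     # acyl carbon index in the donor SMILES
    acceptor_site: int | None = None  # N (amide) or O (ester) index


@dataclass
class AssemblySpec:
    """Blocks (SMILES) plus the linkages to condense."""

    blocks: list[str]
    links: list[Link] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"blocks": self.blocks, "links": [asdict(l) for l in self.links]},
            indent=2)

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "AssemblySpec":
        p = Path(str(text_or_path))
        text = p.read_text(encoding="utf-8") if p.is_file() else str(text_or_path)
        data = json.loads(text)
        return cls(blocks=list(data["blocks"]),
                   links=[Link(**l) for l in data.get("links", [])])


def linear_peptide(blocks: list[str], kinds: list[str] | None = None
                   ) -> AssemblySpec:
    """Head-to-tail chain: block i donates its acyl group to block i+1."""
    kinds = kinds or ["amide"] * (len(blocks) - 1)
    links = [Link(i, i + 1, kinds[i]) for i in range(len(blocks) - 1)]
    return AssemblySpec(blocks=list(blocks), links=links)


def cyclic_peptide(blocks: list[str], kinds: list[str] | None = None
                   ) -> AssemblySpec:
    """Head-to-tail ring: like :func:`linear_peptide` plus last->first."""
    n = len(blocks)
    kinds = kinds or ["amide"] * n
    links = [Link(i, (i + 1) % n, kinds[i]) for i in range(n)]
    return AssemblySpec(blocks=list(blocks), links=links)


def _carboxyl_sites(mol: Chem.Mol) -> list[tuple[int, int]]:
    """(acyl carbon, hydroxyl oxygen) pairs, in atom-index order."""
    return sorted((c, o) for c, _od, o in mol.GetSubstructMatches(_CARBOXYL))


def _amine_sites(mol: Chem.Mol) -> list[int]:
    """Free amine nitrogens, backbone alpha-amines first."""
    alpha = {m[0] for m in mol.GetSubstructMatches(_ALPHA_AMINE)}
    all_n = sorted({m[0] for m in mol.GetSubstructMatches(_AMINE)})
    return sorted(all_n, key=lambda i: (i not in alpha, i))


def _hydroxyl_sites(mol: Chem.Mol) -> list[int]:
    """Alcohol oxygens (carboxyl OH excluded by the [CX4] neighbour)."""
    return sorted({m[0] for m in mol.GetSubstructMatches(_HYDROXYL)})


def assemble(spec: AssemblySpec) -> str:
    """Condense the spec into a single neutral molecule; returns SMILES."""
    mols = []
    for smi in spec.blocks:
        m = Chem.MolFromSmiles(smi)
        if m is None:
            raise SmilesError(smi, "cannot parse assembly block")
        mols.append(m)

    offsets = []
    total = 0
    combined = None
    for m in mols:
        offsets.append(total)
        total += m.GetNumAtoms()
        combined = m if combined is None else Chem.CombineMols(combined, m)
    rw = Chem.RWMol(combined)

    used_donor: dict[int, set[int]] = {i: set() for i in range(len(mols))}
    used_acceptor: dict[int, set[int]] = {i: set() for i in range(len(mols))}
    new_bonds: list[tuple[int, int]] = []
    doomed_oxygens: list[int] = []

    for link in spec.links:
        if link.kind not in ("amide", "ester"):
            raise AssemblyError(f"unknown linkage kind {link.kind!r}")
        dmol, amol = mols[link.donor], mols[link.acceptor]

        # donor acyl carbon + the hydroxyl oxygen to eliminate
        sites = _carboxyl_sites(dmol)
        if link.donor_site is not None:
            sites = [s for s in sites if s[0] == link.donor_site]
            if not sites:
                raise AssemblyError(
                    f"block {link.donor}: atom {link.donor_site} is not a "
                    "carboxyl carbon")
        sites = [s for s in sites if s[0] not in used_donor[link.donor]]
        if not sites:
            raise AssemblyError(
                f"block {link.donor} has no unused carboxyl site")
        acyl_c, oh_o = sites[0]
        used_donor[link.donor].add(acyl_c)

        # acceptor nitrogen or oxygen
        if link.kind == "amide":
            cand = _amine_sites(amol)
            wanted = "amine nitrogen"
        else:
            cand = _hydroxyl_sites(amol)
            wanted = "hydroxyl oxygen"
        if link.acceptor_site is not None:
            sym = amol.GetAtomWithIdx(link.acceptor_site).GetSymbol()
            ok = "N" if link.kind == "amide" else "O"
            if sym != ok:
                raise AssemblyError(
                    f"block {link.acceptor}: atom {link.acceptor_site} is "
                    f"{sym}, expected {wanted}")
            cand = [link.acceptor_site]
        cand = [a for a in cand if a not in used_acceptor[link.acceptor]]
        if not cand:
            raise AssemblyError(
                f"block {link.acceptor} has no unused {wanted}")
        acc = cand[0]
        used_acceptor[link.acceptor].add(acc)

        new_bonds.append((offsets[link.donor] + acyl_c,
                          offsets[link.acceptor] + acc))
        doomed_oxygens.append(offsets[link.donor] + oh_o)

    for a, b in new_bonds:
        rw.AddBond(a, b, Chem.BondType.SINGLE)
        acc_atom = rw.GetAtomWithIdx(b)
        if acc_atom.GetNoImplicit() and acc_atom.GetNumExplicitHs() > 0:
            acc_atom.SetNumExplicitHs(acc_atom.GetNumExplicitHs() - 1)
    for o_idx in sorted(doomed_oxygens, reverse=True):
        rw.RemoveAtom(o_idx)

    try:
        Chem.SanitizeMol(rw)
    except Exception as exc:
        raise AssemblyError(f"condensation produced an invalid molecule: "
                            f"{exc}") from exc
    return Chem.MolToSmiles(rw)


def random_assembly_specs(seed: int, n_specs: int, min_blocks: int = 2,
                          max_blocks: int = 10
                          ) -> list[tuple[str, AssemblySpec]]:
    """Randomized linear/cyclic/branched specs over the standard monomers.

    The oracle pool is the twenty proteinogenic amino acids plus ornithine
    and putrescine; putrescine only ever terminates a linear chain (it
    accepts two acyl groups but donates none).  Branched specs hang one
    residue off a lysine/ornithine side-chain amine at an interior
    position, so the block graph genuinely gains a degree-3 node.
    Returns ``(intended topology, spec)`` pairs; decomposing the
    assembled molecule must recover exactly the input blocks and a type
    consistent with the intended topology.
    """
    import random

    from .residues import AMINO_ACIDS, EXTRA_MONOMERS

    rng = random.Random(seed)
    aa_pool = [smi for _name, smi in AMINO_ACIDS.values()]
    put = EXTRA_MONOMERS["Put"][1]
    side_amine_donors = [AMINO_ACIDS["Lys"][1], EXTRA_MONOMERS["Orn"][1]]

    specs: list[tuple[str, AssemblySpec]] = []
    for _ in range(n_specs):
        n = rng.randint(min_blocks, max_blocks)
        topology = rng.choice(["linear", "linear", "cyclic", "branched"])
        if topology == "linear":
            blocks = [rng.choice(aa_pool) for _ in range(n)]
            if rng.random() < 0.3:
                blocks[-1] = put
            specs.append(("linear", linear_peptide(blocks)))
        elif topology == "cyclic":
            n = max(n, 3)
            blocks = [rng.choice(aa_pool) for _ in range(n)]
            specs.append(("cyclic", cyclic_peptide(blocks)))
        else:
            n = max(n, 4)
            backbone = [rng.choice(aa_pool) for _ in range(n - 1)]
            attach = rng.randrange(1, len(backbone) - 1)
            backbone[attach] = rng.choice(side_amine_donors)
            blocks = backbone + [rng.choice(aa_pool)]
            links = [Link(i, i + 1) for i in range(len(backbone) - 1)]
            # the side-chain amine is atom 0 in both Lys and Orn SMILES
            links.append(Link(len(backbone), attach, acceptor_site=0))
            specs.append(("branched", AssemblySpec(blocks, links)))
    return specs
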
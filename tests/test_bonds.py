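"""Amide/ester bond perception, the small-fragment skip rule, toggling."""

import random

import pytest
from rdkit import Chem

from nrpblocks.bonds import find_cleavable_bonds, toggle_bond
from nrpblocks.chem import parse_smiles

AMIDE = Chem.MolFromSmarts("[CX3](=[OX1])-[NX3]")
ESTER = Chem.MolFromSmarts("[CX3](=[OX1])-[OX2]-[#6]")


def brute_force_amides(mol):
    """Independent oracle: every C-N single bond with a C=O on the carbon."""
    out = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        for c, n in ((a, b), (b, a)):
            if c.GetSymbol() != "C" or n.GetSymbol() != "N":
                continue
            if n.GetIsAromatic():
                continue
            has_carbonyl = any(
                nb.GetSymbol() == "O" and
                mol.GetBondBetweenAtoms(c.GetIdx(), nb.GetIdx()).GetBondType()
                == Chem.BondType.DOUBLE
                for nb in c.GetNeighbors())
            if has_carbonyl:
                out.add(bond.GetIdx())
    return out


def test_glycylglycine_has_one_cleavable_bond(glycylglycine):
    g = parse_smiles(glycylglycine)
    ann = find_cleavable_bonds(g)
    assert len(ann.cleavable) == 1
    assert all(p == "auto" for p in ann.provenance.values())


def test_free_glycine_has_none():
    ann = find_cleavable_bonds(parse_smiles("NCC(=O)O"))
    assert ann.cleavable == set()


def test_pseudacyclin_a_six_bonds_and_acetyl_skip(pseudacyclin_a):
    """Six amides are marked; the acetyl amide is excluded because the
    acetyl fragment would have only three heavy atoms."""
    g = parse_smiles(pseudacyclin_a)
    ann = find_cleavable_bonds(g)
    assert len(ann.cleavable) == 6
    # the skipped acetyl amide exists in the molecule but not in the set
    amides = brute_force_amides(g.mol)
    skipped = amides - ann.cleavable
    assert len(skipped) == 1


def test_depsipeptide_ester_flag(depsipeptide):
    g = parse_smiles(depsipeptide)
    with_esters = find_cleavable_bonds(g, include_esters=True)
    without = find_cleavable_bonds(g, include_esters=False)
    ester_bonds = {k for k, r in with_esters.roles.items() if r.kind == "ester"}
    assert len(ester_bonds) == 1
    assert with_esters.cleavable - without.cleavable == ester_bonds
    assert len(without.cleavable) == 4  # the four amides


def test_every_auto_bond_rematches_its_pattern(pseudacyclin_a, depsipeptide):
    for smi in (pseudacyclin_a, depsipeptide):
        g = parse_smiles(smi)
        ann = find_cleavable_bonds(g)
        amides = brute_force_amides(g.mol)
        esters = {g.mol.GetBondBetweenAtoms(m[0], m[2]).GetIdx()
                  for m in g.mol.GetSubstructMatches(ESTER)}
        assert ann.cleavable <= amides | esters


def test_skip_rule_is_symmetric_min_fragment():
    """N-acetyl on a dipeptide: acetyl side has 3 heavy atoms -> skipped,
    regardless of which side of the bond is smaller."""
    # Ac-Gly-Gly: acetyl amide must be skipped, peptide bond kept
    g = parse_smiles("CC(=O)NCC(=O)NCC(=O)O")
    ann = find_cleavable_bonds(g)
    assert len(ann.cleavable) == 1
    role = next(iter(ann.roles.values()))
    # the kept bond is the internal Gly-Gly amide
    assert g.mol.GetAtomWithIdx(role.hetero_atom).GetSymbol() == "N"


def test_toggle_is_an_involution(glycylglycine):
    g = parse_smiles(glycylglycine)
    ann = find_cleavable_bonds(g)
    idx = next(iter(ann.cleavable))
    twice = toggle_bond(toggle_bond(ann, g, idx), g, idx)
    assert twice.cleavable == ann.cleavable


def test_toggle_off_records_manual_removed(glycylglycine):
    g = parse_smiles(glycylglycine)
    ann = find_cleavable_bonds(g)
    idx = next(iter(ann.cleavable))
    off = toggle_bond(ann, g, idx)
    assert idx not in off.cleavable
    assert off.provenance[idx] == "manual-removed"


def test_toggle_skipped_acetyl_gives_seven(pseudacyclin_a):
    g = parse_smiles(pseudacyclin_a)
    ann = find_cleavable_bonds(g)
    skipped = brute_force_amides(g.mol) - ann.cleavable
    (acetyl_bond,) = skipped
    on = toggle_bond(ann, g, acetyl_bond)
    assert len(on.cleavable) == 7
    assert on.provenance[acetyl_bond] == "manual-added"


def test_toggle_unknown_index_raises(glycylglycine):
    g = parse_smiles(glycylglycine)
    ann = find_cleavable_bonds(g)
    with pytest.raises(IndexError):
        toggle_bond(ann, g, 999)


def test_annotation_invariant_under_atom_reordering(pseudacyclin_a):
    """The set of annotated bonds is a property of the molecule: compare
    via canonical (sorted) endpoint-pair sets after renumbering."""
    rng = random.Random(7)
    mol = Chem.MolFromSmiles(pseudacyclin_a)

    def bond_keys(graph, ann):
        ranks = list(Chem.CanonicalRankAtoms(graph.mol))
        keys = set()
        for bidx in ann.cleavable:
            b = graph.mol.GetBondWithIdx(bidx)
            keys.add(frozenset((ranks[b.GetBeginAtomIdx()],
                                ranks[b.GetEndAtomIdx()])))
        return keys

    g0 = parse_smiles(pseudacyclin_a)
    want = bond_keys(g0, find_cleavable_bonds(g0))
    for _ in range(5):
        perm = list(range(mol.GetNumAtoms()))
        rng.shuffle(perm)
        s = Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False)
        g = parse_smiles(s)
        assert bond_keys(g, find_cleavable_bonds(g)) == want
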
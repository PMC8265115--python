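"""Standard monomer structures used as fixtures and local databases.

The twenty proteinogenic amino acids plus the non-proteinogenic monomers
of the showcase siderophores: ornithine (Orn), putrescine (Put),
N-hydroxy-1,5-pentanediamine (Hpd, assembled from succinyl units in
desferrioxamines) and the succinyl unit itself (Suc, supplied for
assembly as succinic acid).  SMILES carry L-stereochemistry where
applicable; block identity strips it anyway.
"""

from __future__ import annotations

from .chem import canonical_generic_smiles, formula_of, parse_smiles
from .decompose import BuildingBlock
from .formula import WATER

__all__ = [
    "AMINO_ACIDS",
    "EXTRA_MONOMERS",
    "proteinogenic_blocks",
    "proteinogenic_container",
]

#: acronym -> (full name, monomer SMILES)
AMINO_ACIDS: dict[str, tuple[str, str]] = {
    "Ala": ("alanine", "C[C@@H](N)C(=O)O"),
    "Arg": ("arginine", "N=C(N)NCCC[C@H](N)C(=O)O"),
    "Asn": ("asparagine", "NC(=O)C[C@H](N)C(=O)O"),
    "Asp": ("aspartic acid", "OC(=O)C[C@H](N)C(=O)O"),
    "Cys": ("cysteine", "N[C@@H](CS)C(=O)O"),
    "Gln": ("glutamine", "NC(=O)CC[C@H](N)C(=O)O"),
    "Glu": ("glutamic acid", "OC(=O)CC[C@H](N)C(=O)O"),
    "Gly": ("glycine", "NCC(=O)O"),
    "His": ("histidine", "N[C@@H](Cc1c[nH]cn1)C(=O)O"),
    "Ile": ("isoleucine", "CC[C@H](C)[C@@H](N)C(=O)O"),
    "Leu": ("leucine", "CC(C)C[C@@H](N)C(=O)O"),
    "Lys": ("lysine", "NCCCC[C@@H](N)C(=O)O"),
    "Met": ("methionine", "CSCC[C@@H](N)C(=O)O"),
    "Phe": ("phenylalanine", "N[C@@H](Cc1ccccc1)C(=O)O"),
    "Pro": ("proline", "OC(=O)[C@@H]1CCCN1"),
    "Ser": ("serine", "N[C@@H](CO)C(=O)O"),
    "Thr": ("threonine", "C[C@@H](O)[C@H](N)C(=O)O"),
    "Trp": ("tryptophan", "N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O"),
    "Tyr": ("tyrosine", "N[C@@H](Cc1ccc(O)cc1)C(=O)O"),
    "Val": ("valine", "CC(C)[C@@H](N)C(=O)O"),
}

#: non-proteinogenic monomers of the showcase molecules.
#: value = (name, monomer SMILES for assembly, SMILES of the decomposed
#: block when it differs from the monomer — Suc condenses both carboxyls
#: and is capped back with a single hydroxyl).
EXTRA_MONOMERS: dict[str, tuple[str, str, str | None]] = {
    "Orn": ("ornithine", "NCCC[C@@H](N)C(=O)O", None),
    "Put": ("putrescine", "NCCCCN", None),
    "Hpd": ("N-hydroxy-1,5-pentanediamine", "ONCCCCCN", None),
    "Suc": ("succinic acid", "OC(=O)CCC(=O)O", "O=CCCC(=O)O"),
    "Ac-Ile": ("N-acetyl-isoleucine", "CC[C@H](C)[C@@H](NC(C)=O)C(=O)O", None),
    "Lac": ("lactic acid", "C[C@H](O)C(=O)O", None),
}


def _amino_acid_block(acronym: str, name: str, smiles: str) -> BuildingBlock:
    molecular = formula_of(parse_smiles(smiles))
    return BuildingBlock(
        acronym=acronym, name=name,
        residue_formula=molecular - WATER,
        smiles=canonical_generic_smiles(smiles),
        n_termini=1, c_termini=1)


def proteinogenic_blocks() -> list[BuildingBlock]:
    """The twenty basic building blocks with residue formulas (AA - H2O)."""
    return [_amino_acid_block(acr, name, smi)
            for acr, (name, smi) in AMINO_ACIDS.items()]


def proteinogenic_container():
    """A fresh 'Proteinogenic Amino Acids' container (20 blocks)."""
    from .database import Container

    return Container(name="Proteinogenic Amino Acids",
                     blocks=proteinogenic_blocks())
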
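"""Shared fixtures: showcase molecules assembled from standard monomers."""

from __future__ import annotations

import pytest

from nrpblocks.assemble import AssemblySpec, Link, assemble, linear_peptide
from nrpblocks.residues import AMINO_ACIDS, EXTRA_MONOMERS

AA = {k: v[1] for k, v in AMINO_ACIDS.items()}
EX = {k: v[1] for k, v in EXTRA_MONOMERS.items()}

# Hpd monomer "ONCCCCCN": atom 1 = N-hydroxy nitrogen, atom 7 = primary amine
HPD_N_HYDROXY = 1
HPD_PRIMARY_N = 7
# Orn monomer "NCCC[C@@H](N)C(=O)O": atom 0 = delta amine, atom 5 = alpha amine
ORN_DELTA_N = 0


def pseudacyclin_a_spec() -> AssemblySpec:
    """cyclo(Pro-Ile-Ile-Orn-Phe) with Ac-Ile amide-bonded to the
    ornithine delta-amine."""
    blocks = [AA["Pro"], AA["Ile"], AA["Ile"], EX["Orn"], AA["Phe"],
              EX["Ac-Ile"]]
    links = [Link(0, 1), Link(1, 2), Link(2, 3), Link(3, 4), Link(4, 0),
             Link(5, 3, acceptor_site=ORN_DELTA_N)]
    return AssemblySpec(blocks, links)


def pseudacyclin_b_spec() -> AssemblySpec:
    """Pseudacyclin A with one isoleucine substituted by valine."""
    blocks = [AA["Pro"], AA["Ile"], AA["Val"], EX["Orn"], AA["Phe"],
              EX["Ac-Ile"]]
    links = [Link(0, 1), Link(1, 2), Link(2, 3), Link(3, 4), Link(4, 0),
             Link(5, 3, acceptor_site=ORN_DELTA_N)]
    return AssemblySpec(blocks, links)


def desferrioxamine_b_scaffold_spec() -> AssemblySpec:
    """The Hpd-Suc-Hpd-Suc-Hpd chain of desferrioxamine B (the terminal
    acetyl is modelled as an N-terminal modification, not a block)."""
    blocks = [EX["Hpd"], EX["Suc"], EX["Hpd"], EX["Suc"], EX["Hpd"]]
    links = [Link(1, 0, acceptor_site=HPD_N_HYDROXY),
             Link(1, 2, acceptor_site=HPD_PRIMARY_N),
             Link(3, 2, acceptor_site=HPD_N_HYDROXY),
             Link(3, 4, acceptor_site=HPD_PRIMARY_N)]
    return AssemblySpec(blocks, links)


def desferrioxamine_b_spec() -> AssemblySpec:
    """Full desferrioxamine B: the scaffold plus the terminal acetyl
    (acetic acid condensed onto the last free N-hydroxy amine)."""
    spec = desferrioxamine_b_scaffold_spec()
    blocks = spec.blocks + ["CC(=O)O"]
    links = spec.links + [Link(5, 4, acceptor_site=HPD_N_HYDROXY)]
    return AssemblySpec(blocks, links)


def ornibactin_like_spec() -> AssemblySpec:
    """A linear chain ending in C-terminally attached putrescine."""
    blocks = [AA["Ser"], EX["Orn"], AA["Ser"], EX["Put"]]
    links = [Link(0, 1), Link(1, 2), Link(2, 3)]
    return AssemblySpec(blocks, links)


def depsipeptide_spec() -> AssemblySpec:
    """Synthetic cyclic depsipeptide (stand-in for the roseotoxin-class
    molecules): four amide links and one ester link through lactic acid."""
    blocks = [AA["Pro"], AA["Ile"], EX["Lac"], AA["Ala"], AA["Phe"]]
    links = [Link(0, 1), Link(1, 2, kind="ester"), Link(2, 3), Link(3, 4),
             Link(4, 0)]
    return AssemblySpec(blocks, links)


@pytest.fixture(scope="session")
def pseudacyclin_a() -> str:
    return assemble(pseudacyclin_a_spec())


@pytest.fixture(scope="session")
def pseudacyclin_b() -> str:
    return assemble(pseudacyclin_b_spec())


@pytest.fixture(scope="session")
def desferrioxamine_b_scaffold() -> str:
    return assemble(desferrioxamine_b_scaffold_spec())


@pytest.fixture(scope="session")
def desferrioxamine_b() -> str:
    return assemble(desferrioxamine_b_spec())


@pytest.fixture(scope="session")
def ornibactin_like() -> str:
    return assemble(ornibactin_like_spec())


@pytest.fixture(scope="session")
def depsipeptide() -> str:
    return assemble(depsipeptide_spec())


@pytest.fixture(scope="session")
def glycylglycine() -> str:
    return assemble(linear_peptide([AA["Gly"], AA["Gly"]]))


# randomized assembly specs for round-trip properties live in the package
from nrpblocks.assemble import random_assembly_specs as random_specs  # noqa: E402,F401
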
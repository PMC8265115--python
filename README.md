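# nrpblocks

Decompose nonribosomal peptides (NRPs) and polyketides (PKs) into their
building blocks, and build the block/sequence/modification databases that
tandem-MS dereplication tools such as CycloBranch consume.

Microbial natural products — antibiotics, immunosuppressants,
siderophores — are assembled enzymatically from monomers that go far
beyond the twenty proteinogenic amino acids, and they frequently form
cyclic and branch-cyclic topologies.  Annotating their tandem mass
spectra requires databases of *residues*: each monomer's formula as it
sits in the chain, not as a free molecule.  Curating those by hand is
slow and error-prone.  `nrpblocks` automates it: given a structure as
SMILES, it

- finds the cleavable peptide (amide) and ester bonds, skipping any cut
  that would strand a fragment of ≤ 3 heavy atoms (so acetyl and similar
  terminal decorations stay on their residue);
- splits the molecule, caps each fragment back to a free monomer
  (cleaved N/O + H; the chain-facing carbonyl + OH → carboxyl), and
  computes residue formulas by water elimination — or by *two-hydrogen*
  elimination for PK blocks that have no C-terminus at all, such as
  putrescine (C4H12N2 → C4H10N2) or the Hpd unit of desferrioxamines
  (C5H14N2O → C5H12N2O);
- orders blocks from N- to C-terminus and classifies the topology as
  linear, cyclic, branched, branch-cyclic, linear-polyketide,
  cyclic-polyketide or other;
- renders/parses the `[A]-[B]-[C]` / `[A]\([B]-[C]\)[D]-[E]` sequence
  notation;
- recommends compound families by Tanimoto similarity over block sets,
  `T(A,B) = |A∩B| / (|A|+|B|−|A∩B|)`;
- reads and writes containers (blocks, sequences, terminal
  modifications) as JSON and as CycloBranch-style tab-separated files,
  with every mass recomputed from its formula;
- assembles test molecules from block sequences (`assemble`), which
  doubles as the round-trip oracle for the decomposition.

## Worked example

Desferrioxamine B's scaffold is a chain of two alternating block types —
Hpd (N-hydroxy-1,5-pentanediamine) and Suc (succinyl) — in which the
amide orientation flips along the chain:

```text
$ nrpblocks decompose "NCCCCCN(O)C(=O)CCC(=O)NCCCCCN(O)C(=O)CCC(=O)NCCCCCNO"
NCCCCCN(O)C(=O)CCC(=O)NCCCCCN(O)C(=O)CCC(=O)NCCCCCNO
  type: linear-polyketide   notation: [B1]-[B2]-[B1]-[B2]-[B1]
  parent: C23H46N6O7  518.342798 Da  (5 occurrences)
  blocks:
          B1  C5H12N2O       116.094963 Da  n/c=2/0  NCCCCCNO
          B2  C4H4O2          84.021129 Da  n/c=0/2  O=CCCC(=O)O
```

Block `B1` (Hpd) is terminated by amine groups on both sides
(`n/c=2/0`): it has no C-terminus, so its residue formula is the
molecular formula minus H2 and the whole chain is typed
`linear-polyketide`.  `B2` (Suc) is cleaved on two acyl sides; it is
capped with a single hydroxyl, giving molecular formula C4H6O3 = residue
C4H4O2 + H2O.  Adding the terminal acetylation (C2H2O, +42.010565 Da) as
an N-terminal modification plus H2 for the two amine chain ends
reconstructs desferrioxamine B's published formula C25H48N6O8
(560.353363 Da).

Passing `--container` resolves blocks against a local database first
(e.g. the bundled twenty proteinogenic amino acids), and `--finder`
consults an offline fixture backend for anything unknown; unmatched
blocks get synthesized acronyms like `B1`.  Other subcommands: `mass`,
`canonicalize [--generic]`, `assemble --spec`, `export`/`import`
(CycloBranch TSV ↔ container JSON) and `recommend --model
tanimoto|text`.

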
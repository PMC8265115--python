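# Methods

`nrpblocks` turns a molecular structure (SMILES) of a nonribosomal peptide
(NRP) or polyketide (PK) into a sequence of building blocks suitable for
tandem-MS database search, and manages those blocks in exportable
containers.  This note records the model, the conventions chosen where the
problem is genuinely underdetermined, and what the test suite does and
does not demonstrate.

## Bond perception and the skip rule

Cleavable bonds are perceived on the sanitized RDKit molecule with SMARTS
patterns:

- **amide**: `[CX3](=[OX1])-[NX3]` — the C–N single bond of any secondary
  or tertiary amide.  Aromatic nitrogens are excluded (aliphatic `N` in
  SMARTS): an amide whose nitrogen sits in an aromatic ring cannot carry a
  chain through it without destroying the ring.  Tertiary (N-methylated)
  amides are cleavable; depsipeptides of the roseotoxin/destruxin class
  contain them and must split.
- **ester** (flag-controlled, on by default): `[CX3](=[OX1])-[OX2]-[#6]`
  — the acyl–oxygen single bond.  Requiring a carbon on the alkoxy side
  excludes free carboxyl groups.

A candidate is dropped when the smaller of the two fragments produced by
its hypothetical cleavage has **three or fewer heavy atoms** (connected
components with the bond removed; a ring bond never disconnects and is
never skipped).  This keeps terminal decorations — acetyl is the
motivating case, three heavy atoms exactly — attached to their residue
instead of becoming blocks.  The rule is applied symmetrically
(min of both sides); for chemically sensible monomers only the decoration
side can be that small.  Manual toggles are authoritative: they bypass
both the pattern match and the skip rule, mirroring the interactive
break-point editing the workflow assumes.

## Capping and the residue-formula calculus

Removing all cleavable bonds leaves one fragment per block occurrence.
Fragments are capped back to free, neutral monomers:

- every cleaved N (amide) or O (ester) regains one hydrogen;
- the **first** cleaved acyl carbon (lowest atom index) regains a
  hydroxyl, converting the chain-facing carbonyl into a carboxyl group;
- any further cleaved acyl carbon is left as a formyl group.

Only one hydroxyl is ever invented per block.  A block cleaved on two
acyl sides — the succinyl unit of desferrioxamines — therefore gets the
molecular formula C4H6O3 (one carboxyl, one formyl), not succinic acid's
C4H6O4: mass spectrometry cannot place a second oxygen, so the convention
adds exactly one water to the residue.

Residue formulas follow the water-elimination convention, with the
two-hydrogen fallback for blocks that have **no C-terminus**:

| terminus profile | residue formula | example |
| --- | --- | --- |
| ≥1 C-terminus | molecular − H2O | Ile: C6H13NO2 → C6H11NO |
| no C-terminus | molecular − H2  | Put: C4H12N2 → C4H10N2; Hpd: C5H14N2O → C5H12N2O |

A C-terminus is a cleaved acyl bond or a free carboxyl; an N-terminus is
a cleaved amide nitrogen or a free, non-acylated amine.  Blocks without a
C-terminus (amine groups on both sides) are what flags the parent as a
polyketide.

**Conservation.**  By construction, summing residue formulas over all
occurrences and adding, per occurrence, H2O (if it has a C-terminus) or
H2 (if not), minus one H per cleaved valence and one O per capped acyl
side, reconstructs the parent formula exactly.  For a plain linear
peptide this reduces to "residues + H + OH"; for a ring, to "residues"
with no end caps.  The test suite asserts the identity, as formula
equality (error 0.0 Da), on every randomized decomposition.

## Ordering, classification, notation

Occurrences and cleaved bonds form the block graph; each edge is directed
from the acyl (C) side to the amine/alkoxy side, i.e. upstream→downstream
in N→C reading.  Classification reads the graph: cycle ⇔
`|edges| ≥ |nodes|` (connected graph), branch ⇔ node of degree > 2; one
branch with a cycle is branch-cyclic; two branch points (or two branches
at one node) are `other`, as is any branched polyketide — the downstream
notation has no types for them.  A lone block is linear (or
linear-polyketide without a C-terminus).

Ordering conventions, chosen once and documented as conventions rather
than chemistry:

- linear chains start at the end that donates its acyl group (the
  N-terminus); when no unique direction exists (two amine ends, as in
  desferrioxamines), the occurrence containing the lowest atom index of
  the input SMILES starts;
- rings are emitted as one rotation starting at the lowest-atom-index
  occurrence, walking in the acyl→amine direction when the start block
  offers one;
- for acyclic branched structures, the backbone is the longest path
  through the branch point; ties prefer the N→C-oriented candidate, then
  the lexicographically smallest acronym sequence.

Notation follows the downstream convention: `[A]-[B]-[C]` for
linear/cyclic (the ring closure is implicit), and
`[A]\([B]-[C]\)[D]-[E]` with the branch parenthesized after its
attachment block.  The published description of the branched format is
ambiguous about whether the attachment block sits inside or before the
parentheses; this package places the branch blocks inside and the
attachment block before, and guarantees parse/render round-trip identity.
Cyclic rotations are compared rotation-insensitively on import.

## Similarity and recommendation

Tanimoto similarity over block *sets* (structures, not acronyms):
`T(A,B) = |A∩B| / (|A|+|B|−|A∩B|)`.  Identity of a block is its
canonical generic SMILES, so renamed monomers still match.  The best
score wins; score ties prefer the stored sequence whose total block count
(repeats included) is closest to the query's, then insertion order.  A
score of zero recommends nothing.  The text model extracts the query name
minus its final whitespace token (so "pseudacyclin B" searches for
"pseudacyclin") and matches case-insensitive substrings; the extraction
rule is a convention reproducing the documented behaviour, since no
formal rule was ever published.

## Containers and I/O

All masses are derived from formulas — a stated mass is checked on import
(tolerance 1e-4 Da) and the formula wins, with a warning.  The
tab-separated dialect (blocks: name, acronym, residue formula, residue
mass, neutral losses, references; sequences: type, name, formula, mass,
notation, N/C/branch modification names, reference; modifications: name,
formula, mass, N|C) covers every documented field, but the exact column
order used by current CycloBranch releases is not published; the layout
is isolated in one reader/writer pair so adapting it is a localized
change.  Formulas render in Hill order (canonical; note ammonia renders
`H3N`).  Export→import→export is byte-identical.

Terminal-modification placement rules: linear — at most one N-terminal
and one C-terminal; cyclic and cyclic-polyketide — none; branched and
branch-cyclic — at most one (either polarity); linear-polyketide — at
most two, same-polarity pairs allowed.  Type `other` accepts none (a
convention: it has no defined attachment points).

## The fixture generator

`assemble()` condenses monomers (−H2O per linkage) into linear, cyclic
and branched molecules; `random_assembly_specs()` draws 2–10 blocks from
the twenty proteinogenic amino acids plus ornithine and putrescine,
putrescine only as a chain terminator and branches always via a
lysine/ornithine side-chain amine at an interior backbone position.  The
showcase fixtures are assembled from their published block sequences:
pseudacyclin A as cyclo(Pro-Ile-Ile-Orn-Phe) with Ac-Ile on the ornithine
δ-amine, the desferrioxamine B scaffold as Hpd-Suc-Hpd-Suc-Hpd.

What the generator does *not* emulate: exotic monomers (chromophores,
fatty-acyl chains), internal modifications (by design these are new
blocks), thioester/glycosidic linkages, charged or multi-component
structures, and real structural noise such as drawing variants from
public databases.  Passing round trips therefore demonstrate internal
consistency of cleavage/capping/ordering on condensation-built molecules,
not coverage of every natural-product topology.

Two fixtures are synthetic stand-ins: the full structures of roseotoxin A
and ornibactin C8 are not reproduced from the literature; a five-residue
cyclic depsipeptide (one lactic-acid ester linkage) stands in for the
roseotoxin class, and an "ornibactin-like" Ser-Orn-Ser-Put chain
exercises the C-terminal putrescine rule.

## Desferrioxamine B and terminal acetylation

The full desferrioxamine B molecule carries a terminal acetyl whose amide
is — correctly — excluded by the skip rule, so fully automatic
decomposition of the complete structure yields an N-acetylated terminal
Hpd block.  The curated representation instead stores the plain
Hpd/Suc blocks and declares acetylation as an N-terminal modification
(C2H2O, +42.010565 Da).  The package follows that representation: the
scaffold decomposes to two block types, and the full molecular formula is
recovered as 3×Hpd + 2×Suc residues + C2H2O + H2 = C25H48N6O8
(monoisotopic 560.353363 Da), which the acceptance script recomputes.

## Numerical choices and problem sizes

Element masses are a single bundled table of most-abundant-isotope masses
(CODATA/AME2020, ≥6 decimals), cross-checked in tests against pyteomics.
Canonicalization delegates to RDKit's canonical SMILES; only determinism
and molecule identity are load-bearing.  No tautomer or protonation
normalization precedes canonicalization.  Decomposition requires a net
charge of zero (zwitterions are fine); multi-component SMILES are
rejected at parse time.

Randomized suites use fixed seeds (hypothesis derandomized); the
acceptance script drives its 100-spec round-trip ensemble from `--seed`.
Problem sizes — 100 random assemblies of 2–10 blocks, 200-case notation
round trips, 300-case Tanimoto oracle comparisons — were chosen as the
point where adding cases stopped changing coverage of the topology/
terminus combinations.
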
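"""Containers: in-memory database with JSON persistence and
CycloBranch-style tab-separated import/export.

A container groups building blocks, sequence records, terminal
modifications, families and organisms; it is the unit users share and the
unit exported to the downstream spectra-annotation software.  Every mass
in a container is derivable from a formula — masses in files are checked
on import and recomputed, never trusted.

The tab-separated column layout is a declared dialect covering every
field the data model names; it is isolated in the reader/writer pair so a
different column order is a one-file change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .classify import SequenceType
from .decompose import BuildingBlock
from .formula import Formula, FormulaError
from .notation import NotationError, parse_notation

__all__ = [
    "TerminalModification",
    "SequenceRecord",
    "Container",
    "DatabaseError",
    "validate_modifications",
    "validate_container",
    "export_cyclobranch",
    "import_cyclobranch",
    "save_container",
    "load_container",
]

SCHEMA_VERSION = 1
MASS_TOLERANCE = 1e-4  # Da; file mass vs recomputed-from-formula


class DatabaseError(ValueError):
    """Container invariant violation or malformed import payload."""


@dataclass
class TerminalModification:
    """A mass/formula delta applied at a chain end (e.g. acetylation)."""

    name: str
    formula: Formula
    nterminal: bool = True  # False => C-terminal

    @property
    def mass(self) -> float:
        return self.formula.monoisotopic_mass


@dataclass
class SequenceRecord:
    """A stored compound: its type, notation, formula and annotations."""

    name: str
    type: SequenceType
    notation: str = ""
    formula: Formula = field(default_factory=Formula)
    families: list[str] = field(default_factory=list)
    organisms: list[str] = field(default_factory=list)
    n_modification: str = ""
    c_modification: str = ""
    branch_modification: str = ""
    reference: tuple[str, str] | None = None
    smiles: str = ""

    @property
    def mass(self) -> float:
        return self.formula.monoisotopic_mass

    def modification_names(self) -> list[str]:
        return [m for m in (self.n_modification, self.c_modification,
                            self.branch_modification) if m]

    def acronyms(self) -> list[str]:
        if not self.notation:
            return []
        return parse_notation(self.notation).acronyms

    def total_blocks(self) -> int:
        return len(self.acronyms())


@dataclass
class Container:
    """A named, shareable collection forming one exportable database."""

    name: str = "container"
    blocks: list[BuildingBlock] = field(default_factory=list)
    sequences: list[SequenceRecord] = field(default_factory=list)
    modifications: list[TerminalModification] = field(default_factory=list)
    families: list[str] = field(default_factory=list)
    organisms: list[str] = field(default_factory=list)
    visibility: str = "private"  # private | public

    def block_by_acronym(self, acronym: str) -> BuildingBlock | None:
        return next((b for b in self.blocks if b.acronym == acronym), None)

    def modification_by_name(self, name: str) -> TerminalModification | None:
        return next((m for m in self.modifications if m.name == name), None)


# --------------------------------------------------------------------------
# modification validity


def validate_modifications(seq_type: SequenceType,
                           mods: list[TerminalModification]) -> list[str]:
    """Check terminal-modification placement rules for *seq_type*.

    Returns a list of human-readable violations (empty = ok): linear
    sequences allow one N-terminal and one C-terminal modification;
    cyclic ones allow none; branched and branch-cyclic allow a single
    branch modification of either polarity; linear polyketides allow two,
    same-polarity pairs included.
    """
    n = sum(1 for m in mods if m.nterminal)
    c = len(mods) - n
    v: list[str] = []
    if seq_type is SequenceType.LINEAR:
        if n > 1:
            v.append(f"linear: at most one N-terminal modification (got {n})")
        if c > 1:
            v.append(f"linear: at most one C-terminal modification (got {c})")
    elif seq_type in (SequenceType.CYCLIC, SequenceType.CYCLIC_POLYKETIDE):
        if mods:
            v.append(f"{seq_type}: no terminal modifications allowed "
                     f"(got {len(mods)})")
    elif seq_type in (SequenceType.BRANCHED, SequenceType.BRANCH_CYCLIC):
        if len(mods) > 1:
            v.append(f"{seq_type}: at most one branch modification "
                     f"(got {len(mods)})")
    elif seq_type is SequenceType.LINEAR_POLYKETIDE:
        if len(mods) > 2:
            v.append(f"linear-polyketide: at most two modifications "
                     f"(got {len(mods)})")
    else:  # OTHER: notation-less; no defined attachment points
        if mods:
            v.append("other: terminal modifications are not supported")
    return v


def validate_container(container: Container) -> list[str]:
    """All container invariants; returns violations (empty = valid)."""
    v: list[str] = []
    seen: set[str] = set()
    for b in container.blocks:
        if not b.acronym:
            v.append(f"block {b.name!r}: empty acronym")
        elif b.acronym in seen:
            v.append(f"duplicate block acronym {b.acronym!r}")
        seen.add(b.acronym)
    for s in container.sequences:
        if s.type is not SequenceType.OTHER:
            try:
                acrs = s.acronyms()
            except NotationError as exc:
                v.append(f"sequence {s.name!r}: bad notation: {exc}")
                continue
            unknown = [a for a in acrs if a not in seen]
            if unknown:
                v.append(f"sequence {s.name!r}: unknown acronyms {unknown}")
        mods = []
        for mn in s.modification_names():
            mod = container.modification_by_name(mn)
            if mod is None:
                v.append(f"sequence {s.name!r}: unknown modification {mn!r}")
            else:
                mods.append(mod)
        v.extend(f"sequence {s.name!r}: {msg}"
                 for msg in validate_modifications(s.type, mods))
    return v


# --------------------------------------------------------------------------
# CycloBranch tab-separated dialect


def _render_refs(refs: list[tuple[str, str]]) -> str:
    return ";".join(f"{db}: {item}" for db, item in refs)


def _parse_refs(cell: str) -> list[tuple[str, str]]:
    out = []
    for part in cell.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise DatabaseError(f"malformed reference {part!r}")
        db, item = part.split(":", 1)
        out.append((db.strip(), item.strip()))
    return out


def _check_cell(value: str, where: str) -> str:
    if "\t" in value or "\n" in value:
        raise DatabaseError(f"{where}: tabs/newlines not allowed in fields")
    return value


def export_cyclobranch(container: Container) -> dict[str, str]:
    """Render the container as three tab-separated text payloads.

    Returns ``{"blocks": ..., "sequences": ..., "modifications": ...}``
    with one row per item, UTF-8/Unix-newline conventions, and empty
    fields as empty strings.  Raises before emitting anything if the
    container violates an invariant.
    """
    violations = validate_container(container)
    if violations:
        raise DatabaseError("container invalid: " + "; ".join(violations))

    block_rows = []
    for b in container.blocks:
        row = [b.name, b.acronym, b.residue_formula.hill(),
               f"{b.residue_mass:.6f}",
               ";".join(l.hill() for l in b.losses),
               _render_refs(b.references)]
        block_rows.append("\t".join(_check_cell(c, f"block {b.acronym}")
                                    for c in row))

    seq_rows = []
    for s in container.sequences:
        row = [s.type.value, s.name, s.formula.hill(), f"{s.mass:.6f}",
               s.notation, s.n_modification, s.c_modification,
               s.branch_modification,
               f"{s.reference[0]}: {s.reference[1]}" if s.reference else ""]
        seq_rows.append("\t".join(_check_cell(c, f"sequence {s.name}")
                                  for c in row))

    mod_rows = []
    for m in container.modifications:
        row = [m.name, m.formula.hill(), f"{m.mass:.6f}",
               "N" if m.nterminal else "C"]
        mod_rows.append("\t".join(_check_cell(c, f"modification {m.name}")
                                  for c in row))

    def payload(rows: list[str]) -> str:
        return "".join(r + "\n" for r in rows)

    return {"blocks": payload(block_rows), "sequences": payload(seq_rows),
            "modifications": payload(mod_rows)}


def _rows(payload: str, ncols: int, what: str):
    for lineno, line in enumerate(payload.splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != ncols:
            raise DatabaseError(
                f"{what} line {lineno}: expected {ncols} tab-separated "
                f"fields, got {len(cells)}")
        yield lineno, cells


def _checked_formula(cell: str, mass_cell: str, what: str, lineno: int,
                     warnings: list[str]) -> Formula:
    try:
        f = Formula.parse(cell)
    except FormulaError as exc:
        raise DatabaseError(f"{what} line {lineno}: {exc}") from exc
    if mass_cell.strip():
        try:
            stated = float(mass_cell)
        except ValueError:
            raise DatabaseError(
                f"{what} line {lineno}: bad mass {mass_cell!r}") from None
        if abs(stated - f.monoisotopic_mass) > MASS_TOLERANCE:
            warnings.append(
                f"{what} line {lineno}: stated mass {stated} differs from "
                f"formula mass {f.monoisotopic_mass:.6f}; formula wins")
    return f


def import_cyclobranch(blocks_payload: str = "", sequences_payload: str = "",
                       modifications_payload: str = "",
                       name: str = "imported",
                       warnings: list[str] | None = None) -> Container:
    """Rebuild a container from the three tab-separated payloads.

    Masses are recomputed from formulas; a stated mass off by more than
    ``MASS_TOLERANCE`` is reported in *warnings* (if given) and the
    formula wins.
    """
    import logging

    log = logging.getLogger(__name__)
    warns: list[str] = [] if warnings is None else warnings

    blocks: list[BuildingBlock] = []
    for lineno, c in _rows(blocks_payload, 6, "blocks"):
        bname, acr, res_f, res_m, losses, refs = c
        f = _checked_formula(res_f, res_m, "blocks", lineno, warns)
        blocks.append(BuildingBlock(
            acronym=acr, name=bname, residue_formula=f, smiles="",
            n_termini=1, c_termini=1,
            losses=[Formula.parse(x) for x in losses.split(";") if x.strip()],
            references=_parse_refs(refs)))

    mods: list[TerminalModification] = []
    for lineno, c in _rows(modifications_payload, 4, "modifications"):
        mname, mf, mm, flag = c
        if flag not in ("N", "C"):
            raise DatabaseError(
                f"modifications line {lineno}: terminus flag must be N or C")
        f = _checked_formula(mf, mm, "modifications", lineno, warns)
        mods.append(TerminalModification(name=mname, formula=f,
                                         nterminal=flag == "N"))

    seqs: list[SequenceRecord] = []
    for lineno, c in _rows(sequences_payload, 9, "sequences"):
        stype, sname, sf, sm, notation, nmod, cmod, bmod, ref = c
        try:
            t = SequenceType(stype)
        except ValueError:
            raise DatabaseError(
                f"sequences line {lineno}: unknown type {stype!r}") from None
        f = _checked_formula(sf, sm, "sequences", lineno, warns)
        refs = _parse_refs(ref)
        seqs.append(SequenceRecord(
            name=sname, type=t, notation=notation, formula=f,
            n_modification=nmod, c_modification=cmod,
            branch_modification=bmod,
            reference=refs[0] if refs else None))

    for w in warns if warnings is None else []:
        log.warning("%s", w)

    container = Container(name=name, blocks=blocks, sequences=seqs,
                          modifications=mods)
    violations = validate_container(container)
    if violations:
        raise DatabaseError("imported container invalid: "
                            + "; ".join(violations))
    return container


# --------------------------------------------------------------------------
# JSON persistence


def _block_to_json(b: BuildingBlock) -> dict:
    return {
        "acronym": b.acronym, "name": b.name,
        "residue_formula": b.residue_formula.hill(),
        "smiles": b.smiles,
        "n_termini": b.n_termini, "c_termini": b.c_termini,
        "losses": [l.hill() for l in b.losses],
        "references": [f"{db}: {item}" for db, item in b.references],
    }


def _seq_to_json(s: SequenceRecord) -> dict:
    return {
        "name": s.name, "type": s.type.value, "notation": s.notation,
        "formula": s.formula.hill(), "families": s.families,
        "organisms": s.organisms,
        "n_modification": s.n_modification,
        "c_modification": s.c_modification,
        "branch_modification": s.branch_modification,
        "reference": (f"{s.reference[0]}: {s.reference[1]}"
                      if s.reference else ""),
        "smiles": s.smiles,
    }


def save_container(container: Container, path: str | Path) -> None:
    """Write the container as deterministic, diff-able JSON."""
    data = {
        "schema_version": SCHEMA_VERSION,
        "name": container.name,
        "visibility": container.visibility,
        "families": container.families,
        "organisms": container.organisms,
        "blocks": [_block_to_json(b) for b in container.blocks],
        "sequences": [_seq_to_json(s) for s in container.sequences],
        "modifications": [
            {"name": m.name, "formula": m.formula.hill(),
             "nterminal": m.nterminal}
            for m in container.modifications],
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


def load_container(path: str | Path) -> Container:
    """Read a container saved by :func:`save_container`."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DatabaseError(
            f"unsupported container schema version {version!r} "
            f"(expected {SCHEMA_VERSION})")
    blocks = [
        BuildingBlock(
            acronym=b["acronym"], name=b["name"],
            residue_formula=Formula.parse(b["residue_formula"]),
            smiles=b.get("smiles", ""),
            n_termini=b.get("n_termini", 1), c_termini=b.get("c_termini", 1),
            losses=[Formula.parse(x) for x in b.get("losses", [])],
            references=_parse_refs(";".join(b.get("references", []))))
        for b in data.get("blocks", [])
    ]
    seqs = []
    for s in data.get("sequences", []):
        refs = _parse_refs(s.get("reference", ""))
        seqs.append(SequenceRecord(
            name=s["name"], type=SequenceType(s["type"]),
            notation=s.get("notation", ""),
            formula=Formula.parse(s.get("formula", "")),
            families=list(s.get("families", [])),
            organisms=list(s.get("organisms", [])),
            n_modification=s.get("n_modification", ""),
            c_modification=s.get("c_modification", ""),
            branch_modification=s.get("branch_modification", ""),
            reference=refs[0] if refs else None,
            smiles=s.get("smiles", "")))
    mods = [TerminalModification(name=m["name"],
                                 formula=Formula.parse(m["formula"]),
                                 nterminal=m["nterminal"])
            for m in data.get("modifications", [])]
    container = Container(
        name=data.get("name", "container"), blocks=blocks, sequences=seqs,
        modifications=mods, families=list(data.get("families", [])),
        organisms=list(data.get("organisms", [])),
        visibility=data.get("visibility", "private"))
    violations = validate_container(container)
    if violations:
        raise DatabaseError("loaded container invalid: "
                            + "; ".join(violations))
    return container
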
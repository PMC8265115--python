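"""Container model: TSV export/import, JSON persistence, validity rules."""

import random

import pytest

from nrpblocks.classify import SequenceType
from nrpblocks.database import (Container, DatabaseError, SequenceRecord,
                                TerminalModification, export_cyclobranch,
                                import_cyclobranch, load_container,
                                save_container, validate_container,
                                validate_modifications)
from nrpblocks.decompose import BuildingBlock
from nrpblocks.formula import Formula
from nrpblocks.residues import proteinogenic_container


def _mod(name, formula, nterm=True):
    return TerminalModification(name=name, formula=Formula.parse(formula),
                                nterminal=nterm)


# --------------------------------------------------------------------------
# modification validity


def test_cyclic_allows_no_modifications():
    v = validate_modifications(SequenceType.CYCLIC, [_mod("Ac", "C2H2O")])
    assert v and "no terminal modifications" in v[0]


def test_linear_allows_one_each_polarity():
    mods = [_mod("Ac", "C2H2O", True), _mod("amide", "HN", False)]
    assert validate_modifications(SequenceType.LINEAR, mods) == []
    assert validate_modifications(SequenceType.LINEAR,
                                  mods + [_mod("x", "CH2", True)])


def test_linear_polyketide_allows_same_polarity_pair():
    mods = [_mod("Ac", "C2H2O", True), _mod("Ac2", "C2H2O", True)]
    assert validate_modifications(SequenceType.LINEAR_POLYKETIDE, mods) == []
    assert validate_modifications(SequenceType.LINEAR_POLYKETIDE,
                                  mods + [_mod("x", "CH2", False)])


def test_branch_cyclic_allows_single_branch_modification():
    assert validate_modifications(SequenceType.BRANCH_CYCLIC,
                                  [_mod("Ac", "C2H2O", False)]) == []
    assert validate_modifications(
        SequenceType.BRANCH_CYCLIC,
        [_mod("a", "C2H2O"), _mod("b", "CH2")])


# --------------------------------------------------------------------------
# TSV export / import


@pytest.fixture
def sample_container():
    c = proteinogenic_container()
    c.modifications.append(_mod("acetylation", "C2H2O", True))
    c.blocks[0].losses = [Formula.parse("H2O"), Formula.parse("NH3")]
    c.blocks[0].references = [("CID", "602")]
    c.sequences.append(SequenceRecord(
        name="glycylglycine", type=SequenceType.LINEAR,
        notation="[Gly]-[Gly]", formula=Formula.parse("C4H8N2O3"),
        families=["test peptides"], n_modification="acetylation",
        reference=("CID", "11163")))
    return c


def test_proteinogenic_export_has_twenty_block_rows(sample_container):
    payloads = export_cyclobranch(sample_container)
    rows = payloads["blocks"].splitlines()
    assert len(rows) == 20
    assert all(len(r.split("\t")) == 6 for r in rows)


def test_block_row_fields(sample_container):
    payloads = export_cyclobranch(sample_container)
    row = payloads["blocks"].splitlines()[0].split("\t")
    assert row[0] == "alanine" and row[1] == "Ala"
    assert row[2] == "C3H5NO"
    assert float(row[3]) == pytest.approx(71.037114, abs=1e-6)
    assert row[4] == "H2O;H3N"  # canonical Hill: ammonia renders H3N
    assert row[5] == "CID: 602"


def test_import_recomputes_masses():
    """Mass comes from the formula, at 6-decimal precision."""
    payload = "glycine\tGly\tC2H3NO\t0.0\t\t\n"
    warnings: list[str] = []
    c = import_cyclobranch(blocks_payload=payload, warnings=warnings)
    assert c.blocks[0].residue_mass == pytest.approx(57.021464, abs=1e-6)
    assert warnings and "formula wins" in warnings[0]


def test_import_losses_cell():
    payload = "glycine\tGly\tC2H3NO\t57.021464\tH2O;NH3\t\n"
    c = import_cyclobranch(blocks_payload=payload)
    assert [l.hill() for l in c.blocks[0].losses] == ["H2O", "H3N"]


def test_import_column_count_error_carries_line_number():
    with pytest.raises(DatabaseError, match="line 2"):
        import_cyclobranch(blocks_payload="a\tA\tC2H3NO\t\t\t\nbad row\n")


def test_import_empty_payloads_give_empty_container():
    c = import_cyclobranch()
    assert (c.blocks, c.sequences, c.modifications) == ([], [], [])


def test_export_import_export_is_byte_identical(sample_container):
    first = export_cyclobranch(sample_container)
    c2 = import_cyclobranch(first["blocks"], first["sequences"],
                            first["modifications"])
    second = export_cyclobranch(c2)
    assert first == second


def test_randomized_tsv_round_trip():
    rng = random.Random(5150)
    blocks = []
    for i in range(30):
        formula = Formula(C=rng.randint(1, 20), H=rng.randint(1, 40),
                          N=rng.randint(0, 5), O=rng.randint(0, 8))
        blocks.append(BuildingBlock(
            acronym=f"X{i}", name=f"block {i}", residue_formula=formula,
            smiles="", n_termini=1, c_termini=1,
            losses=[Formula.parse("H2O")] if rng.random() < 0.5 else [],
            references=[("CID", str(rng.randint(1, 10 ** 6)))]))
    c = Container(name="rand", blocks=blocks)
    p = export_cyclobranch(c)
    c2 = import_cyclobranch(p["blocks"], p["sequences"], p["modifications"],
                            name="rand")
    assert [b.acronym for b in c2.blocks] == [b.acronym for b in blocks]
    assert [b.residue_formula for b in c2.blocks] \
        == [b.residue_formula for b in blocks]
    assert export_cyclobranch(c2) == p


def test_export_refuses_invalid_container():
    c = Container(blocks=[
        BuildingBlock("Dup", "a", Formula(C=1), "", 1, 1),
        BuildingBlock("Dup", "b", Formula(C=2), "", 1, 1),
    ])
    with pytest.raises(DatabaseError, match="duplicate"):
        export_cyclobranch(c)


# --------------------------------------------------------------------------
# JSON persistence


def test_container_json_round_trip(tmp_path, sample_container):
    path = tmp_path / "c.json"
    save_container(sample_container, path)
    loaded = load_container(path)
    assert loaded == sample_container


def test_reference_string_survives_round_trip(tmp_path, sample_container):
    path = tmp_path / "c.json"
    save_container(sample_container, path)
    loaded = load_container(path)
    assert loaded.blocks[0].references == [("CID", "602")]
    assert loaded.sequences[0].reference == ("CID", "11163")


def test_schema_version_mismatch(tmp_path):
    path = tmp_path / "c.json"
    path.write_text('{"schema_version": 99, "name": "x"}')
    with pytest.raises(DatabaseError, match="schema version"):
        load_container(path)


def test_acronym_collision_detected_on_load(tmp_path, sample_container):
    import json

    path = tmp_path / "c.json"
    save_container(sample_container, path)
    data = json.loads(path.read_text())
    data["blocks"][1]["acronym"] = data["blocks"][0]["acronym"]
    path.write_text(json.dumps(data))
    with pytest.raises(DatabaseError, match="duplicate"):
        load_container(path)


def test_validate_container_flags_unknown_acronyms():
    c = Container(sequences=[SequenceRecord(
        name="ghost", type=SequenceType.LINEAR, notation="[Zz]-[Qq]")])
    v = validate_container(c)
    assert v and "unknown acronyms" in v[0]
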
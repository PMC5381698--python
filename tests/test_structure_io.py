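"""Structure parsing, writing and region resolution."""

import numpy as np
import pytest

from quatlock import read_structure, resolve_region, write_structure
from quatlock.structure_io import (
    Atom,
    Assembly,
    Chain,
    RegionDefinition,
    Residue,
    StructureFormatError,
    load_region_definitions,
)
from quatlock.synthetic_data import copy_assembly


def _pdb_atom_line(serial, name, res, chain, seq, x, y, z, occ=1.0, altloc=" "):
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{res:<3s} {chain}{seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           {name[0]}\n"
    )


@pytest.fixture
def two_chain_pdb(tmp_path):
    lines = []
    serial = 0
    for chain in "AB":
        for seq in (1, 2, 3):
            for name, dx in (("N", 0.0), ("CA", 1.5), ("C", 3.0)):
                serial += 1
                lines.append(
                    _pdb_atom_line(serial, name, "ALA", chain, seq, dx, seq * 4.0, 10.0 if chain == "B" else 0.0)
                )
        lines.append("TER\n")
    lines.append("END\n")
    path = tmp_path / "two_chain.pdb"
    path.write_text("".join(lines))
    return path


def test_parse_identity(two_chain_pdb):
    asm = read_structure(two_chain_pdb, fmt="pdb")
    assert asm.chain_ids() == ["A", "B"]
    assert asm.n_atoms() == 18  # one atom per ATOM record
    assert asm.chain("A").residues[0].res_name == "ALA"


def test_altloc_keeps_highest_occupancy(tmp_path):
    lines = [
        _pdb_atom_line(1, "N", "ALA", "A", 1, 0, 0, 0),
        _pdb_atom_line(2, "CA", "ALA", "A", 1, 1.5, 0, 0, occ=0.4, altloc="A"),
        _pdb_atom_line(3, "CA", "ALA", "A", 1, 1.5, 0.5, 0, occ=0.6, altloc="B"),
        _pdb_atom_line(4, "C", "ALA", "A", 1, 3.0, 0, 0),
        "END\n",
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("".join(lines))
    asm = read_structure(path, fmt="pdb")
    res = asm.chain("A").residues[0]
    cas = [a for a in res.atoms if a.name == "CA"]
    assert len(cas) == 1
    assert cas[0].coords[1] == pytest.approx(0.5)  # the 0.6-occupancy conformer

    # occupancy tie -> altloc letter order
    lines[2] = _pdb_atom_line(3, "CA", "ALA", "A", 1, 1.5, 0.5, 0, occ=0.4, altloc="B")
    path.write_text("".join(lines))
    res = read_structure(path, fmt="pdb").chain("A").residues[0]
    assert res.atom("CA").coords[1] == pytest.approx(0.0)  # altloc A wins the tie


def test_hetero_ligand_survives_and_is_flagged(tmp_path, c4_assembly):
    asm = copy_assembly(c4_assembly[0])
    lig = Residue(
        chain_id="A",
        seq_num=900,
        res_name="UDG",
        is_hetero=True,
        atoms=[Atom(serial=9000, name="C1", element="C", coords=np.array([50.0, 0, 0]))],
    )
    asm.chain("A").residues.append(lig)
    path = write_structure(asm, tmp_path / "lig.pdb")
    back = read_structure(path)
    lig_back = back.chain("A").residue(900)
    assert lig_back is not None and lig_back.is_hetero
    assert not lig_back.is_protein  # excluded from protein-only selections
    assert lig_back not in back.chain("A").protein_residues()


def test_unparsable_file_raises_format_error(tmp_path):
    bad = tmp_path / "junk.pdb"
    bad.write_text("this is not : a pdb file at all right??\n" * 3)
    asm_or_exc = None
    try:
        asm_or_exc = read_structure(bad, fmt="pdb")
    except StructureFormatError:
        return
    # gemmi tolerates unknown records; an empty model must still be an error
    assert asm_or_exc is None, "nonsense file should not yield an assembly"


def test_roundtrip_preserves_fields(tmp_path, c4_assembly):
    asm, _ = c4_assembly
    path = write_structure(asm, tmp_path / "rt.pdb")
    back = read_structure(path, fmt="pdb")
    assert back.chain_ids() == asm.chain_ids()
    assert back.n_atoms() == asm.n_atoms()
    for orig_c, back_c in zip(asm.chains, back.chains):
        assert [r.seq_num for r in back_c.residues] == [r.seq_num for r in orig_c.residues]
        for orig_r, back_r in zip(orig_c.residues, back_c.residues):
            for orig_a, back_a in zip(orig_r.atoms, back_r.atoms):
                assert np.abs(orig_a.coords - back_a.coords).max() <= 0.001


def test_roundtrip_idempotent(tmp_path, c4_assembly):
    asm, _ = c4_assembly
    p1 = write_structure(asm, tmp_path / "a.pdb")
    first = read_structure(p1)
    p2 = write_structure(first, tmp_path / "b.pdb")
    second = read_structure(p2)
    assert np.allclose(
        np.array([a.coords for _, _, a in first.all_atoms()]),
        np.array([a.coords for _, _, a in second.all_atoms()]),
    )


def test_mmcif_reading(tmp_path, c4_assembly):
    import gemmi

    asm, _ = c4_assembly
    pdb_path = write_structure(asm, tmp_path / "conv.pdb")
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "conv.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    back = read_structure(cif_path, fmt="mmcif")
    assert back.n_atoms() == asm.n_atoms()
    assert len(back.chains) == len(asm.chains)


def test_write_empty_assembly_errors():
    empty = Assembly(id="x", chains=[Chain(chain_id="A", residues=[])])
    with pytest.raises(ValueError):
        write_structure(empty, "/tmp/never.pdb")


def test_write_out_of_field_coordinate_errors(tmp_path, c4_assembly):
    asm = copy_assembly(c4_assembly[0])
    asm.chains[0].residues[0].atoms[0].coords = np.array([1e5, 0.0, 0.0])
    with pytest.raises(StructureFormatError):
        write_structure(asm, tmp_path / "wide.pdb")


# ---------------------------------------------------------------------------
# Region resolution


def _chain_with_range(start, end):
    residues = [
        Residue(
            chain_id="A",
            seq_num=i,
            res_name="ALA",
            atoms=[Atom(serial=i, name="CA", element="C", coords=np.array([float(i), 0, 0]))],
        )
        for i in range(start, end + 1)
    ]
    return Assembly(id="t", chains=[Chain(chain_id="A", residues=residues)])


def test_region_counts():
    asm = _chain_with_range(280, 300)
    region = RegionDefinition("SB-loop", ((286, 293),))
    sel = resolve_region(asm, region, "A")
    assert len(sel) == 8
    assert not sel.missing_seq_nums


def test_region_isoform_offset():
    # region in long-isoform numbering applied to a short-isoform chain
    asm = _chain_with_range(270, 290)
    region = RegionDefinition("SB-loop", ((286, 293),), numbering_scheme="hUGP1")
    sel = resolve_region(asm, region, "A", offset=11)
    assert [r.seq_num for r in sel] == list(range(275, 283))


def test_region_missing_residues_reported():
    asm = _chain_with_range(350, 370)
    # carve out a disordered stretch
    asm.chains[0].residues = [r for r in asm.chains[0].residues if not 359 <= r.seq_num <= 363]
    region = RegionDefinition("flex-loop", ((357, 365),))
    sel = resolve_region(asm, region, "A")
    assert sel.missing_seq_nums == [359, 360, 361, 362, 363]
    assert len(sel) == 4


def test_region_empty_selection_warns_not_raises():
    asm = _chain_with_range(1, 10)
    region = RegionDefinition("far", ((500, 510),))
    with pytest.warns(UserWarning):
        sel = resolve_region(asm, region, "A")
    assert len(sel) == 0 and sel.warnings


def test_region_offset_linearity():
    # resolving with offset a on a renumbered-by-a chain == offset 0 on the original
    asm = _chain_with_range(10, 40)
    region = RegionDefinition("r", ((15, 20), (30, 33)))
    base = resolve_region(asm, region, "A", offset=0)
    shift = 7
    shifted = _chain_with_range(10 - shift, 40 - shift)
    sel = resolve_region(shifted, region, "A", offset=shift)
    assert [r.seq_num + shift for r in sel] == [r.seq_num for r in base]


def test_region_invariants():
    with pytest.raises(ValueError):
        RegionDefinition("bad", ((10, 5),))
    with pytest.raises(ValueError):
        RegionDefinition("overlap", ((1, 10), (5, 20)))


def test_load_region_definitions(tmp_path):
    cfg = tmp_path / "regions.yaml"
    cfg.write_text(
        "SB-loop:\n  ranges: [[286, 293]]\n  scheme: hUGP1\n"
        "terse: [[1, 10], [20, 30]]\n"
    )
    regions = load_region_definitions(cfg)
    assert regions["SB-loop"].ranges == ((286, 293),)
    assert regions["SB-loop"].numbering_scheme == "hUGP1"
    assert regions["terse"].ranges == ((1, 10), (20, 30))
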
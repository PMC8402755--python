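import numpy as np
import pytest

from polyprot import (
    Atom,
    Residue,
    Selection,
    StructureModel,
    model_sequence,
    read_structure,
    select_atoms,
    write_structure,
)
from polyprot.structure_io import SelectionError, StructureParseError, models_close
from polyprot import synthetic

TEN_ATOM_PDB = """\
HEADER    TOY
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1       1.986  -0.773  -1.206  1.00 10.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      7  CA  GLY A   2       3.984   2.832   0.000  1.00 11.00           C
ATOM      8  C   GLY A   2       5.494   2.696   0.000  1.00 11.00           C
ATOM      9  O   GLY A   2       6.030   1.590   0.000  1.00 11.00           O
HETATM   10 CA    CA X   1      10.000  10.000  10.000  1.00 20.00          CA
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.60 10.00           C
END
"""


@pytest.fixture
def ten_atom_model(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TEN_ATOM_PDB)
    return read_structure(p)


def test_read_preserves_atom_count_and_partition(ten_atom_model):
    """All ATOM/HETATM records survive; polymer and hetero are disjoint."""
    m = ten_atom_model
    assert m.n_atoms() == 10
    assert m.n_polymer_residues() == 2
    assert [(name, a.element) for name, a in m.hetero_sites] == [("CA", "CA")]
    polymer_atoms = sum(len(r.atoms) for r in m.chains["A"])
    assert polymer_atoms + len(m.hetero_sites) == 10


def test_altloc_highest_occupancy_is_primary(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(ALTLOC_PDB)
    m = read_structure(p)
    primaries = [a for a in m.chains["A"][0].atoms if a.is_primary]
    assert len(primaries) == 1
    assert primaries[0].alt_loc == "B"  # occupancy 0.60 wins
    # selections only see the primary conformer
    assert len(select_atoms(m)) == 1


def test_round_trip_preserves_coordinates(tmp_path, helix20, ten_atom_model):
    """write -> read returns an equal model to PDB precision (1e-3 A)."""
    for model in (helix20, ten_atom_model):
        out = tmp_path / f"{model.id}.pdb"
        write_structure(model, out)
        again = read_structure(out)
        assert models_close(model, again, tol=1e-3)


def test_write_empty_model_is_valid(tmp_path):
    out = tmp_path / "empty.pdb"
    write_structure(StructureModel(id="empty"), out)
    text = out.read_text()
    assert text.startswith("HEADER")
    assert "ATOM" not in text


def test_unreadable_and_unknown_format_errors(tmp_path):
    with pytest.raises(StructureParseError):
        read_structure(tmp_path / "missing.pdb")
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure\n")
    with pytest.raises(StructureParseError):
        read_structure(bad, format="mmcif")


def test_selection_ranges_inclusive_and_deterministic(ten_atom_model):
    g = select_atoms(ten_atom_model, "A:1-2")
    assert len(g) == 9
    assert [r.number for _, r, _ in g.refs] == [1] * 5 + [2] * 4
    assert len(select_atoms(ten_atom_model, "A:2-2")) == 4
    # empty selection allowed
    assert len(select_atoms(ten_atom_model, "A:5-9")) == 0


def test_selection_union_of_disjoint_ranges_adds(ten_atom_model):
    """|sel(A) union sel(B)| = |A| + |B| for disjoint ranges (brute force)."""
    a = select_atoms(ten_atom_model, "A:1-1")
    b = select_atoms(ten_atom_model, "A:2-2")
    union = select_atoms(ten_atom_model, "A:1-1,A:2-2")
    assert len(union) == len(a) + len(b)
    ids = {id(atom) for _, _, atom in union}
    assert ids == {id(atom) for _, _, atom in a} | {id(atom) for _, _, atom in b}


def test_malformed_range_rejected():
    sel = Selection.parse("A:9-5")
    with pytest.raises(SelectionError):
        sel.validate()


def test_model_sequence_marks_leading_gaps():
    """Residues 5..9 modeled of a 1..9 construct show as 4 leading gaps."""
    residues = [
        Residue(number=i, name="ALA", atoms=[Atom("CA", "C", np.array([float(i), 0, 0]))])
        for i in range(5, 10)
    ]
    m = StructureModel(id="gap", chains={"A": residues})
    # observed span starts at the first modeled residue
    assert model_sequence(m) == "AAAAA"
    # internal gap
    residues2 = [r for r in residues if r.number != 7]
    m2 = StructureModel(id="gap2", chains={"A": residues2})
    assert model_sequence(m2) == "AA-AA"


def test_model_sequence_gapfree_on_full_helix(helix20):
    assert model_sequence(helix20) == "A" * 20


def test_model_sequence_unknown_chain_raises(helix20):
    with pytest.raises(KeyError):
        model_sequence(helix20, chain="Z")


def test_dimer_write_round_trip_two_chains(tmp_path, helix20):
    dimer = synthetic.make_c2_dimer(helix20, axis=(0, 0, 1), point=(10, 0, 0))
    out = tmp_path / "dimer.pdb"
    write_structure(dimer, out)
    again = read_structure(out)
    assert again.chain_ids == ["A", "B"]
    assert again.n_polymer_residues() == 40
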
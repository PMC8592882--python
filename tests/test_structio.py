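"""Multi-model PDB I/O and the selection mini-language."""

import numpy as np
import pytest

from nacgeo.structio import (
    AtomSelection,
    PDBFormatError,
    SelectionError,
    Trajectory,
    read_pdb,
    select,
    write_pdb,
)


def _pdb_line(serial, name, resname, chain, resid, x, y, z, element, record="ATOM"):
    return (
        f"{record:<6}{serial:>5} {name:<4}{'':1}{resname:<3} {chain}{resid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}\n"
    )


def _write_two_model_file(path):
    lines = []
    for model in (1, 2):
        lines.append(f"MODEL     {model}\n")
        for i in range(3):
            lines.append(_pdb_line(i + 1, "CA", "GLY", "A", i + 1,
                                   float(i + model), 0.0, 0.0, "C"))
        lines.append("ENDMDL\n")
    path.write_text("".join(lines))


class TestReadPdb:
    def test_models_become_frames(self, tmp_path):
        f = tmp_path / "two.pdb"
        _write_two_model_file(f)
        traj = read_pdb(f)
        assert traj.n_frames == 2
        assert traj.n_atoms == 3
        assert traj.coords[0, 0, 0] == pytest.approx(1.0)
        assert traj.coords[1, 0, 0] == pytest.approx(2.0)

    def test_hetatm_retained_and_flagged(self, tmp_path):
        f = tmp_path / "het.pdb"
        f.write_text(
            _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
            + _pdb_line(2, "O", "HOH", "W", 2, 5, 0, 0, "O", record="HETATM")
        )
        traj = read_pdb(f)
        assert traj.n_atoms == 2
        assert list(traj.topology.hetero) == [False, True]

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        f = tmp_path / "alt.pdb"
        line_a = (
            "ATOM      1  CA AGLY A   1       1.000   0.000   0.000  0.30  0.00           C\n"
        )
        line_b = (
            "ATOM      2  CA BGLY A   1       2.000   0.000   0.000  0.70  0.00           C\n"
        )
        f.write_text(line_a + line_b)
        traj = read_pdb(f)
        assert traj.n_atoms == 1
        assert traj.coords[0, 0, 0] == pytest.approx(2.0)  # B has occupancy 0.70

    def test_mismatched_model_sizes_name_the_model(self, tmp_path):
        f = tmp_path / "bad.pdb"
        text = "MODEL     1\n" + _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
        text += "ENDMDL\nMODEL     2\n"
        text += _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
        text += _pdb_line(2, "CB", "GLY", "A", 1, 1, 0, 0, "C")
        text += "ENDMDL\n"
        f.write_text(text)
        with pytest.raises(PDBFormatError, match="MODEL 2"):
            read_pdb(f)

    def test_unparseable_coordinate_reports_line(self, tmp_path):
        f = tmp_path / "badcoord.pdb"
        good = _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0, "C")
        bad = good[:30] + "   xx.xx" + good[38:]
        f.write_text(good + bad)
        with pytest.raises(PDBFormatError, match="line 2"):
            read_pdb(f)

    def test_empty_file_is_an_error(self, tmp_path):
        f = tmp_path / "empty.pdb"
        f.write_text("REMARK nothing here\n")
        with pytest.raises(PDBFormatError, match="no ATOM"):
            read_pdb(f)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_pdb(tmp_path / "nope.pdb")


class TestWritePdb:
    def test_roundtrip_identities_and_coordinates(self, tmp_path, two_frame_trajectory):
        out = tmp_path / "rt.pdb"
        write_pdb(two_frame_trajectory, out)
        back = read_pdb(out)
        assert back.n_frames == two_frame_trajectory.n_frames
        top0, top1 = two_frame_trajectory.topology, back.topology
        assert list(top0.name) == list(top1.name)
        assert list(top0.chain) == list(top1.chain)
        assert list(top0.resid) == list(top1.resid)
        assert list(top0.hetero) == list(top1.hetero)
        # PDB columns carry 3 decimals
        assert np.abs(back.coords - two_frame_trajectory.coords).max() < 5.2e-4

    def test_single_frame_has_no_model_records(self, tmp_path, peptide_structure):
        out = tmp_path / "single.pdb"
        write_pdb(peptide_structure, out)
        assert "MODEL" not in out.read_text()
        out2 = tmp_path / "forced.pdb"
        write_pdb(Trajectory.from_structure(peptide_structure), out2, force_model_records=True)
        assert "MODEL" in out2.read_text()

    def test_oversized_coordinates_error(self, tmp_path, peptide_structure):
        big = peptide_structure.with_coords(peptide_structure.coords + 1e5)
        with pytest.raises(PDBFormatError, match="fixed-width"):
            write_pdb(big, tmp_path / "big.pdb")


class TestSelection:
    def test_name_selection(self, peptide_structure):
        idx = select(peptide_structure, "name CA")
        assert len(idx) == 5
        assert all(peptide_structure.name[i] == "CA" for i in idx)

    def test_compound_expression(self, peptide_structure):
        idx = select(peptide_structure, "chain A and resid 1-2 and name CA")
        assert len(idx) == 2
        assert list(peptide_structure.resid[idx]) == [1, 2]

    def test_protein_excludes_hetatm_water(self, peptide_structure):
        idx = select(peptide_structure, "protein")
        assert len(idx) == 15  # the water is excluded
        assert not peptide_structure.hetero[idx].any()

    def test_or_not_and_parentheses(self, peptide_structure):
        idx = select(peptide_structure, "(chain A or chain B) and not name CA")
        assert len(idx) == 10

    def test_empty_selection_warns(self, peptide_structure):
        with pytest.warns(UserWarning, match="matched no atoms"):
            idx = select(peptide_structure, "resname XXX")
        assert len(idx) == 0

    def test_syntax_error_names_the_token(self, peptide_structure):
        with pytest.raises(SelectionError, match="frobnicate"):
            select(peptide_structure, "name CA and frobnicate")

    def test_selection_is_idempotent_and_ordered(self, peptide_structure):
        sel = AtomSelection("chain B or chain A")
        i1 = select(peptide_structure, sel)
        i2 = select(peptide_structure, sel)
        assert np.array_equal(i1, i2)
        assert np.all(np.diff(i1) > 0)  # topology order

    def test_resid_comma_list(self, peptide_structure):
        idx = select(peptide_structure, "resid 1,3 and name CA")
        assert list(peptide_structure.resid[idx]) == [1, 3]
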
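"""CSV dialects, CYANA .upl/.lol files, XPLOR export, viewer scripts."""

import numpy as np
import pytest

from afrestraints import (
    CHIMERAX_CSV_HEADER,
    PYMOL_CSV_HEADER,
    RestraintConfig,
    WriterError,
    build_restraints,
    default_output_name,
    parse_cyana_restraints,
    write_cyana_restraints,
    write_master_csv,
    write_viewer_script,
    write_xplor_restraints,
)
from afrestraints.structure_io import AtomRecord, StructureModel

from conftest import random_structure


def fixture_records():
    """Two Cα pairs with exactly representable distances and round pLDDTs:
    (643 THR, 647 GLU) at 10.00 Å both >= 90, and (643 THR, 651 LEU) at
    12.00 Å with min pLDDT 85."""
    atoms = [
        AtomRecord("A", 643, "THR", "CA", "C", 0.0, 0.0, 0.0, 90.0, True),
        AtomRecord("A", 647, "GLU", "CA", "C", 10.0, 0.0, 0.0, 95.0, True),
        AtomRecord("A", 651, "LEU", "CA", "C", -12.0, 0.0, 0.0, 85.0, True),
    ]
    return build_restraints(StructureModel("m", atoms), RestraintConfig())


class TestMasterCsv:
    def test_headers_are_exact(self, tmp_path):
        for dialect, header in [("pymol", PYMOL_CSV_HEADER), ("chimerax", CHIMERAX_CSV_HEADER)]:
            path = write_master_csv([], tmp_path / f"{dialect}.csv", dialect)
            assert path.read_text() == header + "\n"

    def test_pymol_row_is_consistent(self, tmp_path):
        records = fixture_records()
        path = write_master_csv(records, tmp_path / "out.csv", "pymol")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + len(records)
        for line, rec in zip(lines[1:], records):
            cells = line.split(",")
            assert len(cells) == 16
            max_werr = max(float(cells[11]), float(cells[12]))
            assert float(cells[13]) == pytest.approx(max_werr)
            assert float(cells[14]) - float(cells[15]) == pytest.approx(
                2 * rec.max_weighted_error, abs=0.011
            )

    def test_dialects_share_distance_and_limits(self, tmp_path):
        records = fixture_records()
        pml = write_master_csv(records, tmp_path / "p.csv", "pymol").read_text().splitlines()[1:]
        cx = write_master_csv(records, tmp_path / "c.csv", "chimerax").read_text().splitlines()[1:]
        for prow, crow in zip(pml, cx):
            p, c = prow.split(","), crow.split(",")
            assert (p[8], p[14], p[15]) == (c[6], c[10], c[11])  # Distance, UPL, LOL

    def test_golden_bytes_for_frozen_fixture(self, tmp_path):
        """Byte-identical output for a frozen fixture; expected rows are
        written out by hand from the interpolation arithmetic."""
        records = fixture_records()
        pml = write_master_csv(records, tmp_path / "p.csv", "pymol").read_text()
        cx = write_master_csv(records, tmp_path / "c.csv", "chimerax").read_text()
        # pair (643, 647): both >= 90 -> gef 0, werr 1.40, upl 11.40, lol 8.60
        # pair (643, 651): plddts (90, 85) -> gefs (0, 0.5), werrs (1.40, 1.48)
        assert pml == (
            PYMOL_CSV_HEADER + "\n"
            "643,THR,90.00,CA,647,GLU,95.00,CA,10.00,0.0000,0.0000,"
            "1.4000,1.4000,1.4000,11.40,8.60\n"
            "643,THR,90.00,CA,651,LEU,85.00,CA,12.00,0.0000,0.5000,"
            "1.4000,1.4800,1.4800,13.48,10.52\n"
        )
        assert cx == (
            CHIMERAX_CSV_HEADER + "\n"
            "A,643,CA,A,647,CA,10.00,90.00,0.0000,1.4000,11.40,8.60\n"
            "A,643,CA,A,651,CA,12.00,85.00,0.5000,1.4800,13.48,10.52\n"
        )


class TestDefaultOutputName:
    @pytest.mark.parametrize(
        "config,dialect,expected",
        [
            (RestraintConfig(), "chimerax", "CX_distances_CA_CA_15A_b80.csv"),
            (RestraintConfig(), "pymol", "PML_distances_CA_CA_15A_b80.csv"),
            (
                RestraintConfig(atom_name1="CA", atom_name2="MG",
                                distance_cutoff=10, plddt_cutoff=90),
                "chimerax",
                "CX_distances_CA_MG_10A_b90.csv",
            ),
            (
                RestraintConfig(distance_cutoff=12.5, plddt_cutoff=82.5),
                "pymol",
                "PML_distances_CA_CA_12.5A_b82.5.csv",
            ),
        ],
    )
    def test_pattern(self, config, dialect, expected):
        assert default_output_name(config, dialect) == expected


class TestCyanaFiles:
    def test_upl_and_lol_lines(self, tmp_path):
        records = fixture_records()
        upl, lol = write_cyana_restraints(records, tmp_path / "r.upl", tmp_path / "r.lol")
        assert upl.read_text().splitlines()[0] == "643 THR CA 647 GLU CA 11.40"
        assert lol.read_text().splitlines()[0] == "643 THR CA 647 GLU CA 8.60"
        assert len(upl.read_text().splitlines()) == len(records)

    def test_empty_records_give_empty_files(self, tmp_path):
        upl, lol = write_cyana_restraints([], tmp_path / "e.upl", tmp_path / "e.lol")
        assert upl.read_text() == "" and lol.read_text() == ""

    def test_parse_back_recovers_limits(self, tmp_path):
        rng = np.random.default_rng(2)
        records = build_restraints(random_structure(rng, 60), RestraintConfig())
        assert records
        with pytest.warns(UserWarning, match="chain"):  # random model spans chains
            upl, lol = write_cyana_restraints(
                records, tmp_path / "r.upl", tmp_path / "r.lol"
            )
        for path, attr in [(upl, "upl"), (lol, "lol")]:
            rows = parse_cyana_restraints(path)
            assert len(rows) == len(records)
            for row, rec in zip(rows, records):
                assert row[0] == rec.pair.atom1.residue_number
                assert row[3] == rec.pair.atom2.residue_number
                assert row[6] == pytest.approx(getattr(rec, attr), abs=0.005)

    def test_nonpositive_residue_numbers_rejected(self, tmp_path):
        atoms = [
            AtomRecord("A", -1, "THR", "CA", "C", 0.0, 0.0, 0.0, 90.0, True),
            AtomRecord("A", 3, "GLU", "CA", "C", 8.0, 0.0, 0.0, 90.0, True),
        ]
        records = build_restraints(StructureModel("m", atoms), RestraintConfig())
        with pytest.raises(WriterError, match="renumber"):
            write_cyana_restraints(records, tmp_path / "r.upl", tmp_path / "r.lol")

    def test_multichain_records_warn(self, tmp_path):
        atoms = [
            AtomRecord("A", 1, "THR", "CA", "C", 0.0, 0.0, 0.0, 90.0, True),
            AtomRecord("B", 1, "GLU", "CA", "C", 8.0, 0.0, 0.0, 90.0, True),
        ]
        records = build_restraints(StructureModel("m", atoms), RestraintConfig())
        with pytest.warns(UserWarning, match="chain"):
            write_cyana_restraints(records, tmp_path / "r.upl", tmp_path / "r.lol")


class TestXplorExport:
    def test_assign_statement_bounds(self, tmp_path):
        records = fixture_records()
        path = write_xplor_restraints(records, tmp_path / "r.tbl")
        line = path.read_text().splitlines()[0]
        assert line == (
            "assign (resid 643 and name CA)(resid 647 and name CA) 10.00 1.40 1.40"
        )

    def test_floor_clamped_record_has_dminus_equal_distance(self, tmp_path):
        atoms = [
            AtomRecord("A", 1, "THR", "CA", "C", 0.0, 0.0, 0.0, 95.0, True),
            AtomRecord("A", 3, "GLU", "CA", "C", 1.0, 0.0, 0.0, 95.0, True),
        ]
        records = build_restraints(StructureModel("m", atoms), RestraintConfig())
        line = write_xplor_restraints(records, tmp_path / "r.tbl").read_text().splitlines()[0]
        assert line.endswith("1.00 1.00 1.40")

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(WriterError):
            write_xplor_restraints([], tmp_path / "r.tbl")


class TestViewerScripts:
    @pytest.mark.parametrize("flavor,token", [("pymol", "distance af_rest_"),
                                              ("chimerax", "distance /")])
    def test_one_command_per_record(self, tmp_path, flavor, token):
        records = fixture_records()
        path = write_viewer_script(records, tmp_path / "view.txt", flavor)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        assert sum(line.startswith("distance") for line in lines) == len(records)
        assert all(token in line for line in lines[1:])

    def test_zero_records_give_comment_only_script(self, tmp_path):
        path = write_viewer_script([], tmp_path / "v.pml", "pymol")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_24_record_chain_matches_pair_count(self, tmp_path, linear_chain_10):
        records = build_restraints(linear_chain_10, RestraintConfig())
        path = write_viewer_script(records, tmp_path / "v.cxc", "chimerax")
        assert sum(
            line.startswith("distance") for line in path.read_text().splitlines()
        ) == 24
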
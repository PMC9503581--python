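import numpy as np
import pytest

from ssassign.formats import (
    PeakFormatError,
    SequenceParseError,
    StarFormatError,
    load_shift_table,
    parse_sequence,
    read_peak_list,
    read_sequence,
    read_sparky_resonances,
    write_peak_list,
    write_shift_table,
    write_sparky_resonances,
    write_tabular,
)
from ssassign.model import (
    AssignmentResult,
    Peak,
    PeakList,
    ResidueAssignment,
    ShiftEntry,
    ShiftTable,
)

SPARKY = """\
     Assignment w1 w2 w3 Data Height

  ?-?-? 176.02 120.31 54.88 1.2e6
"""


class TestSparky:
    def test_basic_3d_row(self, tmp_path):
        p = tmp_path / "ncocx.list"
        p.write_text(SPARKY)
        pl = read_peak_list(p, "NCOCX", axis_order=[1, 0, 2])
        assert len(pl.peaks) == 1
        assert pl.peaks[0].position == (120.31, 176.02, 54.88)
        assert pl.peaks[0].height == pytest.approx(1.2e6)

    def test_empty_body(self, tmp_path):
        p = tmp_path / "nca.list"
        p.write_text("Assignment w1 w2 Data Height\n\n")
        pl = read_peak_list(p, "NCA")
        assert pl.peaks == []

    def test_unparseable_lines_counted(self, tmp_path):
        p = tmp_path / "nca.list"
        p.write_text("?-? 120.1 54.3\ngarbage line here\n?-? 121.0 55.0\n")
        pl = read_peak_list(p, "NCA")
        assert len(pl.peaks) == 2
        assert pl.skipped_lines == 1

    def test_order_preserved(self, tmp_path):
        p = tmp_path / "nca.list"
        p.write_text("?-? 120.1 54.3\n?-? 121.0 55.0\n")
        pl = read_peak_list(p, "NCA")
        assert [pk.position[0] for pk in pl.peaks] == [120.1, 121.0]


class TestXeasy:
    def test_standard_row(self, tmp_path):
        p = tmp_path / "x.peaks"
        p.write_text("# Number of dimensions 3\n"
                     "1 120.31 176.02 54.88 1 U 1.2e6 0.0e0 - 0 0 0 0\n")
        pl = read_peak_list(p, "NCOCX")
        assert len(pl.peaks) == 1
        assert pl.peaks[0].position == (120.31, 176.02, 54.88)
        assert pl.peaks[0].height == pytest.approx(1.2e6)


class TestTabularTxt:
    def test_tab_separated(self, tmp_path):
        p = tmp_path / "nca.txt"
        p.write_text("120.31\t54.88\t1000.0\n")
        pl = read_peak_list(p, "NCA")
        assert pl.peaks[0].position == (120.31, 54.88)
        assert pl.peaks[0].height == 1000.0

    def test_unknown_extension_needs_hint(self, tmp_path):
        p = tmp_path / "nca.dat"
        p.write_text("120.31 54.88\n")
        with pytest.raises(PeakFormatError):
            read_peak_list(p, "NCA")
        pl = read_peak_list(p, "NCA", format_hint="tabular")
        assert len(pl.peaks) == 1


class TestPeakListRoundTrip:
    @pytest.mark.parametrize("fmt", ["sparky", "xeasy"])
    def test_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(3)
        peaks = [Peak(tuple(rng.uniform(10, 180, size=3)), float(rng.uniform(1, 9)))
                 for _ in range(25)]
        pl = PeakList("NCACX", 3, ("15N", "13C", "13C"), peaks)
        path = tmp_path / ("x.list" if fmt == "sparky" else "x.peaks")
        write_peak_list(pl, path, fmt)
        back = read_peak_list(path, "NCACX")
        assert len(back.peaks) == len(peaks)
        for a, b in zip(peaks, back.peaks):
            assert a.position == pytest.approx(b.position, abs=1e-3)


class TestSequence:
    def test_one_letter(self, tmp_path):
        p = tmp_path / "seq.txt"
        p.write_text("MQYK\n")
        seq = read_sequence(p)
        assert seq.residues == "MQYK"
        assert list(seq.positions()) == [1, 2, 3, 4]

    def test_three_letter_equivalent(self):
        assert parse_sequence("MET GLN TYR LYS").residues == \
            parse_sequence("MQYK").residues

    def test_case_insensitive_three_letter(self):
        assert parse_sequence("met gln").residues == "MQ"

    def test_whitespace_and_linebreaks(self):
        assert parse_sequence("MQ\nYK  LI\n").residues == "MQYKLI"

    def test_unknown_code_rejected(self):
        with pytest.raises(SequenceParseError, match="X"):
            parse_sequence("MQXZ")

    def test_empty_rejected(self):
        with pytest.raises(SequenceParseError):
            parse_sequence("  \n ")


def _result(entries):
    residues = {}
    for idx, rtype, atom, ppm, prob in entries:
        ra = residues.setdefault(idx, ResidueAssignment(idx, rtype, {}, prob))
        ra.atoms[atom] = (ppm, prob)
        ra.best_probability = max(ra.best_probability, prob)
    return AssignmentResult(residues=residues, candidates={}, offsets={})


class TestShiftTableWriters:
    def example(self):
        return _result([
            (1, "G", "N", 108.95, 0.99), (1, "G", "CA", 45.2, 0.99),
            (1, "G", "C", 174.1, 0.99),
            (2, "A", "N", 123.5, 0.98), (2, "A", "CA", 52.9, 0.98),
            (2, "A", "CB", 19.2, 0.98), (2, "A", "C", 177.5, 0.98),
        ])

    @pytest.mark.parametrize("dialect", ["2.1", "3.1"])
    def test_row_count_and_round_trip(self, tmp_path, dialect):
        res = self.example()
        path = tmp_path / "shifts.str"
        write_shift_table(res, dialect, path)
        table = load_shift_table(path)
        assert len(table) == 7
        for idx, rtype, atom, ppm, _ in res.iter_shifts():
            assert table.get(idx, atom) == pytest.approx(ppm, abs=1e-3)
            assert table.residue_type(idx) == rtype

    def test_empty_result_refused(self, tmp_path):
        empty = AssignmentResult(residues={}, candidates={}, offsets={})
        with pytest.raises(ValueError):
            write_shift_table(empty, "3.1", tmp_path / "x.str")

    def test_random_round_trip(self, tmp_path):
        # round-trip oracle on randomly generated tables, fixed seed
        rng = np.random.default_rng(42)
        entries = []
        for idx in range(1, 30):
            entries.append((idx, "A", "CA", float(rng.uniform(40, 70)),
                            float(rng.uniform(0, 1))))
        res = _result(entries)
        path = tmp_path / "shifts.str"
        write_shift_table(res, "3.1", path)
        table = load_shift_table(path)
        for idx, _r, atom, ppm, _p in res.iter_shifts():
            assert table.get(idx, atom) == pytest.approx(ppm, abs=1e-3)


class TestSparkyResonances:
    def test_lines_and_round_trip(self, tmp_path):
        res = _result([(1, "G", "N", 108.95, 0.9), (1, "G", "CA", 45.2, 0.9)])
        path = tmp_path / "res.list"
        write_sparky_resonances(res, path)
        rows = read_sparky_resonances(path)
        assert rows == [("G", 1, "CA", 45.2), ("G", 1, "N", 108.95)]


class TestLoadShiftTable:
    def test_star_31_filters_protons(self, tmp_path):
        body = """data_x
loop_
  _Atom_chem_shift.ID
  _Atom_chem_shift.Seq_ID
  _Atom_chem_shift.Comp_ID
  _Atom_chem_shift.Atom_ID
  _Atom_chem_shift.Val
  1 1 ALA CA 52.3
  2 1 ALA CB 19.1
  3 1 ALA C 177.2
  4 1 ALA N 123.0
  5 1 ALA HA 4.2
  6 1 ALA HB 1.4
  7 2 GLY CA 45.1
  8 2 GLY H 8.1
stop_
"""
        p = tmp_path / "t.str"
        p.write_text(body)
        table = load_shift_table(p)
        assert len(table) == 5
        assert table.get(2, "CA") == 45.1

    def test_tabular(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("2 ALA CA 52.3\n")
        table = load_shift_table(p)
        e = table.entries[0]
        assert (e.residue_index, e.residue_type, e.atom, e.ppm) == (2, "A", "CA", 52.3)

    def test_no_shift_loop(self, tmp_path):
        p = tmp_path / "t.str"
        p.write_text("data_x\nnothing here\n")
        with pytest.raises(StarFormatError):
            load_shift_table(p)

    def test_tabular_round_trip(self, tmp_path):
        table = ShiftTable([ShiftEntry(1, "A", "CA", 52.312),
                            ShiftEntry(2, "G", "N", 108.951)])
        p = tmp_path / "t.txt"
        write_tabular(table, p)
        back = load_shift_table(p)
        assert back.get(1, "CA") == pytest.approx(52.312, abs=1e-3)
        assert back.get(2, "N") == pytest.approx(108.951, abs=1e-3)
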
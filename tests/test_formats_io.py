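import numpy as np
import pandas as pd
import pytest

from coopnet import formats_io as fio


class TestBed:
    def test_five_column_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tp1\t0.95\n")
        peaks = fio.read_bed(p)
        assert len(peaks) == 1
        pk = peaks[0]
        assert (pk.chrom, pk.start, pk.end, pk.name, pk.posterior) == ("chr1", 100, 200, "p1", 0.95)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert fio.read_bed(p) == []

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(fio.FormatError, match="2|start"):
            fio.read_bed(p)

    def test_missing_posterior_defaults_to_one(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\tp1\n")
        assert fio.read_bed(p)[0].posterior == 1.0

    def test_round_trip(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tp1\t0.95\nchr2\t5\t50\tp2\t0.5\n")
        peaks = fio.read_bed(p)
        out = tmp_path / "b.bed"
        fio.write_bed(peaks, out)
        assert fio.read_bed(out) == peaks

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\nchr1\tnope\t20\n")
        with pytest.raises(fio.FormatError, match=":2"):
            fio.read_bed(p)


TRANSFAC_BLOCK = """\
VV  TEST
XX
//
ID  M00001
XX
P0      A      C      G      T
01      10      0      0      0
02      0      10      0      0
03      0      0      10      0
04      0      0      0      10
05      2      2      2      2
XX
//
"""

MEME_MINIMAL = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF M8 testmotif
letter-probability matrix: alength= 4 w= 8 nsites= 20 E= 0
 0.970000  0.010000  0.010000  0.010000
 0.010000  0.970000  0.010000  0.010000
 0.010000  0.010000  0.970000  0.010000
 0.010000  0.010000  0.010000  0.970000
 0.970000  0.010000  0.010000  0.010000
 0.010000  0.970000  0.010000  0.010000
 0.010000  0.010000  0.970000  0.010000
 0.010000  0.010000  0.010000  0.970000
"""


class TestPwm:
    def test_transfac_counts_normalised_with_pseudocount(self, tmp_path):
        p = tmp_path / "m.dat"
        p.write_text(TRANSFAC_BLOCK)
        pwms = fio.read_pwm(p, dialect="transfac")
        assert len(pwms) == 1
        probs = pwms[0].probs
        # (10,0,0,0) row: dominant base close to 1, others ~pseudocount-sized
        assert probs[0, 0] > 0.95
        assert np.all(probs[0, 1:] < 0.02)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        # uniform counts row stays uniform
        np.testing.assert_allclose(probs[4], 0.25, atol=1e-9)

    def test_meme_minimal_length(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(MEME_MINIMAL)
        pwms = fio.read_pwm(p, dialect="meme")
        assert len(pwms[0]) == 8
        assert pwms[0].motif_id == "M8"

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            fio.read_pwm(tmp_path / "x", dialect="jaspar")

    def test_zero_count_row_rejected(self):
        counts = np.array([[1, 1, 1, 1], [0, 0, 0, 0], [1, 0, 0, 0], [2, 2, 2, 2]])
        with pytest.raises(fio.FormatError, match="zero"):
            fio.Pwm.from_counts("X", "x", counts)

    def test_meme_write_read_round_trip(self, tmp_path):
        pwm = fio.Pwm.from_consensus("TRE", "AP1", "TGASTCA")
        path = tmp_path / "out.meme"
        fio.write_meme([pwm], path)
        back = fio.read_pwm(path, dialect="meme", pseudocount=0.0)
        assert back[0].motif_id == "TRE"
        # MEME minimal readers quantise probabilities to counts, so the
        # round trip is exact only to ~1/nsites
        np.testing.assert_allclose(back[0].probs, pwm.probs, atol=2e-3)

    def test_short_motif_rejected(self):
        with pytest.raises(fio.FormatError, match="length"):
            fio.Pwm("X", "x", np.full((3, 4), 0.25))


class TestExpression:
    def test_read_matches_sheet(self, tmp_path):
        m = tmp_path / "e.tsv"
        m.write_text("gene_id\ts1\ts2\ts3\ts4\ng1\t1\t2\t3\t4\ng2\t4\t3\t2\t1\n")
        s = tmp_path / "ss.tsv"
        s.write_text(
            "sample\tcondition\ttime_h\treplicate\n"
            "s1\tWKY\t0\t1\ns2\tWKY\t0\t2\ns3\tWKY\t2\t1\ns4\tWKY\t2\t2\n"
        )
        e = fio.read_expression(m, s)
        assert e.genes == ["g1", "g2"]
        assert e.data.shape == (2, 4)

    def test_sample_missing_from_sheet(self, tmp_path):
        m = tmp_path / "e.tsv"
        m.write_text("gene_id\ts1\tsX\ng1\t1\t2\n")
        s = tmp_path / "ss.tsv"
        s.write_text("sample\tcondition\ttime_h\treplicate\ns1\tWKY\t0\t1\n")
        with pytest.raises(fio.FormatError, match="sX"):
            fio.read_expression(m, s)

    def test_non_numeric_cell_named(self, tmp_path):
        m = tmp_path / "e.tsv"
        m.write_text("gene_id\ts1\ng1\t1\ng2\toops\n")
        s = tmp_path / "ss.tsv"
        s.write_text("sample\tcondition\ttime_h\treplicate\ns1\tWKY\t0\t1\n")
        with pytest.raises(fio.FormatError, match="g2.*s1"):
            fio.read_expression(m, s)

    def test_duplicate_gene_rejected(self, tmp_path):
        m = tmp_path / "e.tsv"
        m.write_text("gene_id\ts1\ng1\t1\ng1\t2\n")
        s = tmp_path / "ss.tsv"
        s.write_text("sample\tcondition\ttime_h\treplicate\ns1\tWKY\t0\t1\n")
        with pytest.raises(fio.FormatError, match="duplicate"):
            fio.read_expression(m, s)

    def test_round_trip(self, tmp_path, expr_factory):
        e = expr_factory(np.arange(16.0).reshape(2, 8), ["g1", "g2"])
        e.to_tsv(tmp_path / "m.tsv", tmp_path / "s.tsv")
        back = fio.read_expression(tmp_path / "m.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.data, e.data, check_names=False)


class TestGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tg1\tg2\n")
        sets = fio.read_gmt(p)
        assert sets[0].set_id == "S1"
        assert sets[0].genes == frozenset({"g1", "g2"})

    def test_round_trip_identity(self, tmp_path):
        sets = [fio.GeneSet("S1", "d1", frozenset({"a", "b"})),
                fio.GeneSet("S2", "d2", frozenset({"c"}))]
        p = tmp_path / "s.gmt"
        fio.write_gmt(sets, p)
        assert fio.read_gmt(p) == sets

    def test_duplicate_member_warns_and_dedups(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tg1\tg1\tg2\n")
        with pytest.warns(UserWarning, match="duplicate"):
            sets = fio.read_gmt(p)
        assert sets[0].genes == frozenset({"g1", "g2"})

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tonly-desc\n")
        with pytest.raises(fio.FormatError, match="<3"):
            fio.read_gmt(p)


class TestNetwork:
    def test_single_edge(self, tmp_path):
        p = tmp_path / "n.tsv"
        fio.write_network(
            [{"source": "JunD", "target": "ATF3", "edge_type": "dimer-partner", "fwer": 0.01}], p
        )
        df = fio.read_network(p)
        assert len(df) == 1
        assert df.loc[0, "edge_type"] == "dimer-partner"

    def test_empty_network_header_only(self, tmp_path):
        p = tmp_path / "n.tsv"
        fio.write_network([], p)
        assert p.read_text().strip() == "\t".join(fio.NETWORK_COLUMNS)

    def test_duplicate_edges_written_once(self, tmp_path):
        p = tmp_path / "n.tsv"
        e = {"source": "a", "target": "b", "edge_type": "complex-target"}
        fio.write_network([e, dict(e)], p)
        assert len(fio.read_network(p)) == 1
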
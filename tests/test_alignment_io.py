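import numpy as np
import pytest

from recruitplot import (
    IdentityMode,
    compute_identity,
    parse_blast_tab,
    parse_sam,
    write_filtered,
)
from recruitplot.alignment_io import sam_header_text

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:3000\n"


def write_sam(path, lines):
    path.write_text(SAM_HEADER + "".join(line + "\n" for line in lines))
    return path


def blast_row(qid="r1", sid="c1", pident=95.0, length=100, mism=5, gapo=0,
              qs=1, qe=100, ss=951, se=1050, ev="1e-30", bits=180):
    return f"{qid}\t{sid}\t{pident:.3f}\t{length}\t{mism}\t{gapo}\t{qs}\t{qe}\t{ss}\t{se}\t{ev}\t{bits}"


class TestParseBlastTab:
    def test_field_mapping_and_coordinates(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(blast_row() + "\n")
        (rec,) = parse_blast_tab(path, "s1", "g1")
        assert (rec.matches, rec.ref_start, rec.ref_end) == (95, 950, 1050)
        assert rec.pct_id_local == 95.0
        assert rec.read_length is None
        assert rec.source_format == "blast_tab"

    def test_minus_strand_interval_reversed(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(blast_row(ss=1050, se=951) + "\n")
        (rec,) = parse_blast_tab(path, "s1", "g1")
        assert (rec.ref_start, rec.ref_end) == (950, 1050)

    def test_perfect_identity(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(blast_row(pident=100.0, length=150, mism=0, qe=150, se=1100) + "\n")
        (rec,) = parse_blast_tab(path, "s1", "g1")
        assert rec.matches == 150 and rec.pct_id_local == 100.0

    def test_short_row_errors_with_line_number(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(blast_row() + "\nr2\tc1\t95.0\n")
        with pytest.raises(ValueError, match=":2"):
            list(parse_blast_tab(path, "s1", "g1"))

    def test_non_numeric_coordinate_errors(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(blast_row(ss="x") + "\n")
        with pytest.raises(ValueError, match="non-numeric"):
            list(parse_blast_tab(path, "s1", "g1"))


class TestParseSam:
    def test_simple_match_with_nm(self, tmp_path):
        path = write_sam(tmp_path / "a.sam",
                         [f"r1\t0\tc1\t951\t60\t100M\t*\t0\t0\t{'A' * 100}\t*\tNM:i:5"])
        (rec,) = parse_sam(path, "s1", "g1")
        assert (rec.ref_start, rec.ref_end) == (950, 1050)
        assert (rec.aln_columns, rec.matches, rec.read_length) == (100, 95, 100)
        assert rec.pct_id_local == 95.0 and rec.pct_id_global == 95.0

    def test_soft_clip_counts_in_global_denominator(self, tmp_path):
        path = write_sam(tmp_path / "a.sam",
                         [f"r1\t0\tc1\t1\t60\t20S80M\t*\t0\t0\t{'A' * 100}\t*\tNM:i:0"])
        (rec,) = parse_sam(path, "s1", "g1")
        assert (rec.ref_start, rec.ref_end) == (0, 80)
        assert (rec.aln_columns, rec.matches, rec.read_length) == (80, 80, 100)
        assert rec.pct_id_local == 100.0
        assert rec.pct_id_global == pytest.approx(80.0)

    def test_deletion_identity_matches_per_column_oracle(self, tmp_path):
        # hand-built pair: read equals reference with 2 bases deleted
        rng = np.random.default_rng(11)
        ref = rng.choice(list("ACGT"), size=102)
        read = np.concatenate([ref[:50], ref[52:]])
        # per-column reconstruction: walk the alignment, count identical columns
        identical = sum(a == b for a, b in zip(read[:50], ref[:50]))
        identical += sum(a == b for a, b in zip(read[50:], ref[52:]))
        columns = 50 + 2 + 50  # M + D + M
        assert (identical, columns) == (100, 102)

        path = write_sam(
            tmp_path / "a.sam",
            [f"r1\t0\tc1\t1\t60\t50M2D50M\t*\t0\t0\t{''.join(read)}\t*\tNM:i:2"],
        )
        (rec,) = parse_sam(path, "s1", "g1")
        assert (rec.ref_start, rec.ref_end) == (0, 102)
        assert (rec.aln_columns, rec.matches) == (columns, identical)
        assert rec.pct_id_local == pytest.approx(100 * 100 / 102)

    def test_md_fallback_when_nm_missing(self, tmp_path):
        path = write_sam(tmp_path / "a.sam",
                         [f"r1\t0\tc1\t1\t60\t100M\t*\t0\t0\t{'A' * 100}\t*\tMD:Z:40C20T38"])
        (rec,) = parse_sam(path, "s1", "g1")
        assert rec.matches == 98

    def test_eqx_fallback(self, tmp_path):
        path = write_sam(tmp_path / "a.sam",
                         [f"r1\t0\tc1\t1\t60\t60=1X39=\t*\t0\t0\t{'A' * 100}\t*"])
        (rec,) = parse_sam(path, "s1", "g1")
        assert rec.matches == 99 and rec.aln_columns == 100

    def test_skips_unmapped_secondary_supplementary_and_uncomputable(self, tmp_path):
        lines = [
            f"r1\t0\tc1\t1\t60\t100M\t*\t0\t0\t{'A' * 100}\t*\tNM:i:0",
            f"r2\t4\t*\t0\t0\t*\t*\t0\t0\t{'A' * 100}\t*",
            f"r1\t256\tc1\t500\t60\t100M\t*\t0\t0\t*\t*\tNM:i:1",
            f"r1\t2048\tc1\t900\t60\t50M\t*\t0\t0\t{'A' * 50}\t*\tNM:i:0",
            f"r3\t0\tc1\t1\t60\t100M\t*\t0\t0\t{'A' * 100}\t*",  # no NM/MD/=X
        ]
        recs = list(parse_sam(write_sam(tmp_path / "a.sam", lines), "s1", "g1"))
        assert [r.read_id for r in recs] == ["r1"]


class TestComputeIdentity:
    def test_local_and_global(self, tmp_path):
        path = write_sam(tmp_path / "a.sam",
                         [f"r1\t0\tc1\t1\t60\t100M20S\t*\t0\t0\t{'A' * 120}\t*\tNM:i:5"])
        (rec,) = parse_sam(path, "s1", "g1")
        assert compute_identity(rec, IdentityMode.LOCAL) == pytest.approx(95.0)
        assert compute_identity(rec, IdentityMode.GLOBAL) == pytest.approx(95 / 120 * 100, abs=1e-4)

    def test_global_rejected_for_blast(self, tmp_path):
        path = tmp_path / "b.tsv"
        path.write_text(blast_row() + "\n")
        (rec,) = parse_blast_tab(path, "s1", "g1")
        with pytest.raises(ValueError, match="tabular BLAST"):
            compute_identity(rec, IdentityMode.GLOBAL)


class TestWriteFiltered:
    def test_blast_pass_through_is_byte_identical(self, tmp_path):
        src = tmp_path / "in.tsv"
        rows = [blast_row(qid=f"r{i}", ss=1 + i, se=100 + i) for i in range(3)]
        src.write_text("\n".join(rows) + "\n")
        recs = list(parse_blast_tab(src, "s1", "g1"))
        out = tmp_path / "out.tsv"
        assert write_filtered(recs, out) == 3
        assert out.read_text() == src.read_text()

    def test_sam_round_trip_re_parses_identically(self, tmp_path):
        src = write_sam(
            tmp_path / "in.sam",
            [f"r{i}\t0\tc1\t{i * 100 + 1}\t60\t100M\t*\t0\t0\t{'A' * 100}\t*\tNM:i:{i}"
             for i in range(3)],
        )
        recs = list(parse_sam(src, "s1", "g1"))
        out = tmp_path / "out.sam"
        write_filtered(recs, out, header_text=sam_header_text(src))
        assert out.read_text() == src.read_text()
        reparsed = list(parse_sam(out, "s1", "g1"))
        assert reparsed == recs

    def test_mixed_formats_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        [f"r1\t0\tc1\t1\t60\t100M\t*\t0\t0\t{'A' * 100}\t*\tNM:i:0"])
        bl = tmp_path / "b.tsv"
        bl.write_text(blast_row() + "\n")
        recs = list(parse_sam(sam, "s1", "g1")) + list(parse_blast_tab(bl, "s1", "g1"))
        with pytest.raises(ValueError, match="mixed"):
            write_filtered(recs, tmp_path / "out")

    def test_empty_selection_writes_header_only_sam(self, tmp_path):
        out = tmp_path / "out.sam"
        write_filtered([], out, header_text=SAM_HEADER)
        assert out.read_text() == SAM_HEADER


class TestFormatEquivalence:
    def test_sam_and_blast_emissions_agree(self, two_pop_sim):
        """The same simulated read set expressed as SAM and outfmt 6 yields
        records with identical intervals and local identities within the
        printed pident precision."""
        sam_recs = {r.read_id: r for r in parse_sam(two_pop_sim["sam"], "s1", "g1")}
        blast_recs = {r.read_id: r for r in parse_blast_tab(two_pop_sim["blast"], "s1", "g1")}
        assert sam_recs.keys() == blast_recs.keys()
        for rid, s in sam_recs.items():
            b = blast_recs[rid]
            assert (s.ref_start, s.ref_end) == (b.ref_start, b.ref_end)
            assert s.pct_id_local == pytest.approx(b.pct_id_local, abs=0.01)
            assert s.matches == b.matches
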
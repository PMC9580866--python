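import numpy as np
import pytest

from recruitplot import (
    Contig,
    FilterSpec,
    IdentityMode,
    RecruitDB,
    ReferenceSet,
    build_database,
)

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:c1\tLN:3000\n"


def sam_line(rid, pos, nm, flag=0, length=100):
    return (
        f"{rid}\t{flag}\tc1\t{pos}\t60\t{length}M\t*\t0\t0\t{'A' * length}\t*\tNM:i:{nm}\n"
    )


def one_contig_ref(genome_id="g1"):
    return ReferenceSet(genome_id=genome_id, contigs=[Contig("c1", 3000, 0)])


@pytest.fixture
def toy_db(tmp_path):
    """Two genomes; read r1 maps to both (97% on gA, 93% on gB); r2 and r3
    map only to gA at 95% and 94%."""
    sam_a = tmp_path / "a.sam"
    sam_a.write_text(
        SAM_HEADER
        + sam_line("r1", 1, 3)
        + sam_line("r2", 951, 5)
        + sam_line("r3", 2001, 6)
    )
    sam_b = tmp_path / "b.sam"
    sam_b.write_text(SAM_HEADER + sam_line("r1", 101, 7))
    db = build_database(
        [one_contig_ref("gA"), one_contig_ref("gB")],
        [(sam_a, "s1", "gA"), (sam_b, "s1", "gB")],
        tmp_path / "db.sqlite",
    )
    yield db
    db.close()


class TestBuildDatabase:
    def test_secondary_records_dropped(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + sam_line("r1", 1, 0)
            + sam_line("r2", 101, 0)
            + sam_line("r3", 201, 0)
            + sam_line("r1", 301, 1, flag=256)
        )
        db = build_database([one_contig_ref()], [(sam, "s1", "g1")], tmp_path / "db.sqlite")
        recs, _ = db.select_reads(FilterSpec(genome_id="g1", sample_id="s1"))
        assert len(recs) == 3
        db.close()

    def test_duplicate_sample_genome_mapping_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + sam_line("r1", 1, 0))
        with pytest.raises(ValueError, match="duplicate sample/genome"):
            build_database(
                [one_contig_ref()],
                [(sam, "s1", "g1"), (sam, "s1", "g1")],
                tmp_path / "db.sqlite",
            )

    def test_unknown_genome_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(SAM_HEADER + sam_line("r1", 1, 0))
        with pytest.raises(ValueError, match="ghost"):
            build_database([one_contig_ref()], [(sam, "s1", "ghost")], tmp_path / "db.sqlite")

    def test_multi_mapping_retained_at_build_time(self, toy_db):
        rows = toy_db.conn.execute(
            "SELECT genome_id FROM reads WHERE read_id='r1' ORDER BY genome_id"
        ).fetchall()
        assert [r[0] for r in rows] == ["gA", "gB"]

    def test_reference_round_trips_through_db(self, toy_db):
        ref = toy_db.get_reference("gA")
        assert ref.total_length == 3000
        assert toy_db.mapping_info("s1", "gA")["source_format"] == "sam"


class TestSelectReads:
    def test_best_hit_excludes_read_best_elsewhere(self, toy_db):
        recs, _ = toy_db.select_reads(
            FilterSpec(genome_id="gB", sample_id="s1", best_hit_only=True)
        )
        assert recs == []

    def test_best_hit_keeps_read_on_its_best_genome(self, toy_db):
        recs, _ = toy_db.select_reads(
            FilterSpec(genome_id="gA", sample_id="s1", best_hit_only=True)
        )
        assert sorted(r.read_id for r in recs) == ["r1", "r2", "r3"]

    def test_without_best_hit_both_genomes_keep_r1(self, toy_db):
        recs, _ = toy_db.select_reads(
            FilterSpec(genome_id="gB", sample_id="s1", best_hit_only=False)
        )
        assert [r.read_id for r in recs] == ["r1"]

    def test_min_aln_length_threshold(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + sam_line("r1", 1, 0, length=30)
            + sam_line("r2", 101, 0, length=100)
            + sam_line("r3", 301, 0, length=250)
        )
        db = build_database([one_contig_ref()], [(sam, "s1", "g1")], tmp_path / "db.sqlite")
        recs, _ = db.select_reads(
            FilterSpec(genome_id="g1", sample_id="s1", min_aln_length=50)
        )
        assert sorted(r.read_id for r in recs) == ["r2", "r3"]
        db.close()

    def test_min_identity_on_toy_set(self, toy_db):
        """98.0% and 95.0% survive a 95% cutoff (>= semantics); 94.0% does not."""
        recs, qr = toy_db.select_reads(
            FilterSpec(genome_id="gA", sample_id="s1", min_identity=95.0)
        )
        assert sorted(r.read_id for r in recs) == ["r1", "r2"]
        assert qr.records_selected == 2

    def test_min_pct_read_aligned_rejected_for_blast(self, tmp_path):
        blast = tmp_path / "b.tsv"
        blast.write_text("r1\tc1\t95.000\t100\t5\t0\t1\t100\t1\t100\t1e-30\t180\n")
        db = build_database([one_contig_ref()], [(blast, "s1", "g1")], tmp_path / "db.sqlite")
        with pytest.raises(ValueError, match="not available"):
            db.select_reads(
                FilterSpec(genome_id="g1", sample_id="s1", min_pct_read_aligned=50.0)
            )
        with pytest.raises(ValueError, match="tabular BLAST"):
            db.select_reads(
                FilterSpec(genome_id="g1", sample_id="s1",
                           identity_mode=IdentityMode.GLOBAL)
            )
        db.close()

    def test_min_pct_read_aligned_on_soft_clipped_read(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            SAM_HEADER
            + f"r1\t0\tc1\t1\t60\t40S60M\t*\t0\t0\t{'A' * 100}\t*\tNM:i:0\n"
            + sam_line("r2", 201, 0)
        )
        db = build_database([one_contig_ref()], [(sam, "s1", "g1")], tmp_path / "db.sqlite")
        recs, _ = db.select_reads(
            FilterSpec(genome_id="g1", sample_id="s1", min_pct_read_aligned=80.0)
        )
        assert [r.read_id for r in recs] == ["r2"]
        db.close()


class TestFilterProperties:
    def test_best_hit_leaves_at_most_one_record_per_read(self, tmp_path):
        rng = np.random.default_rng(5)
        genomes = ["gA", "gB", "gC"]
        sams = {}
        for g in genomes:
            lines = [SAM_HEADER]
            for i in range(40):
                if rng.random() < 0.6:
                    lines.append(sam_line(f"r{i}", int(rng.integers(1, 2900)),
                                          int(rng.integers(0, 10))))
            sams[g] = tmp_path / f"{g}.sam"
            sams[g].write_text("".join(lines))
        db = build_database(
            [one_contig_ref(g) for g in genomes],
            [(sams[g], "s1", g) for g in genomes],
            tmp_path / "db.sqlite",
        )
        seen: dict[str, int] = {}
        for g in genomes:
            recs, _ = db.select_reads(
                FilterSpec(genome_id=g, sample_id="s1", best_hit_only=True)
            )
            for r in recs:
                seen[r.read_id] = seen.get(r.read_id, 0) + 1
        assert all(n == 1 for n in seen.values())
        db.close()

    @pytest.mark.parametrize("field,values", [
        ("min_aln_length", [0, 50, 120, 300]),
        ("min_identity", [0.0, 90.0, 95.0, 99.0, 100.0]),
    ])
    def test_raising_thresholds_is_monotone(self, toy_db, field, values):
        counts = []
        for v in values:
            spec = FilterSpec(genome_id="gA", sample_id="s1", **{field: v})
            recs, _ = toy_db.select_reads(spec)
            counts.append(len(recs))
        assert counts == sorted(counts, reverse=True)


class TestQueryRecord:
    def test_replay_reproduces_the_selection(self, toy_db):
        recs, qr = toy_db.select_reads(
            FilterSpec(genome_id="gA", sample_id="s1", min_identity=95.0)
        )
        assert toy_db.replay(qr.selection_expression) == recs

    def test_sidecar_text_round_trips_expression(self, toy_db, tmp_path):
        _, qr = toy_db.select_reads(FilterSpec(genome_id="gA", sample_id="s1"))
        qr.write(tmp_path / "q.txt")
        text = (tmp_path / "q.txt").read_text()
        assert qr.selection_expression in text
        assert "records_selected\t3" in text
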
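"""Single-file sqlite database of parsed mappings, plus filter semantics.

A session's reads are persisted once, indexed by read name and by
(sample, genome), then every plot or export is a query against that
database.  The exact SQL evaluated for a selection is serialised into a
:class:`QueryRecord` sidecar so any exported plot or read set can be
regenerated later from the same database.
"""

from __future__ import annotations

import datetime
import json
import logging
import sqlite3
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

from .alignment_io import (
    AlignmentRecord,
    IdentityMode,
    parse_blast_tab,
    parse_sam,
    sam_header_text,
    sniff_format,
)
from .reference_io import Contig, GeneAnnotation, ReferenceSet

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "QueryRecord",
    "RecruitDB",
    "build_database",
]


@dataclass
class FilterSpec:
    """User selection criteria for reads.

    Defaults follow the tool's conventions: best-hit filtering on, no
    length or identity floor, local identity.  ``min_pct_read_aligned``
    needs the read's full length and is therefore rejected for tabular
    BLAST data.
    """

    genome_id: str
    sample_id: str
    min_aln_length: int = 0
    min_pct_read_aligned: float | None = None
    best_hit_only: bool = True
    min_identity: float = 0.0
    identity_mode: IdentityMode = IdentityMode.LOCAL

    def __post_init__(self) -> None:
        self.identity_mode = IdentityMode(self.identity_mode)
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if self.min_pct_read_aligned is not None and not (
            0 < self.min_pct_read_aligned <= 100
        ):
            raise ValueError("min_pct_read_aligned must be in (0, 100] when set")

    def to_json(self) -> str:
        d = asdict(self)
        d["identity_mode"] = self.identity_mode.value
        return json.dumps(d, sort_keys=True)


@dataclass
class QueryRecord:
    """The reproducibility trace written next to every plot/data/read export."""

    timestamp: str
    database_path: str
    filter_json: str
    selection_expression: str
    records_selected: int

    def to_text(self) -> str:
        return (
            f"# query record\n"
            f"timestamp\t{self.timestamp}\n"
            f"database\t{self.database_path}\n"
            f"filter\t{self.filter_json}\n"
            f"records_selected\t{self.records_selected}\n"
            f"selection_expression\t{self.selection_expression}\n"
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


_SCHEMA = """
CREATE TABLE IF NOT EXISTS genomes (
    genome_id TEXT PRIMARY KEY,
    total_length INTEGER NOT NULL
);
CREATE TABLE IF NOT EXISTS contigs (
    genome_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    length INTEGER NOT NULL,
    offset INTEGER NOT NULL,
    file_order INTEGER NOT NULL,
    PRIMARY KEY (genome_id, contig_id)
);
CREATE TABLE IF NOT EXISTS genes (
    genome_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL,
    gene_id TEXT NOT NULL,
    product TEXT NOT NULL DEFAULT ''
);
CREATE TABLE IF NOT EXISTS mappings (
    sample_id TEXT NOT NULL,
    genome_id TEXT NOT NULL,
    path TEXT NOT NULL,
    source_format TEXT NOT NULL,
    header TEXT,
    PRIMARY KEY (sample_id, genome_id)
);
CREATE TABLE IF NOT EXISTS reads (
    rid INTEGER PRIMARY KEY,
    read_id TEXT NOT NULL,
    sample_id TEXT NOT NULL,
    genome_id TEXT NOT NULL,
    contig_id TEXT NOT NULL,
    ref_start INTEGER NOT NULL,
    ref_end INTEGER NOT NULL,
    aln_columns INTEGER NOT NULL,
    matches INTEGER NOT NULL,
    read_length INTEGER,
    pct_id_local REAL NOT NULL,
    pct_id_global REAL,
    read_consuming INTEGER,
    source_format TEXT NOT NULL,
    source_line TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_reads_read ON reads (read_id);
CREATE INDEX IF NOT EXISTS idx_reads_sg ON reads (sample_id, genome_id);
"""

_READ_COLS = (
    "read_id, sample_id, genome_id, contig_id, ref_start, ref_end, aln_columns, "
    "matches, read_length, pct_id_local, pct_id_global, read_consuming, "
    "source_format, source_line"
)


def _sql_str(value: str) -> str:
    return "'" + value.replace("'", "''") + "'"


class RecruitDB:
    """Handle on a single-file recruitment database."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "RecruitDB":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- ingestion ---------------------------------------------------------

    def add_reference(self, ref: ReferenceSet) -> None:
        cur = self.conn.cursor()
        existing = cur.execute(
            "SELECT 1 FROM genomes WHERE genome_id = ?", (ref.genome_id,)
        ).fetchone()
        if existing:
            raise ValueError(f"genome {ref.genome_id!r} already in database")
        cur.execute(
            "INSERT INTO genomes VALUES (?, ?)", (ref.genome_id, ref.total_length)
        )
        cur.executemany(
            "INSERT INTO contigs VALUES (?, ?, ?, ?, ?)",
            [
                (ref.genome_id, c.id, c.length, c.offset, i)
                for i, c in enumerate(ref.contigs)
            ],
        )
        cur.executemany(
            "INSERT INTO genes VALUES (?, ?, ?, ?, ?, ?, ?)",
            [
                (ref.genome_id, g.contig_id, g.start, g.end, g.strand, g.gene_id, g.product)
                for g in ref.genes
            ],
        )
        self.conn.commit()

    def add_mapping(
        self,
        path: str | Path,
        sample_id: str,
        genome_id: str,
        source_format: str | None = None,
    ) -> int:
        """Parse one mapping file and store its primary records; returns the count."""
        path = Path(path)
        cur = self.conn.cursor()
        if not cur.execute(
            "SELECT 1 FROM genomes WHERE genome_id = ?", (genome_id,)
        ).fetchone():
            raise ValueError(f"no reference loaded for genome {genome_id!r}")
        if cur.execute(
            "SELECT 1 FROM mappings WHERE sample_id = ? AND genome_id = ?",
            (sample_id, genome_id),
        ).fetchone():
            raise ValueError(
                f"duplicate sample/genome mapping: ({sample_id!r}, {genome_id!r})"
            )
        if source_format is None:
            source_format = sniff_format(path)
        header = sam_header_text(path) if source_format == "sam" else None
        parser = parse_sam if source_format == "sam" else parse_blast_tab
        n = 0
        for rec in parser(path, sample_id, genome_id):
            cur.execute(
                f"INSERT INTO reads ({_READ_COLS}) VALUES "
                "(?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    rec.read_id, rec.sample_id, rec.genome_id, rec.contig_id,
                    rec.ref_start, rec.ref_end, rec.aln_columns, rec.matches,
                    rec.read_length, rec.pct_id_local, rec.pct_id_global,
                    rec.read_consuming, rec.source_format, rec.source_line,
                ),
            )
            n += 1
        cur.execute(
            "INSERT INTO mappings VALUES (?, ?, ?, ?, ?)",
            (sample_id, genome_id, str(path), source_format, header),
        )
        self.conn.commit()
        log.info("ingested %d record(s) from %s as (%s, %s)", n, path, sample_id, genome_id)
        return n

    # -- retrieval ---------------------------------------------------------

    def get_reference(self, genome_id: str) -> ReferenceSet:
        cur = self.conn.cursor()
        rows = cur.execute(
            "SELECT contig_id, length, offset FROM contigs "
            "WHERE genome_id = ? ORDER BY file_order",
            (genome_id,),
        ).fetchall()
        if not rows:
            raise KeyError(f"genome {genome_id!r} not in database")
        contigs = [Contig(id=r[0], length=r[1], offset=r[2]) for r in rows]
        genes = [
            GeneAnnotation(*r)
            for r in cur.execute(
                "SELECT contig_id, start, end, strand, gene_id, product "
                "FROM genes WHERE genome_id = ? ORDER BY contig_id, start",
                (genome_id,),
            )
        ]
        return ReferenceSet(genome_id=genome_id, contigs=contigs, genes=genes)

    def mapping_info(self, sample_id: str, genome_id: str) -> dict:
        row = self.conn.execute(
            "SELECT path, source_format, header FROM mappings "
            "WHERE sample_id = ? AND genome_id = ?",
            (sample_id, genome_id),
        ).fetchone()
        if row is None:
            raise KeyError(f"no mapping for ({sample_id!r}, {genome_id!r})")
        return {"path": row[0], "source_format": row[1], "header": row[2]}

    def genome_ids(self) -> list[str]:
        return [r[0] for r in self.conn.execute("SELECT genome_id FROM genomes ORDER BY genome_id")]

    def sample_ids(self) -> list[str]:
        return [r[0] for r in self.conn.execute("SELECT DISTINCT sample_id FROM mappings ORDER BY sample_id")]

    def _selection_sql(self, spec: FilterSpec) -> str:
        """The literal SQL implementing *spec* (parameters inlined for replay)."""
        if spec.best_hit_only:
            # rank every mapping of a read across ALL genomes first, so a
            # read whose best hit is on another genome is excluded entirely
            inner = (
                f"SELECT rid, {_READ_COLS}, ROW_NUMBER() OVER ("
                "PARTITION BY sample_id, read_id "
                "ORDER BY pct_id_local DESC, aln_columns DESC, genome_id ASC"
                ") AS hit_rank FROM reads "
                f"WHERE sample_id = {_sql_str(spec.sample_id)}"
            )
            clauses = ["hit_rank = 1"]
        else:
            inner = (
                f"SELECT rid, {_READ_COLS} FROM reads "
                f"WHERE sample_id = {_sql_str(spec.sample_id)}"
            )
            clauses = []
        clauses.append(f"genome_id = {_sql_str(spec.genome_id)}")
        if spec.min_aln_length > 0:
            clauses.append(f"aln_columns >= {spec.min_aln_length}")
        id_col = (
            "pct_id_local"
            if spec.identity_mode is IdentityMode.LOCAL
            else "pct_id_global"
        )
        if spec.min_identity > 0:
            clauses.append(f"{id_col} >= {spec.min_identity!r}")
        if spec.min_pct_read_aligned is not None:
            clauses.append(
                f"100.0 * read_consuming / read_length >= {spec.min_pct_read_aligned!r}"
            )
        return (
            f"SELECT {_READ_COLS} FROM ({inner}) "
            f"WHERE {' AND '.join(clauses)} ORDER BY rid"
        )

    def _check_spec(self, spec: FilterSpec) -> None:
        info = self.mapping_info(spec.sample_id, spec.genome_id)
        if info["source_format"] == "blast_tab":
            if spec.min_pct_read_aligned is not None:
                raise ValueError(
                    "minimum percent of the read aligning is not available "
                    "for tabular BLAST input"
                )
            if spec.identity_mode is IdentityMode.GLOBAL:
                raise ValueError("global identity unavailable for tabular BLAST input")

    def select_reads(self, spec: FilterSpec) -> tuple[list[AlignmentRecord], QueryRecord]:
        """Evaluate *spec*; returns the surviving records plus their query record."""
        self._check_spec(spec)
        sql = self._selection_sql(spec)
        records = self._run(sql)
        qr = QueryRecord(
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            database_path=str(self.path),
            filter_json=spec.to_json(),
            selection_expression=sql,
            records_selected=len(records),
        )
        return records, qr

    def replay(self, selection_expression: str) -> list[AlignmentRecord]:
        """Re-run a QueryRecord's literal selection expression."""
        return self._run(selection_expression)

    def _run(self, sql: str) -> list[AlignmentRecord]:
        out = []
        for row in self.conn.execute(sql):
            out.append(
                AlignmentRecord(
                    read_id=row[0], sample_id=row[1], genome_id=row[2], contig_id=row[3],
                    ref_start=row[4], ref_end=row[5], aln_columns=row[6], matches=row[7],
                    read_length=row[8], pct_id_local=row[9], pct_id_global=row[10],
                    read_consuming=row[11], source_format=row[12], source_line=row[13],
                )
            )
        return out


def build_database(
    refs: Sequence[ReferenceSet],
    mappings: Iterable[tuple[str | Path, str, str]],
    db_path: str | Path,
) -> RecruitDB:
    """Create a database from references and (path, sample_id, genome_id) mappings."""
    known = {r.genome_id for r in refs}
    db = RecruitDB(db_path)
    for ref in refs:
        db.add_reference(ref)
    for path, sample_id, genome_id in mappings:
        if genome_id not in known:
            db.close()
            raise ValueError(f"mapping {path} names unknown genome {genome_id!r}")
        db.add_mapping(path, sample_id, genome_id)
    return db
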
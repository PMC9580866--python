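"""Shared fixtures: a 3-read toy dataset, a per-base brute-force oracle,
and a small simulated two-population dataset used across modules."""

from __future__ import annotations

import numpy as np
import pytest

from recruitplot import (
    AlignmentRecord,
    BinLayout,
    Contig,
    FilterSpec,
    IdentityMode,
    IdentityWindows,
    PopulationSpec,
    ReferenceSet,
    build_database,
    compute_identity,
)
from recruitplot.simulate import simulate_reads, simulate_reference


def make_record(
    read_id: str,
    ref_start: int,
    ref_end: int,
    pct_id: float,
    contig_id: str = "c1",
    genome_id: str = "g1",
    sample_id: str = "s1",
    aln_columns: int | None = None,
    read_length: int | None = None,
    source_format: str = "sam",
) -> AlignmentRecord:
    """Build a consistent AlignmentRecord from an interval and an identity."""
    aln = aln_columns if aln_columns is not None else ref_end - ref_start
    matches = int(round(pct_id * aln / 100.0))
    rl = read_length if read_length is not None else aln
    return AlignmentRecord(
        read_id=read_id,
        sample_id=sample_id,
        genome_id=genome_id,
        contig_id=contig_id,
        ref_start=ref_start,
        ref_end=ref_end,
        aln_columns=aln,
        matches=matches,
        read_length=None if source_format == "blast_tab" else rl,
        pct_id_local=pct_id,
        pct_id_global=None if source_format == "blast_tab" else 100.0 * matches / rl,
        source_format=source_format,
        source_line=f"{read_id}\tsynthetic",
        read_consuming=None if source_format == "blast_tab" else aln,
    )


def brute_force_matrix(records, layout: BinLayout, windows: IdentityWindows,
                       mode=IdentityMode.LOCAL) -> np.ndarray:
    """Per-base oracle: assign every reference base of every record to its
    column by linear scan, one identity row per record."""
    counts = np.zeros((windows.n_windows, layout.n_columns))
    colmap: dict[tuple[str, int], int] = {}
    for j, col in enumerate(layout.columns):
        for p in range(col.start, col.end):
            colmap[(col.contig_id, p)] = j
    for rec in records:
        ident = compute_identity(rec, mode)
        if ident < windows.min_identity - 1e-9:
            continue
        row = windows.row_of(ident)
        for p in range(rec.ref_start, rec.ref_end):
            counts[row, colmap[(rec.contig_id, p)]] += 1
    return counts


@pytest.fixture
def toy_ref() -> ReferenceSet:
    """A single 3000 bp contig."""
    return ReferenceSet(genome_id="g1", contigs=[Contig(id="c1", length=3000, offset=0)])


@pytest.fixture
def toy_records() -> list[AlignmentRecord]:
    """Three 100 bp reads: 98.0%, 95.0% (spanning a bin boundary), 94.0%."""
    return [
        make_record("r1", 0, 100, 98.0),
        make_record("r2", 950, 1050, 95.0),
        make_record("r3", 2000, 2100, 94.0),
    ]


TWO_POP_SEED = 20260919
HOLE = (10_000, 15_000)  # aligned to 1 kb bin edges


@pytest.fixture(scope="session")
def two_pop_sim(tmp_path_factory):
    """A 30 kb reference with the canonical two-population structure:
    target 98.5+/-0.5% at 20x, co-occurring 94.0+/-0.5% at 5x, and a
    5 kb region no population covers (gene-content hole)."""
    out = tmp_path_factory.mktemp("two_pop")
    simref = simulate_reference(30_000, 2, TWO_POP_SEED, out)
    hole = (simref.ref.contigs[0].id, *HOLE)
    sam, blast, truth = simulate_reads(
        simref,
        [
            PopulationSpec(98.5, 0.5, 20.0, excluded_region=hole),
            PopulationSpec(94.0, 0.5, 5.0, excluded_region=hole),
        ],
        out,
        seed=TWO_POP_SEED + 1,
    )
    return {
        "simref": simref,
        "sam": sam,
        "blast": blast,
        "truth": truth,
        "hole": hole,
        "out": out,
    }


@pytest.fixture(scope="session")
def two_pop_db(two_pop_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("two_pop_db")
    simref = two_pop_sim["simref"]
    db = build_database(
        [simref.ref], [(two_pop_sim["sam"], "s1", simref.ref.genome_id)],
        out / "recruit.sqlite",
    )
    yield db
    db.close()


@pytest.fixture
def default_spec(two_pop_sim) -> FilterSpec:
    return FilterSpec(
        genome_id=two_pop_sim["simref"].ref.genome_id, sample_id="s1"
    )
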
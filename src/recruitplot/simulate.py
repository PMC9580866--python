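"""Synthetic references, populations, and matched SAM + BLAST mappings.

The generator emulates the structure of sequence-discrete populations:
reads of a target population sit at ~95-100% identity to the reference
while co-occurring populations sit lower, and a population may carry an
``excluded_region`` it never covers — a reference region (e.g. a gene
cluster) absent from the sampled population, which shows up downstream
as a zero-coverage hole.

Per-read identity is drawn from a truncated normal (capped at 100) and
converted to an integer mismatch count over the read length; mismatches
only, so the SAM record (CIGAR/NM) and the outfmt-6 row describe the
exact same alignment and cross-format results agree exactly.  An
optional indel rate exercises the gapped path; it is excluded from
cross-format equality since outfmt 6 cannot express gap placement.

The default read length is 200 bp so the realised identity grid
(multiples of 100/read_length) aligns with the default 0.5% identity
windows; a misaligned grid would alias into a sawtooth identity
histogram that no real read set shows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_io import Contig, ReferenceSet

__all__ = [
    "PopulationSpec",
    "SimulatedReference",
    "simulate_reference",
    "simulate_reads",
    "DEFAULT_READ_LENGTH",
]

DEFAULT_READ_LENGTH = 200

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population mapping onto the reference.

    mean_identity/identity_sd parameterise the truncated normal of
    per-read identity (percent); coverage is the expected x-fold depth
    over the region the population can cover; excluded_region is an
    optional (contig_id, start, end) interval the population never
    touches, emulating gene-content difference.
    """

    mean_identity: float
    identity_sd: float
    coverage: float
    excluded_region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mean_identity <= 100:
            raise ValueError("mean_identity must be in (0, 100]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class SimulatedReference:
    """A written FASTA plus its ReferenceSet and raw sequences."""

    ref: ReferenceSet
    sequences: dict[str, np.ndarray]  # contig_id -> byte array
    fasta_path: Path


def simulate_reference(
    length: int,
    n_contigs: int,
    seed: int,
    out_dir: str | Path,
    genome_id: str = "sim_genome",
) -> SimulatedReference:
    """Write a random reference genome of *length* bp over *n_contigs* contigs.

    Contig lengths split near-evenly; deterministic for a fixed seed.
    """
    if n_contigs < 1 or length < n_contigs:
        raise ValueError("need length >= n_contigs >= 1")
    rng = np.random.default_rng(seed)
    base_len, extra = divmod(length, n_contigs)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / f"{genome_id}.fasta"
    contigs: list[Contig] = []
    sequences: dict[str, np.ndarray] = {}
    offset = 0
    with open(fasta_path, "w") as fh:
        for i in range(n_contigs):
            clen = base_len + (1 if i < extra else 0)
            cid = f"{genome_id}_c{i + 1}"
            seq = _BASES[rng.integers(0, 4, size=clen)]
            sequences[cid] = seq
            fh.write(f">{cid}\n")
            raw = seq.tobytes().decode()
            for j in range(0, clen, 70):
                fh.write(raw[j : j + 70] + "\n")
            contigs.append(Contig(id=cid, length=clen, offset=offset))
            offset += clen
    ref = ReferenceSet(genome_id=genome_id, contigs=contigs)
    return SimulatedReference(ref=ref, sequences=sequences, fasta_path=fasta_path)


def _allowed_starts(
    ref: ReferenceSet, read_length: int, excluded: tuple[str, int, int] | None
) -> list[tuple[str, int, int]]:
    """Per contig, (contig_id, lo, hi) ranges of allowed read start positions."""
    out = []
    for c in ref.contigs:
        hi = c.length - read_length
        if hi < 0:
            continue
        if excluded and excluded[0] == c.id:
            _, ex_lo, ex_hi = excluded
            # a read starting in [ex_lo - L + 1, ex_hi) would intersect
            left_hi = min(hi + 1, max(0, ex_lo - read_length + 1))
            if left_hi > 0:
                out.append((c.id, 0, left_hi))
            if ex_hi <= hi:
                out.append((c.id, ex_hi, hi + 1))
        else:
            out.append((c.id, 0, hi + 1))
    return out


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    read = seq.copy()
    for p in positions:
        orig = read[p]
        choices = _BASES[_BASES != orig]
        read[p] = rng.choice(choices)
    return read


def simulate_reads(
    simref: SimulatedReference,
    populations: list[PopulationSpec],
    out_dir: str | Path,
    read_length: int = DEFAULT_READ_LENGTH,
    seed: int = 0,
    sample_id: str = "sim_sample",
    indel_rate: float = 0.0,
    prefix: str = "sim_reads",
) -> tuple[Path, Path, pd.DataFrame]:
    """Emit matched SAM + outfmt-6 BLAST files and a truth table.

    Reads are placed uniformly over each population's allowed start
    positions until expected coverage is met.  Returns
    (sam_path, blast_path, truth table); the truth table records, per
    read, the population index, true reference interval, match count
    and read length, consistent with both emitted files.
    """
    ref = simref.ref
    if read_length > min(c.length for c in ref.contigs):
        raise ValueError("read_length exceeds the shortest contig")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sam_path = out_dir / f"{prefix}.sam"
    blast_path = out_dir / f"{prefix}.blast.tsv"

    sam_lines: list[str] = []
    blast_lines: list[str] = []
    truth_rows: list[dict] = []
    read_no = 0

    for pop_idx, pop in enumerate(populations):
        ranges = _allowed_starts(ref, read_length, pop.excluded_region)
        allowed_total = sum(hi - lo for _, lo, hi in ranges)
        if allowed_total == 0:
            raise ValueError(f"population {pop_idx} has no placement")
        coverable = allowed_total + read_length - 1  # approx span it can cover
        n_reads = max(1, int(round(pop.coverage * coverable / read_length)))
        weights = np.array([hi - lo for _, lo, hi in ranges], dtype=float)
        weights /= weights.sum()
        range_choice = rng.choice(len(ranges), size=n_reads, p=weights)
        identities = rng.normal(pop.mean_identity, pop.identity_sd, size=n_reads)
        identities = np.clip(identities, 0.0, 100.0)
        for k in range(n_reads):
            cid, lo, hi = ranges[range_choice[k]]
            start = int(rng.integers(lo, hi))
            n_mm = int(round((1.0 - identities[k] / 100.0) * read_length))
            n_mm = min(n_mm, read_length)
            read_no += 1
            rid = f"read_{read_no:06d}"
            if indel_rate > 0 and rng.random() < indel_rate:
                rec = _emit_gapped(
                    simref, cid, start, read_length, n_mm, rid, rng
                )
            else:
                rec = _emit_ungapped(simref, cid, start, read_length, n_mm, rid, rng)
            sam_lines.append(rec["sam"])
            if rec["blast"] is not None:
                blast_lines.append(rec["blast"])
            truth_rows.append(
                {
                    "read_id": rid,
                    "population": pop_idx,
                    "contig_id": cid,
                    "ref_start": rec["ref_start"],
                    "ref_end": rec["ref_end"],
                    "matches": rec["matches"],
                    "read_length": read_length,
                }
            )

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in ref.contigs:
        header.append(f"@SQ\tSN:{c.id}\tLN:{c.length}")
    sam_path.write_text("\n".join(header + sam_lines) + "\n")
    blast_path.write_text("\n".join(blast_lines) + ("\n" if blast_lines else ""))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "population", "contig_id", "ref_start", "ref_end",
            "matches", "read_length",
        ],
    )
    truth.to_csv(out_dir / f"{prefix}.truth.tsv", sep="\t", index=False)
    return sam_path, blast_path, truth


def _emit_ungapped(simref, cid, start, read_length, n_mm, rid, rng) -> dict:
    seq = simref.sequences[cid][start : start + read_length]
    mm_pos = rng.choice(read_length, size=n_mm, replace=False) if n_mm else np.array([], dtype=int)
    read = _mutate(seq, mm_pos, rng)
    matches = read_length - n_mm
    reverse = bool(rng.random() < 0.5)
    flag = 16 if reverse else 0
    # SAM stores SEQ in reference orientation; the BLAST row below flips
    # subject coordinates instead, so both describe the same placement.
    read_txt = read.tobytes().decode()
    sam = (
        f"{rid}\t{flag}\t{cid}\t{start + 1}\t60\t{read_length}M\t*\t0\t0\t"
        f"{read_txt}\t*\tNM:i:{n_mm}"
    )
    pident = 100.0 * matches / read_length
    if reverse:
        sstart, send = start + read_length, start + 1
        qstart, qend = 1, read_length
    else:
        sstart, send = start + 1, start + read_length
        qstart, qend = 1, read_length
    blast = (
        f"{rid}\t{cid}\t{pident:.3f}\t{read_length}\t{n_mm}\t0\t"
        f"{qstart}\t{qend}\t{sstart}\t{send}\t1e-30\t{matches * 2}"
    )
    return {
        "sam": sam,
        "blast": blast,
        "ref_start": start,
        "ref_end": start + read_length,
        "matches": matches,
    }


def _emit_gapped(simref, cid, start, read_length, n_mm, rid, rng) -> dict:
    """A read with one small deletion relative to the reference (SAM only)."""
    contig = simref.sequences[cid]
    del_len = int(rng.integers(1, 4))
    ref_span = read_length + del_len
    if start + ref_span > len(contig):
        start = len(contig) - ref_span
    del_at = int(rng.integers(10, read_length - 10))
    ref_seq = contig[start : start + ref_span]
    read = np.concatenate([ref_seq[:del_at], ref_seq[del_at + del_len :]])
    mm_pos = rng.choice(read_length, size=n_mm, replace=False) if n_mm else np.array([], dtype=int)
    read = _mutate(read, mm_pos, rng)
    aln_columns = read_length + del_len
    matches = read_length - n_mm
    nm = n_mm + del_len
    cigar = f"{del_at}M{del_len}D{read_length - del_at}M"
    sam = (
        f"{rid}\t0\t{cid}\t{start + 1}\t60\t{cigar}\t*\t0\t0\t"
        f"{read.tobytes().decode()}\t*\tNM:i:{nm}"
    )
    return {
        "sam": sam,
        "blast": None,
        "ref_start": start,
        "ref_end": start + ref_span,
        "matches": matches,
    }
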
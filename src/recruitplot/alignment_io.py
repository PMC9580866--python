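"""Read-mapping records from tabular BLAST and SAM/BAM.

Every mapping becomes one :class:`AlignmentRecord`, the atom of all
downstream computation.  Two percent-identity definitions are carried:

* **local** — identical columns / alignment columns (gap columns included),
  the BLAST-style definition;
* **global** — identical columns / full read length, counting unaligned
  (soft-clipped) read bases against the read.  Unavailable for tabular
  BLAST input, which does not record the read's full length.

The original input line is retained verbatim on each record so that
filtered exports re-emit inputs byte-identically (BAM is re-emitted as
SAM text).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

log = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "IdentityMode",
    "UNKNOWN",
    "parse_blast_tab",
    "parse_sam",
    "sam_header_text",
    "compute_identity",
    "write_filtered",
    "sniff_format",
]

#: Sentinel for fields tabular BLAST cannot supply (read length, global identity).
UNKNOWN = None


class IdentityMode(str, enum.Enum):
    """Which percent-identity definition to use."""

    LOCAL = "local"
    GLOBAL = "global"


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference mapping with derived identities.

    Coordinates are 0-based half-open on the reference.  ``aln_columns``
    counts alignment columns including gaps (M/=/X/I/D); ``matches``
    counts identical columns.  ``read_consuming`` counts read bases in
    the alignment (M/=/X/I) and backs the percent-of-read-aligned filter.
    """

    read_id: str
    sample_id: str
    genome_id: str
    contig_id: str
    ref_start: int
    ref_end: int
    aln_columns: int
    matches: int
    read_length: int | None
    pct_id_local: float
    pct_id_global: float | None
    source_format: str  # "blast_tab" | "sam"
    source_line: str
    read_consuming: int | None = None

    def __post_init__(self) -> None:
        if not self.ref_start < self.ref_end:
            raise ValueError(
                f"{self.read_id}: empty reference interval "
                f"[{self.ref_start}, {self.ref_end})"
            )
        if not 0 <= self.matches <= self.aln_columns:
            raise ValueError(f"{self.read_id}: matches outside [0, aln_columns]")
        if self.ref_end - self.ref_start > self.aln_columns:
            raise ValueError(f"{self.read_id}: reference span exceeds alignment columns")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


def compute_identity(rec: AlignmentRecord, mode: IdentityMode) -> float:
    """Return the record's percent identity under *mode*."""
    mode = IdentityMode(mode)
    if mode is IdentityMode.LOCAL:
        return rec.pct_id_local
    if rec.source_format == "blast_tab":
        raise ValueError("global identity unavailable for tabular BLAST input")
    if rec.pct_id_global is UNKNOWN:
        raise ValueError(f"{rec.read_id}: read length unknown; global identity undefined")
    return rec.pct_id_global


# ---------------------------------------------------------------------------
# Tabular BLAST (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_MIN_COLS = 12


def parse_blast_tab(
    path: str | Path, sample_id: str, genome_id: str
) -> Iterator[AlignmentRecord]:
    """Stream records from a 12+ column outfmt-6 file.

    ``matches`` is recovered as ``round(pident * length / 100)`` since
    outfmt 6 prints pident, not the match count; the local identity is
    the printed pident verbatim to avoid double rounding.  A subject
    interval with sstart > send (minus strand) is stored reversed.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _BLAST_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_BLAST_MIN_COLS} columns, "
                    f"got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                sstart = int(fields[8])
                send = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
            matches = int(pident * length / 100.0 + 0.5)
            lo, hi = (sstart, send) if sstart <= send else (send, sstart)
            yield AlignmentRecord(
                read_id=fields[0],
                sample_id=sample_id,
                genome_id=genome_id,
                contig_id=fields[1],
                ref_start=lo - 1,
                ref_end=hi,
                aln_columns=length,
                matches=matches,
                read_length=UNKNOWN,
                pct_id_local=pident,
                pct_id_global=UNKNOWN,
                source_format="blast_tab",
                source_line=line,
                read_consuming=UNKNOWN,
            )


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------

# CIGAR op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_ALN_OPS = {0, 1, 2, 7, 8}  # alignment columns (gap columns count)
_READ_OPS = {0, 1, 7, 8}  # read-consuming aligned ops
_MATCH_COL_OPS = {0, 7, 8}  # columns pairing a read base with a ref base

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _md_mismatches(md: str) -> int:
    n = 0
    for num, deletion, sub in _MD_TOKEN.findall(md):
        if sub:
            n += 1
    return n


def _is_bam(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(2) == b"\x1f\x8b"


def sam_header_text(path: str | Path) -> str:
    """Return the header of a SAM/BAM file as SAM text."""
    path = Path(path)
    mode = "rb" if _is_bam(path) else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        return str(af.header)


def _record_from_segment(
    seg: pysam.AlignedSegment,
    sample_id: str,
    genome_id: str,
    source_line: str,
) -> AlignmentRecord | None:
    cig = seg.cigartuples
    if cig is None:
        return None
    aln_columns = sum(ln for op, ln in cig if op in _ALN_OPS)
    read_consuming = sum(ln for op, ln in cig if op in _READ_OPS)
    match_cols = sum(ln for op, ln in cig if op in _MATCH_COL_OPS)
    if aln_columns == 0:
        return None

    if seg.has_tag("NM"):
        matches = aln_columns - int(seg.get_tag("NM"))
    elif seg.has_tag("MD"):
        matches = match_cols - _md_mismatches(str(seg.get_tag("MD")))
    elif any(op in (7, 8) for op, _ in cig):
        matches = sum(ln for op, ln in cig if op == 7)
    else:
        return None  # identity uncomputable

    # query_length covers SEQ including soft clips; hard-clipped bases
    # are unrecoverable and excluded.
    read_length = seg.query_length or seg.infer_query_length()
    pct_local = 100.0 * matches / aln_columns
    pct_global = 100.0 * matches / read_length if read_length else UNKNOWN
    return AlignmentRecord(
        read_id=seg.query_name,
        sample_id=sample_id,
        genome_id=genome_id,
        contig_id=seg.reference_name,
        ref_start=seg.reference_start,
        ref_end=seg.reference_end,
        aln_columns=aln_columns,
        matches=matches,
        read_length=read_length if read_length else UNKNOWN,
        pct_id_local=pct_local,
        pct_id_global=pct_global,
        source_format="sam",
        source_line=source_line,
        read_consuming=read_consuming,
    )


def parse_sam(
    path: str | Path, sample_id: str, genome_id: str
) -> Iterator[AlignmentRecord]:
    """Stream primary mapped records from a SAM or BAM file.

    Unmapped, secondary and supplementary records are skipped (counts
    logged), as are records whose identity cannot be derived from NM,
    MD, or =/X CIGAR ops.  For SAM text input the raw line is retained
    so filtered exports are byte-identical; BAM records are rendered to
    SAM text.
    """
    path = Path(path)
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0, "no_identity": 0}
    hard_clip_seen = False

    if _is_bam(path):
        with pysam.AlignmentFile(str(path), "rb") as af:
            for seg in af:
                rec = _screen_segment(seg, skipped)
                if rec is None:
                    continue
                out = _record_from_segment(seg, sample_id, genome_id, seg.to_string())
                if out is None:
                    skipped["no_identity"] += 1
                    continue
                if not hard_clip_seen and any(op == 5 for op, _ in seg.cigartuples):
                    log.warning("%s: hard-clipped bases excluded from read length", path)
                    hard_clip_seen = True
                yield out
    else:
        header_lines: list[str] = []
        body: list[str] = []
        with open(path) as fh:
            for line in fh:
                (header_lines if line.startswith("@") else body).append(line.rstrip("\n"))
        header = pysam.AlignmentHeader.from_text("\n".join(header_lines) + "\n")
        for line in body:
            if not line.strip():
                continue
            seg = pysam.AlignedSegment.fromstring(line, header)
            if _screen_segment(seg, skipped) is None:
                continue
            out = _record_from_segment(seg, sample_id, genome_id, line)
            if out is None:
                skipped["no_identity"] += 1
                continue
            if not hard_clip_seen and any(op == 5 for op, _ in seg.cigartuples):
                log.warning("%s: hard-clipped bases excluded from read length", path)
                hard_clip_seen = True
            yield out

    for reason, n in skipped.items():
        if n:
            log.info("%s: skipped %d %s record(s)", path, n, reason)


def _screen_segment(seg: pysam.AlignedSegment, skipped: dict) -> pysam.AlignedSegment | None:
    if seg.is_unmapped:
        skipped["unmapped"] += 1
        return None
    if seg.is_secondary:
        skipped["secondary"] += 1
        return None
    if seg.is_supplementary:
        skipped["supplementary"] += 1
        return None
    if seg.cigartuples is None:
        skipped["unmapped"] += 1
        return None
    return seg


# ---------------------------------------------------------------------------
# Filtered export
# ---------------------------------------------------------------------------


def sniff_format(path: str | Path) -> str:
    """Guess 'sam' or 'blast_tab' from content (BAM counts as 'sam')."""
    path = Path(path)
    if _is_bam(path):
        return "sam"
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("@"):
                return "sam"
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 11 and fields[5] != "" and not _looks_blast(fields):
                return "sam"
            return "blast_tab"
    return "blast_tab"


def _looks_blast(fields: list[str]) -> bool:
    if len(fields) < _BLAST_MIN_COLS:
        return False
    try:
        float(fields[2]); int(fields[3]); int(fields[8]); int(fields[9])
    except ValueError:
        return False
    return True


def write_filtered(
    records: Iterable[AlignmentRecord],
    out_path: str | Path,
    header_text: str | None = None,
) -> int:
    """Write records back out in their input format; returns the count.

    BLAST rows and SAM text lines are re-emitted verbatim; records
    parsed from BAM come out as SAM text under *header_text* (the
    original header).  All records must share one source format.
    An empty selection yields a header-only SAM or an empty BLAST file.
    """
    out_path = Path(out_path)
    records = list(records)
    formats = {r.source_format for r in records}
    if len(formats) > 1:
        raise ValueError(f"mixed source formats in one export: {sorted(formats)}")
    fmt = formats.pop() if formats else ("sam" if header_text else "blast_tab")
    with open(out_path, "w") as fh:
        if fmt == "sam" and header_text:
            fh.write(header_text if header_text.endswith("\n") else header_text + "\n")
        for rec in records:
            fh.write(rec.source_line + "\n")
    return len(records)
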
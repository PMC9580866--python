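"""Reference genomes and gene annotations.

A recruitment plot's x-axis is the reference genome laid out as one
concatenated coordinate axis: contigs appear in FASTA file order, each
with a cumulative ``offset`` so that global position ``offset + p`` maps
uniquely back to ``(contig, p)``.  Only contig lengths are kept; the
sequences themselves are never needed downstream.

All internal coordinates are 0-based half-open.  GFF (1-based inclusive)
is converted at the parse boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = ["Contig", "GeneAnnotation", "ReferenceSet", "read_fasta", "read_gff"]


@dataclass(frozen=True)
class Contig:
    """One reference sequence: id, length, and cumulative start offset."""

    id: str
    length: int
    offset: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: length must be >= 1")
        if self.offset < 0:
            raise ValueError(f"contig {self.id!r}: negative offset")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene (or CDS) interval on a contig, 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class ReferenceSet:
    """An ordered collection of contigs (one genome) plus optional genes."""

    genome_id: str
    contigs: list[Contig]
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {c.id: c for c in self.contigs}
        expected = 0
        for c in self.contigs:
            if c.offset != expected:
                raise ValueError(
                    f"contig {c.id!r}: offset {c.offset} != cumulative sum {expected}"
                )
            expected += c.length
        for g in self.genes:
            ctg = self._by_id.get(g.contig_id)
            if ctg is None:
                raise ValueError(f"gene {g.gene_id!r} on unknown contig {g.contig_id!r}")
            if g.end > ctg.length:
                raise ValueError(
                    f"gene {g.gene_id!r} extends past contig {g.contig_id!r} "
                    f"({g.end} > {ctg.length})"
                )

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def contig(self, contig_id: str) -> Contig:
        try:
            return self._by_id[contig_id]
        except KeyError:
            raise KeyError(f"unknown contig {contig_id!r}") from None

    def has_contig(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a concatenated-axis position back to (contig_id, local position)."""
        if not 0 <= global_pos < self.total_length:
            raise ValueError(f"position {global_pos} outside [0, {self.total_length})")
        for c in self.contigs:
            if global_pos < c.offset + c.length:
                return c.id, global_pos - c.offset
        raise AssertionError("unreachable")


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, genome_id: str | None = None) -> ReferenceSet:
    """Load a FASTA file (plain or gzip) as one genome.

    One file is one genome; every record becomes a contig with its offset
    taken from cumulative file order.  Sequences are discarded after
    measuring their lengths.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.name
        for suffix in (".gz", ".fasta", ".fa", ".fna"):
            if genome_id.endswith(suffix):
                genome_id = genome_id[: -len(suffix)]
    contigs: list[Contig] = []
    seen: set[str] = set()
    offset = 0
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            contigs.append(Contig(id=rec.id, length=len(rec.seq), offset=offset))
            offset += len(rec.seq)
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return ReferenceSet(genome_id=genome_id, contigs=contigs)


def _validate_gff_lines(path: Path) -> None:
    # gffutils reports parse failures without line numbers; check the
    # coordinate columns up front so errors can name the offending line.
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected >= 8 GFF columns")
            for col in (3, 4):
                if not fields[col].isdigit():
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric coordinate {fields[col]!r}"
                    )


def read_gff(
    path: str | Path,
    ref: ReferenceSet,
    feature_types: tuple[str, ...] | None = None,
) -> list[GeneAnnotation]:
    """Parse gene intervals from GFF3 for gene-anchored binning.

    Features of type ``gene`` are used when present, otherwise ``CDS``
    (override with *feature_types*).  GFF's 1-based inclusive coordinates
    become 0-based half-open.  Features on contigs absent from *ref* are
    dropped with a logged warning count.
    """
    import gffutils

    path = Path(path)
    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            keep_order=True,
            merge_strategy="create_unique",
            from_string=False,
        )
    except Exception as exc:
        if "empty" in str(exc).lower() or _gff_is_empty(path):
            return []
        raise
    present = {f.lower() for f in db.featuretypes()}
    if feature_types is None:
        feature_types = ("gene",) if "gene" in present else ("CDS",)
    wanted = {t.lower() for t in feature_types}

    genes: list[GeneAnnotation] = []
    dropped = 0
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype.lower() not in wanted:
            continue
        if not ref.has_contig(feat.seqid):
            dropped += 1
            continue
        attrs = feat.attributes
        gene_id = feat.id
        for key in ("ID", "gene_id", "locus_tag", "Name"):
            if key in attrs and attrs[key]:
                gene_id = attrs[key][0]
                break
        product = attrs["product"][0] if "product" in attrs and attrs["product"] else ""
        genes.append(
            GeneAnnotation(
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
                gene_id=gene_id,
                product=product,
            )
        )
    if dropped:
        log.warning(
            "%s: dropped %d feature(s) on contigs absent from reference %r",
            path,
            dropped,
            ref.genome_id,
        )
    return genes


def _gff_is_empty(path: Path) -> bool:
    with _open_text(path) as fh:
        return not any(line.strip() and not line.startswith("#") for line in fh)
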
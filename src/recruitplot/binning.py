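"""Position x identity binning: the 2-D bases matrix behind the main panel.

Columns tile the concatenated genome axis, either as fixed-width windows
(default 1000 bp, last window truncated at each contig end) or anchored
to gene starts/ends with intergenic filler columns.  Rows are percent
identity windows (default 0.5%) anchored at multiples of the window
height, so the 95% population threshold coincides with a window edge.
Each cell holds the total number of read bases mapping into it: a read
contributes its reference span, split across columns exactly where it
mapped, to the single row holding its identity.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import AlignmentRecord, IdentityMode, compute_identity
from .reference_io import ReferenceSet

log = logging.getLogger(__name__)

__all__ = [
    "BinColumn",
    "BinLayout",
    "IdentityWindows",
    "RecruitmentMatrix",
    "make_position_bins",
    "fill_matrix",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_WINDOW_HEIGHT",
    "DEFAULT_POPULATION_THRESHOLD",
]

DEFAULT_BIN_WIDTH = 1000
DEFAULT_WINDOW_HEIGHT = 0.5
DEFAULT_POPULATION_THRESHOLD = 95.0

_EPS = 1e-9


@dataclass(frozen=True)
class BinColumn:
    """One genome-position column: a half-open interval on one contig."""

    contig_id: str
    start: int
    end: int
    label: str  # "window", "gene:<id>[+<id>...]", or "intergenic"

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class BinLayout:
    """Ordered genome-position columns tiling every contig exactly."""

    columns: list[BinColumn]
    bin_width: int
    gene_mode: bool

    def __post_init__(self) -> None:
        self._validate()
        self._index()

    def _validate(self) -> None:
        pos: dict[str, int] = {}
        for col in self.columns:
            expected = pos.get(col.contig_id, 0)
            if col.start != expected:
                raise ValueError(
                    f"columns do not tile contig {col.contig_id!r}: "
                    f"gap/overlap at {col.start} (expected {expected})"
                )
            if col.end <= col.start:
                raise ValueError(f"empty column on {col.contig_id!r} at {col.start}")
            pos[col.contig_id] = col.end

    def _index(self) -> None:
        # per contig: (first column index, list of column start positions)
        self._per_contig: dict[str, tuple[int, list[int], int]] = {}
        for i, col in enumerate(self.columns):
            if col.contig_id not in self._per_contig:
                self._per_contig[col.contig_id] = (i, [], 0)
            first, starts, _ = self._per_contig[col.contig_id]
            starts.append(col.start)
            self._per_contig[col.contig_id] = (first, starts, col.end)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def contig_ids(self) -> list[str]:
        seen: list[str] = []
        for col in self.columns:
            if not seen or seen[-1] != col.contig_id:
                seen.append(col.contig_id)
        return seen

    def overlaps(self, contig_id: str, start: int, end: int) -> list[tuple[int, int]]:
        """Column indices overlapping [start, end) with overlap lengths."""
        if contig_id not in self._per_contig:
            raise KeyError(f"record on unknown contig {contig_id!r}")
        first, starts, contig_end = self._per_contig[contig_id]
        if not (0 <= start < end):
            raise ValueError(f"bad interval [{start}, {end}) on {contig_id!r}")
        out: list[tuple[int, int]] = []
        i = bisect.bisect_right(starts, start) - 1
        while i < len(starts):
            col = self.columns[first + i]
            lo = max(start, col.start)
            hi = min(end, col.end)
            if hi <= lo:
                break
            out.append((first + i, hi - lo))
            i += 1
        return out


@dataclass
class IdentityWindows:
    """Ascending identity windows [lo, lo+h) with a closed top window.

    Edges are multiples of *window_height* from *min_identity* up to 100;
    the top window is [100-h, 100] closed so perfect matches are
    representable.  Every identity in [min_identity, 100] falls in
    exactly one window.
    """

    window_height: float = DEFAULT_WINDOW_HEIGHT
    min_identity: float = 0.0
    edges: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        h = self.window_height
        if h <= 0 or h > 100:
            raise ValueError(f"window height {h} out of range (0, 100]")
        # snap the floor down to a multiple of h so windows stay anchored at 0
        lo = math.floor(self.min_identity / h + _EPS) * h
        lo = min(lo, 100.0 - h)
        n = int(round((100.0 - lo) / h))
        self.min_identity = lo
        self.edges = lo + h * np.arange(n + 1)
        self.edges[-1] = 100.0

    @classmethod
    def from_identities(
        cls, identities: Iterable[float], window_height: float = DEFAULT_WINDOW_HEIGHT
    ) -> "IdentityWindows":
        """Windows floored (to an edge) at the lowest observed identity."""
        vals = list(identities)
        lo = min(vals) if vals else 0.0
        return cls(window_height=window_height, min_identity=lo)

    @property
    def n_windows(self) -> int:
        return len(self.edges) - 1

    def lower_edges(self) -> np.ndarray:
        return self.edges[:-1]

    def row_of(self, identity: float) -> int:
        """Window index for *identity*; raises if below the window range."""
        if identity > 100.0 + _EPS:
            raise ValueError(f"identity {identity} > 100")
        if identity >= 100.0 - _EPS:
            return self.n_windows - 1
        if identity < self.min_identity - _EPS:
            raise ValueError(f"identity {identity} below window floor {self.min_identity}")
        idx = int(math.floor((identity - self.min_identity) / self.window_height + _EPS))
        return min(idx, self.n_windows - 1)


@dataclass
class RecruitmentMatrix:
    """The bases-count grid: rows = identity windows, columns = genome bins."""

    layout: BinLayout
    windows: IdentityWindows
    counts: np.ndarray  # (n_windows, n_columns)
    population_threshold: float = DEFAULT_POPULATION_THRESHOLD

    def __post_init__(self) -> None:
        expected = (self.windows.n_windows, self.layout.n_columns)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if (self.counts < 0).any():
            raise ValueError("negative count in matrix")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def make_position_bins(
    ref: ReferenceSet,
    bin_width: int = DEFAULT_BIN_WIDTH,
    gene_mode: bool = False,
) -> BinLayout:
    """Tile every contig with position columns.

    Fixed mode: [0,w), [w,2w), ... per contig, final column truncated at
    the contig end (its true shorter span is kept; depth normalisation
    divides by true span).  Gene mode: one column per gene interval plus
    intergenic columns covering every gap; overlapping genes merge into
    one column labelled with all their ids.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    columns: list[BinColumn] = []
    if not gene_mode:
        for contig in ref.contigs:
            for start in range(0, contig.length, bin_width):
                end = min(start + bin_width, contig.length)
                columns.append(BinColumn(contig.id, start, end, "window"))
        return BinLayout(columns=columns, bin_width=bin_width, gene_mode=False)

    if not ref.genes:
        raise ValueError(
            "gene mode requires gene annotations: supply a GFF file when "
            "building the reference"
        )
    genes_by_contig: dict[str, list] = {}
    for g in ref.genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    for contig in ref.contigs:
        merged: list[tuple[int, int, list[str]]] = []
        for g in sorted(genes_by_contig.get(contig.id, []), key=lambda g: (g.start, g.end)):
            if merged and g.start < merged[-1][1]:
                lo, hi, ids = merged[-1]
                merged[-1] = (lo, max(hi, g.end), ids + [g.gene_id])
            else:
                merged.append((g.start, g.end, [g.gene_id]))
        pos = 0
        for lo, hi, ids in merged:
            if lo > pos:
                columns.append(BinColumn(contig.id, pos, lo, "intergenic"))
            columns.append(BinColumn(contig.id, lo, hi, "gene:" + "+".join(ids)))
            pos = hi
        if pos < contig.length:
            columns.append(BinColumn(contig.id, pos, contig.length, "intergenic"))
    return BinLayout(columns=columns, bin_width=bin_width, gene_mode=True)


def fill_matrix(
    records: Iterable[AlignmentRecord],
    layout: BinLayout,
    windows: IdentityWindows,
    mode: IdentityMode = IdentityMode.LOCAL,
    population_threshold: float = DEFAULT_POPULATION_THRESHOLD,
) -> RecruitmentMatrix:
    """Accumulate read bases into the (identity window, genome bin) grid.

    Each record lands in exactly one identity row; its reference span
    ref_end - ref_start is split across the columns it overlaps, so a
    record's total contribution equals its span exactly.  Insertions
    contribute to identity but not to positional counts.  Records with
    identity below the window floor are dropped with a logged count.
    """
    counts = np.zeros((windows.n_windows, layout.n_columns), dtype=np.float64)
    dropped_low = 0
    for rec in records:
        identity = compute_identity(rec, mode)
        if identity < windows.min_identity - _EPS:
            dropped_low += 1
            continue
        row = windows.row_of(identity)
        for col_idx, overlap in layout.overlaps(rec.contig_id, rec.ref_start, rec.ref_end):
            counts[row, col_idx] += overlap
    if dropped_low:
        log.info(
            "dropped %d record(s) below the %.3f%% identity window floor",
            dropped_low,
            windows.min_identity,
        )
    return RecruitmentMatrix(
        layout=layout,
        windows=windows,
        counts=counts,
        population_threshold=population_threshold,
    )
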
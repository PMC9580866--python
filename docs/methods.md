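# Methods

## The model

A recruitment plot summarises how a metagenome's reads map to one reference
genome. Natural bacterial and archaeal populations are typically
*sequence-discrete*: members share roughly 95–100% nucleotide identity with
each other, while distinct co-occurring populations sit below ~90–95%.
Plotting each mapped read's genome position against its percent identity to
the reference therefore separates the *target population* (the high-identity
band) from its relatives, and regions of the reference with no
high-identity coverage mark genes the sampled population does not carry.

Because real mappings run to millions of reads, the plot is backed by a 2-D
counts matrix rather than per-read glyphs. Columns are genome regions,
rows are percent-identity windows, and each cell accumulates the total
number of read bases mapping into it.

### The bases matrix

* **Columns.** Each contig is tiled with fixed-width windows (default
  1000 bp; the final window keeps its true, shorter span and depth is always
  normalised by true span). In *gene mode* the columns are instead the exact
  gene intervals from the GFF, with intergenic filler columns covering every
  gap; overlapping genes merge into one column carrying all their ids.
  Contigs are laid out on one concatenated axis in FASTA file order. No
  column ever spans a contig boundary.
* **Rows.** Identity windows of height *h* (default 0.5%), half-open
  [lo, lo+h), anchored at multiples of *h* so the 95% population threshold
  always coincides with a window edge. The top window is closed at 100 so a
  perfect match is representable. The displayed floor defaults to the lowest
  selected identity, floored to a window edge; it is user-overridable.
* **Filling.** A read contributes to exactly one identity row. Its
  *reference span* (ref_end − ref_start) is split across the columns it
  overlaps, exactly where it mapped; a read's total contribution equals its
  span. The reference span — not the raw read length — is what gets
  apportioned, because only the reference span can be divided by genome
  position when the alignment contains indels; inserted read bases count
  toward identity but not toward positional coverage.

### Percent identity

Two definitions are carried per record:

* **local** = matches / alignment columns, where alignment columns include
  gap columns (M/=/X/I/D in CIGAR terms) — the BLAST-style definition;
* **global** = matches / full read length, counting soft-clipped or
  otherwise unaligned read bases against the read. Unavailable for tabular
  BLAST input (outfmt 6 does not record the read's full length); hard-clipped
  bases are unrecoverable from SAM and are excluded with a warning.

Matches are taken as alignment columns − NM when the NM tag is present,
else from the MD tag, else from =/X CIGAR ops; a record with none of these
is skipped, counted, and logged. For outfmt 6, matches =
round(pident·length/100) and the local identity is the printed pident
verbatim, avoiding double rounding.

### Filtering and the database

Parsed records (primary alignments only; secondary and supplementary
records are dropped to prevent double-counting bases) are persisted in a
single-file SQLite database indexed by read name and by (sample, genome).
A selection applies, in order: best-hit ranking, then thresholds.

* **Best-hit-only** (default on): each read keeps the single best record
  across *all* genomes in the database — highest local identity, ties broken
  by longer alignment, then lexicographically smallest genome id. A read
  whose best hit is on another genome is excluded entirely from the viewed
  genome. Ranking always uses local identity, regardless of the display
  mode, so the record set does not change when the user toggles the
  identity definition.
* Thresholds: alignment length ≥ *min_aln_length*; identity (under the
  selected mode) ≥ *min_identity* (≥, so the cart semantics "at or above" a
  cutoff hold); percent of the read aligned ≥ *min_pct_read_aligned*,
  computed as read-consuming alignment columns (M/=/X/I) over the full read
  length (rejected for BLAST input).

The literal SQL implementing the selection, with all parameters inlined, is
serialised into a query-record sidecar written next to every plot, TSV and
read export; replaying that SQL against the same database reproduces the
identical record set.

### Derived panels

* **Depth series**: per column, bases in rows at or above the population
  threshold divided by the column's true span ("within"), and the
  complement ("outside"). 95.0% itself counts as within-population,
  consistent with the ≥ cutoff semantics. Within + outside depth always
  reconstructs the column's total bases. A threshold that is not a window
  edge is snapped down with a warning.
* **Depth histogram**: each column contributes once per series to the bin
  containing its depth; zero-depth columns go to a dedicated zero bin since
  they indicate absent regions, not shallow ones. Default bin width is 1×
  when the maximum depth is below 10×, else max/50.
* **Identity histogram**: row sums of the matrix. Population peaks are
  detected as local maxima with prominence at least 2% of the tallest
  window, so a handful of stray tail reads does not register as a
  population; the sequence-discontinuity point between two peaks is the
  deepest interior window (ties resolve to the middle of the minimal run).

## The simulator

The generator emulates sequence-discrete population structure, not a
sequencing instrument. Per population it draws read start positions
uniformly over allowed placements until the expected coverage is met, and
per-read identity from a truncated normal (mean/sd in percent, capped at
100) converted to an integer mismatch count over the read length. An
`excluded_region` is never touched by that population's reads, emulating a
gene-content difference. Each read is emitted consistently as a SAM record
(CIGAR/NM/SEQ against the actual simulated reference sequence) and as an
outfmt-6 row, plus a truth-table entry.

Defaults define the study conditions used throughout the tests and the
acceptance script: target population 98.5 ± 0.5% at 20×, co-occurring
population 94.0 ± 0.5% at 5×, read length 200 bp, references of 30–50 kb.
The 200 bp read length makes the realised identity grid (multiples of
100/read length) align with the 0.5% windows; a misaligned grid would alias
into a sawtooth identity histogram no real read set shows. It also lets
BLAST's three-decimal pident round-trip to the exact match count, so SAM
and BLAST expressions of the same reads fill byte-identical matrices.

What the simulator does **not** model: sequencing error profiles, quality
scores, paired ends, chimeras, strain-level recombination, GC or coverage
bias. Passing tests therefore demonstrate the correctness of the binning,
filtering, summarisation and export machinery under idealised mappings —
not robustness to mapper-specific artifacts on real data. The optional
indel mode (single short deletion per affected read, SAM-only) exercises
the gapped-identity path but is excluded from cross-format equality, which
outfmt 6 cannot express.

## Numerical choices

* Coordinates are 0-based half-open internally; GFF/SAM/BLAST conventions
  are converted only at parse/write boundaries.
* Window membership uses an epsilon of 1e-9 when flooring identities onto
  window edges; identities exactly on an edge belong to the upper window.
* Counts are accumulated as float64; with integer base counts all
  conservation identities hold exactly, and tests assert exact equality
  against a per-base brute-force counter.
* TSV exports print coordinates 1-based inclusive (stated in the header
  comment) and numbers via a fixed `%.10g`-style format, so repeated
  exports are byte-identical and a re-imported matrix reproduces the
  derived panel TSVs byte-for-byte.
* Rendering produces vector PDF directly from matplotlib primitives; zero
  cells are masked (never offset before log scaling) and zero-depth columns
  are drawn as a discontinuous band at the bottom of the depth panel.

## Problem sizes

Tests and the acceptance script use 10–50 kb references at 5–20× coverage
(thousands of reads), sizes at which the planted population structure —
bimodal identity histogram, ~20× recovered depth, the zero-coverage hole —
is recovered stably across seeds while the full pipeline runs in seconds.

## Known limitations

* One FASTA file is one genome; multi-genome FASTA files are not split.
* Mates of a pair are independent records; there is no pair-aware
  filtering.
* CRAM input is not supported.
* Gene-level statistics beyond gene-anchored columns (e.g. per-gene allele
  diversity) are out of scope.
* The interactive (HTML) plot export of the original workflow is not
  implemented; the PDF and TSV exports carry the same information.
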
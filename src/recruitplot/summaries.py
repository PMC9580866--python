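"""Companion panels derived from the recruitment matrix.

Depth of coverage splits at the population threshold (default 95%):
rows at or above the threshold edge are "within" the target population,
rows below are co-occurring "outside" populations.  Depth per column is
total bases divided by the column's true span, so within + outside
always reconstructs the column total.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .binning import RecruitmentMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DepthSeries",
    "DepthHistogram",
    "IdentityHistogram",
    "depth_series",
    "depth_histogram",
    "identity_histogram",
]

_EPS = 1e-9


@dataclass
class DepthSeries:
    """Per-column within/outside-population x-fold coverage."""

    matrix: RecruitmentMatrix
    threshold: float
    depth_within: np.ndarray
    depth_outside: np.ndarray

    @property
    def n_columns(self) -> int:
        return len(self.depth_within)

    def spans(self) -> np.ndarray:
        return np.array([c.span for c in self.matrix.layout.columns], dtype=float)


@dataclass
class DepthHistogram:
    """Columns binned by depth value, per series, with an explicit zero bin.

    ``bins`` maps series name ('within'/'outside') to a list of
    (depth_lo, depth_hi, n_columns); the zero bin is (0.0, 0.0, n).
    """

    depth_bin_width: float
    bins: dict[str, list[tuple[float, float, int]]]

    def counts(self, series: str) -> list[int]:
        return [n for _, _, n in self.bins[series]]


@dataclass
class IdentityHistogram:
    """Total bases per identity window: row sums of the matrix."""

    window_lo: np.ndarray
    window_hi: np.ndarray
    bases: np.ndarray

    @property
    def total(self) -> float:
        return float(self.bases.sum())

    def local_maxima(self, min_prominence_frac: float = 0.02) -> list[int]:
        """Window indices of the histogram's population peaks.

        Peaks are local maxima with prominence at least
        *min_prominence_frac* of the tallest window, so shot noise from
        a handful of stray reads in a distribution tail does not
        register as a population.  Zero-padding lets a peak sit in the
        first or last window.
        """
        from scipy.signal import find_peaks

        b = self.bases
        if b.sum() <= 0:
            return []
        padded = np.concatenate([[0.0], b, [0.0]])
        idx, _ = find_peaks(padded, prominence=min_prominence_frac * float(b.max()))
        return [int(i) - 1 for i in idx]

    def interior_minimum(self, left_peak: int, right_peak: int) -> int:
        """Index of the deepest window strictly between two peaks.

        Ties (e.g. a run of empty windows) resolve to the middle of the
        minimal run: the point of sequence discontinuity between two
        populations.
        """
        if not 0 <= left_peak < right_peak < len(self.bases):
            raise ValueError("need left_peak < right_peak within range")
        seg = self.bases[left_peak + 1 : right_peak]
        if len(seg) == 0:
            raise ValueError("peaks are adjacent; no interior window")
        lo = seg.min()
        at = np.flatnonzero(seg == lo)
        return left_peak + 1 + int(at[(len(at) - 1) // 2])


def depth_series(matrix: RecruitmentMatrix, threshold: float | None = None) -> DepthSeries:
    """Split per-column coverage at the population identity threshold.

    *threshold* must coincide with a window edge; otherwise it is
    snapped down to the nearest edge with a warning.  Rows whose lower
    edge is at or above the threshold count as within-population.
    """
    if threshold is None:
        threshold = matrix.population_threshold
    w = matrix.windows
    edges = w.edges
    snapped = edges[edges <= threshold + _EPS]
    snap = float(snapped[-1]) if len(snapped) else float(edges[0])
    if abs(snap - threshold) > _EPS:
        log.warning(
            "threshold %.4f is not a window edge; snapped down to %.4f", threshold, snap
        )
    within_rows = w.lower_edges() >= snap - _EPS
    spans = np.array([c.span for c in matrix.layout.columns], dtype=float)
    bases_within = matrix.counts[within_rows].sum(axis=0)
    bases_outside = matrix.counts[~within_rows].sum(axis=0)
    return DepthSeries(
        matrix=matrix,
        threshold=snap,
        depth_within=bases_within / spans,
        depth_outside=bases_outside / spans,
    )


def _default_bin_width(max_depth: float) -> float:
    if max_depth <= 0:
        return 1.0
    return 1.0 if max_depth < 10.0 else max_depth / 50.0


def depth_histogram(series: DepthSeries, depth_bin_width: float | None = None) -> DepthHistogram:
    """Histogram of per-column depth values, within and outside series.

    Zero-depth columns go to a dedicated zero bin (they mark missing
    regions, not merely shallow ones); each column contributes exactly
    once per series.
    """
    max_depth = float(max(series.depth_within.max(initial=0.0),
                          series.depth_outside.max(initial=0.0)))
    if depth_bin_width is None:
        depth_bin_width = _default_bin_width(max_depth)
    if depth_bin_width <= 0:
        raise ValueError("depth_bin_width must be > 0")
    w = depth_bin_width
    bins: dict[str, list[tuple[float, float, int]]] = {}
    n_bins = max(1, int(math.floor(max_depth / w + _EPS)) + 1)
    for name, depths in (("within", series.depth_within), ("outside", series.depth_outside)):
        zero = int(np.sum(depths <= _EPS))
        nonzero = depths[depths > _EPS]
        idx = np.floor(nonzero / w + _EPS).astype(int)
        out = [(0.0, 0.0, zero)]
        for k in range(n_bins):
            out.append((k * w, (k + 1) * w, int(np.sum(idx == k))))
        bins[name] = out
    return DepthHistogram(depth_bin_width=w, bins=bins)


def identity_histogram(matrix: RecruitmentMatrix) -> IdentityHistogram:
    """Row sums of the matrix, ordered by identity window."""
    return IdentityHistogram(
        window_lo=matrix.windows.edges[:-1].copy(),
        window_hi=matrix.windows.edges[1:].copy(),
        bases=matrix.row_sums(),
    )
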
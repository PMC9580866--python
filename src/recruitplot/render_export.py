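"""Four-panel plot rendering (vector PDF) and tab-delimited data export.

Panel arrangement follows the classic recruitment-plot layout: the
position x identity heatmap bottom-left, the within/outside-population
depth series above it sharing the x-axis, the depth histogram top-right,
and the identity histogram bottom-right sharing the y-axis.  Every
export is accompanied by exactly one query-record sidecar when a
:class:`~recruitplot.recruit_db.QueryRecord` is supplied.

TSV coordinates are written 1-based inclusive for readability (stated
in the '#' comment header); they are converted back on import.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LogNorm

from .binning import BinColumn, BinLayout, IdentityWindows, RecruitmentMatrix
from .recruit_db import QueryRecord
from .summaries import (
    DepthHistogram,
    DepthSeries,
    IdentityHistogram,
    depth_histogram,
    depth_series,
    identity_histogram,
)

log = logging.getLogger(__name__)

__all__ = [
    "PlotStyle",
    "render_plot",
    "export_panel_data",
    "import_matrix_tsv",
    "derive_panels",
]

WITHIN_COLOR = "#1f4e8c"  # dark blue: target population
OUTSIDE_COLOR = "#9ecae1"  # light blue: co-occurring populations


@dataclass
class PlotStyle:
    aspect: tuple[int, int] = (16, 9)
    within_color: str = WITHIN_COLOR
    outside_color: str = OUTSIDE_COLOR
    log_matrix: bool = True  # logarithmic cell-fill scale
    log_depth: bool = True
    log_identity_counts: bool = True
    cmap: str = "Blues"


def _global_edges(layout: BinLayout) -> np.ndarray:
    """Column boundaries on the concatenated genome axis."""
    spans = np.array([c.span for c in layout.columns])
    return np.concatenate([[0], np.cumsum(spans)])


def render_plot(
    matrix: RecruitmentMatrix,
    depth: DepthSeries,
    dhist: DepthHistogram,
    ihist: IdentityHistogram,
    out_path: str | Path,
    style: PlotStyle | None = None,
    query_record: QueryRecord | None = None,
) -> Path:
    """Render the four-panel recruitment plot to a vector PDF.

    Zero cells are drawn empty (no offset is added before log scaling);
    zero-depth columns appear as a discontinuous band at the bottom of
    the depth panel.  An empty matrix still renders, annotated
    "no reads selected".
    """
    style = style or PlotStyle()
    out_path = Path(out_path)
    w, h = style.aspect
    fig = plt.figure(figsize=(12.8, 12.8 * h / w))
    gs = fig.add_gridspec(
        2, 2, width_ratios=[3.2, 1], height_ratios=[1, 2.4], hspace=0.08, wspace=0.06
    )
    ax_depth = fig.add_subplot(gs[0, 0])
    ax_dhist = fig.add_subplot(gs[0, 1])
    ax_main = fig.add_subplot(gs[1, 0], sharex=ax_depth)
    ax_ihist = fig.add_subplot(gs[1, 1], sharey=ax_main)

    edges_x = _global_edges(matrix.layout)
    edges_y = matrix.windows.edges
    counts = matrix.counts
    empty = counts.sum() <= 0

    # --- panel A: heatmap ------------------------------------------------
    if not empty:
        masked = np.ma.masked_where(counts <= 0, counts)
        norm = (
            LogNorm(vmin=float(counts[counts > 0].min()), vmax=float(counts.max()))
            if style.log_matrix
            else None
        )
        ax_main.pcolormesh(edges_x, edges_y, masked, norm=norm, cmap=style.cmap)
    else:
        ax_main.annotate(
            "no reads selected",
            xy=(0.5, 0.5),
            xycoords="axes fraction",
            ha="center",
            fontsize=14,
        )
    ax_main.axhline(depth.threshold, color="firebrick", ls="--", lw=1)
    ax_main.set_xlim(edges_x[0], edges_x[-1] if edges_x[-1] > 0 else 1)
    ax_main.set_ylim(edges_y[0], edges_y[-1])
    ax_main.set_xlabel("genome position (bp)")
    ax_main.set_ylabel("percent identity")
    for c_end in edges_x[1:-1][_contig_breaks(matrix.layout)]:
        ax_main.axvline(c_end, color="grey", lw=0.4, alpha=0.5)

    # --- panel B: depth series -------------------------------------------
    centers = 0.5 * (edges_x[:-1] + edges_x[1:])
    for vals, color, label in (
        (depth.depth_within, style.within_color, "within population"),
        (depth.depth_outside, style.outside_color, "outside population"),
    ):
        pos = np.where(vals > 0, vals, np.nan)
        ax_depth.plot(centers, pos, color=color, lw=1.2, label=label)
        zero_x = centers[vals <= 0]
        if len(zero_x):
            ax_depth.plot(
                zero_x, np.full(len(zero_x), _zero_band(vals)), ls="none",
                marker="s", ms=2, color=color, alpha=0.6,
            )
    if style.log_depth and not empty:
        ax_depth.set_yscale("log")
    ax_depth.set_ylabel("depth (x)")
    ax_depth.legend(loc="upper right", fontsize=7, frameon=False)
    plt.setp(ax_depth.get_xticklabels(), visible=False)

    # --- panel C: depth histogram ----------------------------------------
    for i, (name, color) in enumerate(
        (("within", style.within_color), ("outside", style.outside_color))
    ):
        entries = dhist.bins[name]
        xs = np.arange(len(entries))
        ax_dhist.bar(
            xs + (i - 0.5) * 0.4, [n for _, _, n in entries], width=0.4, color=color
        )
    labels = ["0"] + [f"{lo:g}" for lo, _, _ in dhist.bins["within"][1:]]
    step = max(1, len(labels) // 8)
    ax_dhist.set_xticks(np.arange(len(labels))[::step], labels[::step], fontsize=7)
    ax_dhist.set_xlabel("depth (x)")
    ax_dhist.set_ylabel("genome regions")

    # --- panel D: identity histogram -------------------------------------
    heights = ihist.window_hi - ihist.window_lo
    ax_ihist.barh(
        ihist.window_lo, ihist.bases, height=heights, align="edge",
        color=style.within_color, alpha=0.8,
    )
    if style.log_identity_counts and ihist.total > 0:
        ax_ihist.set_xscale("log")
    ax_ihist.axhline(depth.threshold, color="firebrick", ls="--", lw=1)
    ax_ihist.set_xlabel("bases mapped")
    plt.setp(ax_ihist.get_yticklabels(), visible=False)

    fig.savefig(out_path, format="pdf")
    plt.close(fig)
    if query_record is not None:
        query_record.write(_sidecar_path(out_path))
    return out_path


def _contig_breaks(layout: BinLayout) -> np.ndarray:
    ids = [c.contig_id for c in layout.columns]
    return np.array([ids[i] != ids[i + 1] for i in range(len(ids) - 1)], dtype=bool)


def _zero_band(vals: np.ndarray) -> float:
    pos = vals[vals > 0]
    return float(pos.min()) * 0.5 if len(pos) else 0.1


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".query.txt")


# ---------------------------------------------------------------------------
# TSV export / import
# ---------------------------------------------------------------------------

_COORD_NOTE = "# coordinates are 1-based inclusive"


def _fmt(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.10g}"


def export_panel_data(
    matrix: RecruitmentMatrix,
    depth: DepthSeries,
    dhist: DepthHistogram,
    ihist: IdentityHistogram,
    out_prefix: str | Path,
    query_record: QueryRecord | None = None,
) -> dict[str, Path]:
    """Write the four panels as TSVs; returns the paths by panel name.

    The matrix TSV is long-form over every (column, window) cell and is
    sufficient to rebuild the matrix (see :func:`import_matrix_tsv`);
    gene-mode labels carry gene ids in ``col_label``.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": prefix.with_name(prefix.name + ".matrix.tsv"),
        "depth": prefix.with_name(prefix.name + ".depth.tsv"),
        "depth_hist": prefix.with_name(prefix.name + ".depth_hist.tsv"),
        "identity_hist": prefix.with_name(prefix.name + ".identity_hist.tsv"),
    }
    layout, windows = matrix.layout, matrix.windows

    with open(paths["matrix"], "w") as fh:
        fh.write(_COORD_NOTE + "\n")
        fh.write(f"# bin_width: {layout.bin_width}\n")
        fh.write(f"# gene_mode: {layout.gene_mode}\n")
        fh.write(f"# window_height: {_fmt(windows.window_height)}\n")
        fh.write(f"# population_threshold: {_fmt(matrix.population_threshold)}\n")
        fh.write("contig\tcol_start\tcol_end\tcol_label\twindow_lo\twindow_hi\tbases\n")
        for j, col in enumerate(layout.columns):
            for i in range(windows.n_windows):
                fh.write(
                    f"{col.contig_id}\t{col.start + 1}\t{col.end}\t{col.label}\t"
                    f"{_fmt(windows.edges[i])}\t{_fmt(windows.edges[i + 1])}\t"
                    f"{_fmt(matrix.counts[i, j])}\n"
                )

    with open(paths["depth"], "w") as fh:
        fh.write(_COORD_NOTE + "\n")
        fh.write(f"# population_threshold: {_fmt(depth.threshold)}\n")
        fh.write("contig\tcol_start\tcol_end\tdepth_within\tdepth_outside\n")
        for j, col in enumerate(layout.columns):
            fh.write(
                f"{col.contig_id}\t{col.start + 1}\t{col.end}\t"
                f"{_fmt(depth.depth_within[j])}\t{_fmt(depth.depth_outside[j])}\n"
            )

    with open(paths["depth_hist"], "w") as fh:
        fh.write(f"# depth_bin_width: {_fmt(dhist.depth_bin_width)}\n")
        fh.write("# the (0, 0) bin counts zero-coverage regions\n")
        fh.write("series\tdepth_lo\tdepth_hi\tn_columns\n")
        for series in ("within", "outside"):
            for lo, hi, n in dhist.bins[series]:
                fh.write(f"{series}\t{_fmt(lo)}\t{_fmt(hi)}\t{n}\n")

    with open(paths["identity_hist"], "w") as fh:
        fh.write("window_lo\twindow_hi\tbases\n")
        for lo, hi, b in zip(ihist.window_lo, ihist.window_hi, ihist.bases):
            fh.write(f"{_fmt(lo)}\t{_fmt(hi)}\t{_fmt(b)}\n")

    if query_record is not None:
        query_record.write(_sidecar_path(prefix.with_name(prefix.name + ".panels")))
    return paths


def import_matrix_tsv(path: str | Path) -> RecruitmentMatrix:
    """Rebuild a RecruitmentMatrix from its exported long-form TSV."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: no matrix cells")

    col_keys = df[["contig", "col_start", "col_end", "col_label"]].drop_duplicates()
    columns = [
        BinColumn(r.contig, int(r.col_start) - 1, int(r.col_end), r.col_label)
        for r in col_keys.itertuples()
    ]
    layout = BinLayout(
        columns=columns,
        bin_width=int(meta.get("bin_width", 0) or 0) or 1000,
        gene_mode=meta.get("gene_mode", "False") == "True",
    )
    height = float(meta["window_height"])
    windows = IdentityWindows(
        window_height=height, min_identity=float(df["window_lo"].min())
    )
    counts = np.zeros((windows.n_windows, layout.n_columns))
    col_index = {
        (c.contig_id, c.start): j for j, c in enumerate(layout.columns)
    }
    for r in df.itertuples():
        i = windows.row_of(min(float(r.window_lo) + height / 2, 100.0))
        j = col_index[(r.contig, int(r.col_start) - 1)]
        counts[i, j] = float(r.bases)
    return RecruitmentMatrix(
        layout=layout,
        windows=windows,
        counts=counts,
        population_threshold=float(meta.get("population_threshold", 95.0)),
    )


def derive_panels(
    matrix: RecruitmentMatrix,
    threshold: float | None = None,
    depth_bin_width: float | None = None,
) -> tuple[DepthSeries, DepthHistogram, IdentityHistogram]:
    """Convenience: all three derived panels from one matrix."""
    depth = depth_series(matrix, threshold)
    return depth, depth_histogram(depth, depth_bin_width), identity_histogram(matrix)
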
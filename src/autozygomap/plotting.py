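"""Static plots: genome-wide score panorama and per-region genotype grids.

The genome view draws one panel per chromosome with per-marker bars whose
height is the relative homozygosity score; markers strictly above the
score fraction are highlighted in red, the rest grey-blue.  The region
grid mirrors the classic genotype display: homozygous cells red with
intensity growing with the enclosing run length, heterozygous cells blue,
no-calls grey, a diagonal bar where patients are homozygous for different
alleles, and a box around the supporting patients' shared segment.
"""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle
import numpy as np

from .export import RegionGrid
from .genotypes import GenotypeState
from .roh import SharedRegion
from .scoring import ScoreTrack, candidate_regions

__all__ = ["plot_genome", "plot_region_grid", "highlighted_marker_indices"]

_HIGHLIGHT = "#c62828"
_BASECOL = "#90a4ae"
_HET_BLUE = (0.17, 0.35, 0.80)
_NOCALL_GREY = (0.62, 0.62, 0.62)


def highlighted_marker_indices(track: ScoreTrack, score_fraction: float,
                               min_run: int = 15) -> np.ndarray:
    """Global marker indices drawn in the highlight colour.

    Defined as the union of candidate regions' markers, so the plot and
    the candidate caller can never disagree.
    """
    idx: list[np.ndarray] = []
    for r in candidate_regions(track, score_fraction, min_run):
        idx.append(np.arange(r.start_idx, r.end_idx + 1))
    return np.concatenate(idx) if idx else np.array([], dtype=np.int64)


def plot_genome(track: ScoreTrack, score_fraction: float, path,
                min_run: int = 15) -> None:
    """Genome-wide relative-score plot, one panel per chromosome."""
    n = len(track.chrom_blocks)
    fig, axes = plt.subplots(
        1, max(n, 1), figsize=(max(8, 3 * n), 2.8), sharey=True, squeeze=False)
    hot = np.zeros(track.raw.size, dtype=bool)
    hi = highlighted_marker_indices(track, score_fraction, min_run)
    if hi.size:
        hot[hi] = True
    for ax, (chrom, a, b) in zip(axes[0], track.chrom_blocks):
        pos = track.positions[a:b] / 1e6
        rel = track.relative[a:b]
        sub_hot = hot[a:b]
        ax.vlines(pos[~sub_hot], 0, rel[~sub_hot], color=_BASECOL, lw=0.6)
        if sub_hot.any():
            ax.vlines(pos[sub_hot], 0, rel[sub_hot], color=_HIGHLIGHT, lw=0.8)
        ax.axhline(score_fraction, color="black", lw=0.5, ls=":")
        ax.set_xlabel(f"{chrom} (Mb)")
        ax.set_ylim(0, 1.05)
    axes[0][0].set_ylabel("relative homozygosity score")
    fig.suptitle("Genome-wide homozygosity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _cell_colour(cell, max_len: int):
    st = cell.state
    if st == GenotypeState.HET:
        return _HET_BLUE
    if st == GenotypeState.NOCALL:
        return _NOCALL_GREY
    # homozygous: red, stronger with longer enclosing run
    if cell.run_length <= 0:
        strength = 0.15
    else:
        strength = 0.25 + 0.75 * (cell.run_length / max(max_len, 1))
    strength = min(strength, 1.0)
    base = np.array([0.78, 0.10, 0.10])
    white = np.array([1.0, 0.92, 0.92])
    return tuple(white + (base - white) * strength)


def plot_region_grid(grid: RegionGrid, path,
                     region_box: SharedRegion | None = None) -> None:
    """Genotype grid image: rows = patients then controls, columns = markers."""
    n_rows = len(grid.samples)
    n_cols = grid.n_markers
    fig, ax = plt.subplots(
        figsize=(max(6, min(0.12 * n_cols, 18)), max(2, 0.5 * n_rows + 1)))
    max_len = 1
    for row in grid.cells:
        for cell in row:
            max_len = max(max_len, cell.run_length)
    for i, row in enumerate(grid.cells):
        for j, cell in enumerate(row):
            ax.add_patch(Rectangle((j, n_rows - 1 - i), 1, 1,
                                   facecolor=_cell_colour(cell, max_len),
                                   edgecolor="white", lw=0.2))
            if cell.discordant:
                y0 = n_rows - 1 - i
                ax.plot([j, j + 1], [y0, y0 + 1], color="black", lw=1.0)
    if region_box is not None and n_cols:
        inside = np.flatnonzero(
            (grid.positions >= region_box.start_bp)
            & (grid.positions <= region_box.end_bp))
        if inside.size:
            j0, j1 = int(inside[0]), int(inside[-1])
            rows_in_box = [i for i, s in enumerate(grid.samples)
                           if s in region_box.supporting_patients] or \
                list(range(grid.n_patients))
            y_lo = n_rows - 1 - max(rows_in_box)
            y_hi = n_rows - min(rows_in_box)
            ax.add_patch(Rectangle((j0, y_lo), j1 - j0 + 1, y_hi - y_lo,
                                   fill=False, edgecolor="black", lw=1.8))
    ax.set_xlim(0, max(n_cols, 1))
    ax.set_ylim(0, n_rows if n_rows else 1)
    ax.set_yticks([n_rows - 1 - i + 0.5 for i in range(n_rows)])
    ax.set_yticklabels(grid.samples)
    ax.set_xticks([])
    ax.set_xlabel(f"{grid.chrom}: {n_cols} markers")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
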
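"""Per-chromosome genotype map and PCA scatter rendering.

The genotype map shows, for one chromosome, every merged site as a row and
every sample as a column, colored by genotype: dark blue = 0/0 (an SV seen
in other samples but not this one), green = heterozygous, yellow =
homozygous.  To keep chromosomes on a uniform physical scale, neutral
"scaffold" rows are inserted every 50,000 bp (default) and at both
chromosome ends, even where no SV was detected; they carry a fourth,
light-gray category so absent data stays visually distinct from 0/0 (set
``scaffold_as_no_sv`` to blend them, matching the classic rendering).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .model import Cohort
from .pca import PcaResult

__all__ = ["PlotMatrix", "build_plot_matrix", "render_genotype_map", "render_pca_scatter"]

CATEGORIES = ("no_sv", "het", "hom", "scaffold")
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
_GT_CATEGORY = {"0/0": "no_sv", "0/1": "het", "1/1": "hom"}

#: genotype-map palette: dark blue / green / yellow (+ light gray scaffold)
_COLORS = ("#1f3b73", "#2ca02c", "#ffd300", "#d9d9d9")


@dataclass
class PlotMatrix:
    row_positions: list[int]  # bp, ascending; sites and scaffold points
    columns: list[str]  # samples in manifest order
    cells: list[list[str]]  # rows x columns of category labels


def build_plot_matrix(
    cohort: Cohort,
    chrom: str,
    chrom_length: int,
    scaffold_interval: int = 50000,
    scaffold_as_no_sv: bool = False,
) -> PlotMatrix:
    """Assemble the genotype-map matrix for one chromosome.

    Scaffold rows sit at 0, every ``scaffold_interval``, and at
    ``chrom_length``; a scaffold point coinciding with a site position
    yields only the site row.
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    sites = [s for s in cohort.sites if s.chrom == chrom]
    site_positions = {s.pos for s in sites}
    scaffold_positions = set(range(0, chrom_length + 1, scaffold_interval))
    scaffold_positions.add(chrom_length)
    scaffold_positions -= site_positions
    scaffold_cat = "no_sv" if scaffold_as_no_sv else "scaffold"
    rows: list[tuple[int, list[str]]] = [
        (p, [scaffold_cat] * len(cohort.samples)) for p in scaffold_positions
    ]
    for s in sites:
        rows.append((s.pos, [_GT_CATEGORY[s.genotypes.get(c, "0/0")] for c in cohort.samples]))
    rows.sort(key=lambda r: r[0])
    return PlotMatrix(
        row_positions=[p for p, _ in rows],
        columns=list(cohort.samples),
        cells=[cells for _, cells in rows],
    )


def render_genotype_map(matrix: PlotMatrix, path: str | os.PathLike) -> None:
    """Render the genotype map to PNG or SVG (by extension); deterministic."""
    if not matrix.cells:
        raise ValueError("empty plot matrix")
    grid = np.array([[_CAT_INDEX[c] for c in row] for row in matrix.cells])
    fig, ax = plt.subplots(figsize=(max(2.0, 0.5 * len(matrix.columns)), 8.0))
    cmap = ListedColormap(_COLORS)
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=0, vmax=len(CATEGORIES) - 1,
              interpolation="nearest", origin="lower")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks([0, len(matrix.row_positions) - 1])
    ax.set_yticklabels([str(matrix.row_positions[0]), str(matrix.row_positions[-1])], fontsize=7)
    ax.set_ylabel("position (bp)")
    fig.tight_layout()
    _save_deterministic(fig, path)


def render_pca_scatter(result: PcaResult, samples: list[str], path: str | os.PathLike) -> None:
    """2-D scatter of PC1/PC2 scores with sample labels."""
    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = result.scores[:, 0], result.scores[:, 1]
    ax.scatter(xs, ys, s=30, color="#1f77b4")
    for x, y, label in zip(xs, ys, samples):
        ax.annotate(label, (x, y), fontsize=7, xytext=(3, 3), textcoords="offset points")
    ev = result.explained_fraction
    ax.set_xlabel(f"PC1 ({ev[0] * 100:.1f}%)")
    if len(ev) > 1:
        ax.set_ylabel(f"PC2 ({ev[1] * 100:.1f}%)")
    fig.tight_layout()
    _save_deterministic(fig, path)


def _save_deterministic(fig, path: str | os.PathLike) -> None:
    path = str(path)
    kwargs = {}
    if path.endswith(".svg"):
        kwargs["metadata"] = {"Date": None}  # strip the embedded timestamp
    fig.savefig(path, **kwargs)
    plt.close(fig)
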
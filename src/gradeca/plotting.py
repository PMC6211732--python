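"""Overrepresentation-map and scree-plot rendering.

The overrepresentation map draws the grade density on the unit square with
*marginal-proportional* rectangle sizes: cell (i, j) occupies
[S_{i-1}, S_i) x [T_{j-1}, T_j), so heavy rows/columns are wide — this is
what distinguishes the map of a copula density from an ordinary heatmap.
Grayscale by default, darker = larger ratio; optional bold separators mark
cluster boundaries.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .grade import GradeDensityMap

__all__ = ["render_overrepresentation", "plot_scree"]

#: above this many cells the map is rasterised to a pixel grid instead of
#: drawing one quadrilateral per cell
_EXACT_CELL_LIMIT = 400_000


def render_overrepresentation(
    density: GradeDensityMap,
    model=None,
    path=None,
    ax=None,
    colormap: str = "Greys",
    vmax: float | None = None,
    raster_shape: tuple[int, int] = (1200, 2400),
):
    """Draw the grade density as a unit-square overrepresentation map.

    Rows run top-to-bottom, columns left-to-right.  For matrices up to
    ~4e5 cells each rectangle is drawn exactly (``pcolormesh`` on the grade
    breakpoints); larger maps are rasterised to ``raster_shape`` pixels by
    sampling the piecewise-constant density.  ``model`` (a ClusterModel)
    adds bold separators at the cluster boundaries.  Returns the Axes.
    """
    h = density.h
    S, T = density.row_cum, density.col_cum
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    if vmax is None:
        vmax = max(2.0, float(np.percentile(h, 99.5)))
    if h.size <= _EXACT_CELL_LIMIT:
        ax.pcolormesh(T, S, h, cmap=colormap, vmin=0.0, vmax=vmax, shading="flat")
    else:
        ny, nx = raster_shape
        u = (np.arange(ny) + 0.5) / ny
        v = (np.arange(nx) + 0.5) / nx
        ii = np.clip(np.searchsorted(S, u, side="right") - 1, 0, h.shape[0] - 1)
        jj = np.clip(np.searchsorted(T, v, side="right") - 1, 0, h.shape[1] - 1)
        img = h[np.ix_(ii, jj)]
        ax.imshow(
            img, cmap=colormap, vmin=0.0, vmax=vmax, origin="lower",
            extent=(0, 1, 0, 1), aspect="auto", interpolation="nearest",
        )
    if model is not None:
        for c in model.row_cuts:
            ax.axhline(S[c], color="black", lw=2.0)
        for c in model.col_cuts:
            ax.axvline(T[c], color="black", lw=2.0)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.invert_yaxis()  # first row at the top
    ax.set_xlabel("column grade (v)")
    ax.set_ylabel("row grade (u)")
    if path is not None:
        ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_scree(scree_values, ax=None, path=None):
    """Criterion vs cluster count, for the usual elbow read-off."""
    if ax is None:
        _, ax = plt.subplots()
    ks = [k for k, _ in scree_values]
    vals = [v for _, v in scree_values]
    ax.plot(ks, vals, marker="o", color="black")
    ax.set_xlabel("number of clusters")
    ax.set_ylabel("criterion")
    if path is not None:
        ax.figure.savefig(Path(path), dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
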
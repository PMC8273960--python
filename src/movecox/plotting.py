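"""Ternary heatmap of hazard-ratio surfaces.

Compositions (SB, LIPA, MVPA) are projected barycentrically onto an
equilateral triangle and the HR surface is rendered with a diverging
colour map centred at HR = 1; the reference composition is marked with a
black circle.  Display-only choices (colour clipping, rounding of axis
labels) never feed back into the estimates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["barycentric_xy", "plot_hr_surface"]

_SQRT3_2 = np.sqrt(3.0) / 2.0


def barycentric_xy(sb, lipa, mvpa):
    """Project compositions onto the unit triangle.

    Corners: SB at (0, 0), LIPA at (1, 0), MVPA at (1/2, sqrt(3)/2).
    """
    sb = np.asarray(sb, float)
    lipa = np.asarray(lipa, float)
    mvpa = np.asarray(mvpa, float)
    total = sb + lipa + mvpa
    b, c = lipa / total, mvpa / total
    return b + 0.5 * c, _SQRT3_2 * c


def plot_hr_surface(surface, ax=None, clip=(0.8, 1.3), cmap="RdYlBu_r"):
    """Render an HR surface from :meth:`hr_surface` as a ternary heatmap.

    ``surface`` is the DataFrame with columns sb_min, lipa_min,
    mvpa_min, hr, is_reference.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    grid = surface[~surface["is_reference"]]
    if len(grid) < 3:
        raise ValueError("surface grid too small to triangulate")
    x, y = barycentric_xy(grid["sb_min"], grid["lipa_min"], grid["mvpa_min"])
    tri = mtri.Triangulation(x, y)
    vals = grid["hr"].to_numpy().clip(*clip)
    m = ax.tripcolor(tri, vals, cmap=cmap, vmin=clip[0], vmax=clip[1], shading="gouraud")
    ref = surface[surface["is_reference"]]
    rx, ry = barycentric_xy(ref["sb_min"], ref["lipa_min"], ref["mvpa_min"])
    ax.plot(rx, ry, "o", color="black", markersize=9, label="reference")
    for (cx, cy), lab in zip(
        [(0, 0), (1, 0), (0.5, _SQRT3_2)], ("SB", "LIPA", "MVPA")
    ):
        ax.annotate(
            lab, (cx, cy), textcoords="offset points",
            xytext=(0, 8 if cy > 0 else -14), ha="center", fontsize=11,
        )
    ax.figure.colorbar(m, ax=ax, label="HR vs reference composition")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.legend(loc="upper left", frameon=False)
    return ax
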
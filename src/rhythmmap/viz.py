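"""Interpretable map renderings: membership, reference, magnification,
macrocluster and trajectory plots.

All plots draw the latent grid with row 0 at the top (matrix convention;
noted in each figure caption) and are pure functions of their inputs: the
same artifacts and style render the same image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from rhythmmap.gtm import GTMResults
from rhythmmap.macrocluster import MacroclusterPartition
from rhythmmap.magnification import MagnificationField
from rhythmmap.screening import ScreeningResult

__all__ = [
    "MapStyle",
    "plot_membership_map",
    "plot_reference_maps",
    "plot_magnification_map",
    "plot_macrocluster_map",
    "plot_trajectory",
]

#: gray (low) -> red (high), the reference-map convention
REFERENCE_CMAP = LinearSegmentedColormap.from_list("gray_red", ["#b0b0b0", "#d40000"])

_CAPTION = "latent grid drawn with row 0 at the top (matrix convention)"


@dataclass
class MapStyle:
    """Rendering options shared by the map plots."""

    cmap_reference: object = field(default_factory=lambda: REFERENCE_CMAP)
    cmap_magnification: str = "gray_r"  # light = low MF, dark = high MF
    cluster_palette: str = "tab10"
    base_marker_area: float = 40.0
    fmt: str = "png"
    dpi: int = 120

    @classmethod
    def from_dict(cls, d: dict) -> "MapStyle":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


def _node_xy(grid, k):
    rows, cols = grid.shape
    r, c = divmod(k, cols)
    return c, r


def _grid_axes(ax, grid, title):
    rows, cols = grid.shape
    ax.set_xlim(-0.7, cols - 0.3)
    ax.set_ylim(rows - 0.3, -0.7)  # row 0 at top
    ax.set_xticks(range(cols))
    ax.set_yticks(range(rows))
    ax.set_aspect("equal")
    ax.set_title(f"{title}\n({_CAPTION})", fontsize=9)


def _occupancy(results: GTMResults, R=None):
    R = results.responsibilities_ if R is None else R
    nodes = np.argmax(R, axis=1)
    return np.bincount(nodes, minlength=results.model.grid.K)


def _save(fig, path, style):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_membership_map(results: GTMResults, R=None, style=None, path="membership.png"):
    """Occupied nodes only; marker area grows with the snippet count."""
    style = style or MapStyle()
    grid = results.model.grid
    occ = _occupancy(results, R)
    fig, ax = plt.subplots(figsize=(5, 5))
    for k in np.flatnonzero(occ):
        x, y = _node_xy(grid, k)
        ax.scatter(x, y, s=style.base_marker_area * occ[k] / occ.max() * 4 + 10,
                   color="#3465a4", alpha=0.85, edgecolors="k", linewidths=0.4)
    _grid_axes(ax, grid, "Membership map (marker area ~ node occupancy)")
    return _save(fig, path, style)


def plot_reference_maps(results: GTMResults, variables, style=None, out_dir="refmaps"):
    """One gray->red map per variable, de-standardized to original units."""
    style = style or MapStyle()
    valid = list(results.model.feature_names)
    unknown = [v for v in variables if v not in valid]
    if unknown:
        raise ValueError(f"unknown variables {unknown}; valid names: {valid}")
    grid = results.model.grid
    Y = results.reference_vectors_
    scaler = results.model.standardizer
    paths = []
    for var in variables:
        j = valid.index(var)
        vals = Y[:, j]
        if scaler is not None and var in scaler.columns:
            vals = scaler.inverse_transform_column(var, vals)
        vmin, vmax = float(vals.min()), float(vals.max())
        denom = (vmax - vmin) or 1.0
        fig, ax = plt.subplots(figsize=(5, 5))
        for k in range(grid.K):
            x, y = _node_xy(grid, k)
            ax.scatter(x, y, s=style.base_marker_area,
                       color=style.cmap_reference((vals[k] - vmin) / denom))
        _grid_axes(ax, grid, f"Reference map: {var}")
        paths.append(_save(fig, Path(out_dir) / f"refmap_{var}.{style.fmt}", style))
    return paths


def plot_magnification_map(field: MagnificationField, style=None, path="magnification.png"):
    """Grayscale magnification field: light = low distortion, dark = high."""
    style = style or MapStyle()
    rows, cols = field.grid.shape
    img = field.values.reshape(rows, cols)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(img, cmap=style.cmap_magnification, origin="upper")
    fig.colorbar(im, ax=ax, label="magnification factor")
    ax.set_title(f"Magnification map\n({_CAPTION})", fontsize=9)
    return _save(fig, path, style)


def plot_macrocluster_map(
    partition: MacroclusterPartition,
    grid,
    occupancy=None,
    diagnosis_labels=None,
    style=None,
    path="macroclusters.png",
):
    """One color per macrocluster; sizes optionally scale with occupancy."""
    style = style or MapStyle()
    palette = plt.get_cmap(style.cluster_palette)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for m in range(1, partition.M + 1):
        xs, ys, ss = [], [], []
        for k in partition.members(m):
            x, y = _node_xy(grid, k)
            xs.append(x)
            ys.append(y)
            if occupancy is not None and occupancy.max() > 0:
                ss.append(style.base_marker_area * occupancy[k] / occupancy.max() * 4 + 10)
            else:
                ss.append(style.base_marker_area)
        label = f"cluster {m}"
        if diagnosis_labels is not None:
            label += f" ({diagnosis_labels.get(m, '?')})"
        ax.scatter(xs, ys, s=ss, color=palette((m - 1) % 10), label=label,
                   edgecolors="k", linewidths=0.3)
    ax.legend(loc="center left", bbox_to_anchor=(1.02, 0.5), fontsize=8)
    _grid_axes(ax, grid, "Macrocluster map")
    return _save(fig, path, style)


def plot_trajectory(
    result: ScreeningResult,
    partition: MacroclusterPartition,
    grid,
    style=None,
    path="trajectory.png",
):
    """Chronological snippet trajectory over the macrocluster map, with the
    ECG's node probability distribution as an adjacent heat grid."""
    if result.trajectory.size == 0:
        raise ValueError("trajectory is empty")
    style = style or MapStyle()
    palette = plt.get_cmap(style.cluster_palette)
    fig, (ax, axp) = plt.subplots(
        1, 2, figsize=(9.5, 4.5), gridspec_kw={"width_ratios": [1.2, 1]}
    )
    for m in range(1, partition.M + 1):
        pts = [_node_xy(grid, k) for k in partition.members(m)]
        ax.scatter([p[0] for p in pts], [p[1] for p in pts],
                   s=style.base_marker_area, color=palette((m - 1) % 10), alpha=0.45)
    xy = np.array([_node_xy(grid, k) for k in result.trajectory], dtype=float)
    for i in range(len(xy) - 1):
        ax.annotate(
            "",
            xy=xy[i + 1],
            xytext=xy[i],
            arrowprops=dict(arrowstyle="->", color="k", lw=1.2),
        )
    for i, (x, y) in enumerate(xy):
        ax.annotate(str(i), (x, y), fontsize=8, fontweight="bold",
                    textcoords="offset points", xytext=(4, 4))
    ax.scatter(*xy[0], marker="s", s=60, color="k", zorder=5)
    _grid_axes(ax, grid, f"ECG {result.ecg_id}: trajectory "
                         f"(assigned {result.assigned_diagnosis})")

    rows, cols = grid.shape
    im = axp.imshow(result.node_distribution.reshape(rows, cols),
                    cmap="viridis", origin="upper")
    fig.colorbar(im, ax=axp, label="probability")
    axp.set_title("per-ECG node distribution", fontsize=9)
    return _save(fig, path, style)
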
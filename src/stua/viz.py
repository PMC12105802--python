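"""Raster maps of the uncertainty-analysis outputs.

Variance grids use a sequential palette; sensitivity, irrelevance and
relevance grids use a diverging palette symmetric about zero.  Excluded or
unoccupied cells (the missing sentinel) render in a neutral mask colour so
the screened-out parts of the map stay visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colors as mcolors

__all__ = ["MapStyle", "render_field_map", "render_propagation_panel"]


@dataclass(frozen=True)
class MapStyle:
    """Presentation of one grid map."""

    palette: str = "sequential"  # 'sequential' (values >= 0) or 'diverging' (centred at 0)
    value_bounds: Optional[tuple[float, float]] = None
    mask_colour: str = "0.82"
    annotate_regions: bool = False
    cmap_sequential: str = "viridis"
    cmap_diverging: str = "RdBu_r"

    def __post_init__(self) -> None:
        if self.palette not in ("sequential", "diverging"):
            raise ValueError(f"unknown palette {self.palette!r}")


def _norm_and_cmap(grid: np.ndarray, style: MapStyle):
    finite = grid[np.isfinite(grid)]
    if style.palette == "diverging":
        if style.value_bounds is not None:
            lo, hi = style.value_bounds
            v = max(abs(lo), abs(hi))
        else:
            v = float(np.max(np.abs(finite))) if finite.size else 1.0
        v = v or 1.0
        # symmetric about zero by construction
        return mcolors.Normalize(vmin=-v, vmax=v), style.cmap_diverging
    if style.value_bounds is not None:
        lo, hi = style.value_bounds
    else:
        lo = float(np.min(finite)) if finite.size else 0.0
        hi = float(np.max(finite)) if finite.size else 1.0
    if lo == hi:
        hi = lo + 1.0
    return mcolors.Normalize(vmin=lo, vmax=hi), style.cmap_sequential


def _draw(ax, grid: np.ndarray, style: MapStyle, title: str = ""):
    grid = np.asarray(grid, dtype=float)
    masked = np.ma.masked_invalid(grid)
    if masked.mask.all():
        warnings.warn("grid has no finite values; rendering fully masked map")
    norm, cmap_name = _norm_and_cmap(grid, style)
    cmap = plt.get_cmap(cmap_name).copy()
    cmap.set_bad(style.mask_colour)
    im = ax.imshow(masked, origin="upper", norm=norm, cmap=cmap,
                   interpolation="nearest")
    if style.annotate_regions:
        ax.axvline(grid.shape[1] / 2 - 0.5, color="black", lw=0.8)
    if title:
        ax.set_title(title, fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    return im


def render_field_map(
    grid: np.ndarray,
    style: MapStyle,
    out_path: Union[str, Path],
    title: str = "",
) -> Path:
    """Render one grid to a PNG; returns the written path."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = _draw(ax, grid, style, title)
    cbar = fig.colorbar(im, ax=ax, shrink=0.85)
    cbar.set_ticks([im.norm.vmin, (im.norm.vmin + im.norm.vmax) / 2, im.norm.vmax])
    fig.savefig(out_path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return out_path


def render_propagation_panel(artifacts, out_path: Union[str, Path]) -> Path:
    """2x2 panel: (a) VC at t2, (b) sensitivity U at t2, (c) I, (d) R."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    panels = [
        ("VC_t2", "(a) variance VC", MapStyle(palette="sequential")),
        ("U_t2", "(b) total effects sensitivity U", MapStyle(palette="diverging")),
        ("I", "(c) irrelevance index I", MapStyle(palette="diverging")),
        ("R", "(d) relevance index R", MapStyle(palette="diverging")),
    ]
    grids = artifacts.grids()
    missing = [name for name, _, _ in panels if name not in grids or grids[name] is None]
    if missing:
        raise ValueError(f"artifact set incomplete; missing {missing}")
    fig, axes = plt.subplots(2, 2, figsize=(8.0, 7.0))
    for ax, (name, title, style) in zip(axes.flat, panels):
        im = _draw(ax, grids[name], style, title)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(out_path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    return out_path
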
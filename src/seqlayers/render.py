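"""Matplotlib rendering of layer drawing tables.

Layers are pure data: tidy tables plus aesthetic bindings.  This module
is the bundled backend that turns them into figures — grouped compound
paths for letter glyphs (pieces keep their original winding, so holes
like the bowl of an ``O`` render correctly), rectangles for alignment
tiles and bar segments, one subplot per facet panel.  Any other renderer
that understands grouped polygons, rectangles and facets could consume
the same tables.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg", force=False)

from matplotlib import pyplot as plt
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.path import Path

from .align import AlignLayer
from .bar import BarLayer
from .colorschemes import ColorScheme
from .logo import LogoLayer
from .theme import ThemeSpec, apply_theme, axis_metadata, theme_seq

__all__ = ["render_figure", "render_composed"]

_NEUTRAL_TILE = "#FFFFFF"
_TILE_EDGE = "#DDDDDD"


def _continuous_mapper(scheme: ColorScheme):
    cmap = LinearSegmentedColormap.from_list(scheme.name, list(scheme.gradient))
    vals = [float(v) for v in scheme.mapping.values()] or [0.0, 1.0]
    norm = Normalize(vmin=min(vals), vmax=max(vals))
    return cmap, norm


def _glyph_paths(table: pd.DataFrame):
    """Yield (compound Path, color-or-value) per glyph in a vertex table."""
    if len(table) == 0:
        return
    color_col = "col" if "col" in table.columns else "value"
    for _, glyph in table.groupby("group", sort=False):
        verts, codes = [], []
        for _, piece in glyph.groupby("piece", sort=True):
            piece = piece.sort_values("order")
            pts = piece[["x", "y"]].to_numpy()
            verts.extend(pts)
            verts.append(pts[0])
            codes.extend([Path.MOVETO] + [Path.LINETO] * (len(pts) - 1)
                         + [Path.CLOSEPOLY])
        yield Path(np.asarray(verts), codes), glyph[color_col].iloc[0]


def _draw_glyphs(ax, table: pd.DataFrame, scheme: ColorScheme) -> None:
    mapper = None
    if "col" not in table.columns and "value" in table.columns:
        mapper = _continuous_mapper(scheme)
    for path, color in _glyph_paths(table):
        if mapper is not None and not isinstance(color, str):
            cmap, norm = mapper
            color = cmap(norm(float(color)))
        ax.add_patch(PathPatch(path, facecolor=color, linewidth=0))


def _draw_rects(ax, rows, scheme: ColorScheme, neutral: str | None = None) -> None:
    mapper = None
    if "col" not in rows.columns and "value" in rows.columns:
        mapper = _continuous_mapper(scheme)
    for _, r in rows.iterrows():
        if "y_lo" in rows.columns:
            x0, y0 = r["x"] - r["width"] / 2, r["y_lo"]
            w, h = r["width"], r["y_hi"] - r["y_lo"]
        else:
            x0, y0 = r["x"] - r["width"] / 2, r["y"] - r["height"] / 2
            w, h = r["width"], r["height"]
        if "col" in rows.columns:
            color = r["col"]
        elif mapper is not None:
            cmap, norm = mapper
            color = cmap(norm(float(r["value"])))
        else:
            color = neutral or _NEUTRAL_TILE
        ax.add_patch(Rectangle((x0, y0), w, h, facecolor=color,
                               edgecolor=_TILE_EDGE, linewidth=0.3))


def _panel_axes(fig, labels: Sequence[str]):
    axes = fig.subplots(1, len(labels), squeeze=False, sharey=True)[0]
    for ax, label in zip(axes, labels):
        if len(labels) > 1:
            ax.set_title(str(label))
    return dict(zip(labels, axes))


def render_figure(layer, theme: ThemeSpec | None = None,
                  figsize: tuple[float, float] = (8.0, 3.0)):
    """Draw one layer (all facet panels) and return the matplotlib figure."""
    theme = theme or theme_seq()
    fig = plt.figure(figsize=figsize)
    labels = layer.panel_labels
    axes = _panel_axes(fig, labels)
    meta = axis_metadata(layer)

    for label, ax in axes.items():
        if isinstance(layer, LogoLayer):
            sub = layer.data[layer.data["seq_group"] == label]
            _draw_glyphs(ax, sub, layer.scheme)
            lo = min(0.0, float(sub["y"].min())) if len(sub) else 0.0
            hi = float(sub["y"].max()) if len(sub) else 1.0
            ax.set_ylim(lo - 0.02 * (hi - lo or 1), hi * 1.02 if hi > 0 else 0.1)
        elif isinstance(layer, AlignLayer):
            bg = layer.bg_data[layer.bg_data["seq_group"] == label]
            _draw_rects(ax, bg, layer.scheme, neutral=_NEUTRAL_TILE)
            if layer.letter_data is not None and len(layer.letter_data):
                sub = layer.letter_data[layer.letter_data["seq_group"] == label]
                _draw_glyphs(ax, sub, layer.scheme)
            k = len(layer.panels[label])
            ax.set_ylim(k, 0)  # reversed: first sequence on top
        elif isinstance(layer, BarLayer):
            bars = layer.bar_data[layer.bar_data["seq_group"] == label]
            _draw_rects(ax, bars, layer.scheme)
            if layer.letter_data is not None and len(layer.letter_data):
                sub = layer.letter_data[layer.letter_data["seq_group"] == label]
                _draw_glyphs(ax, sub, layer.scheme)
            top = float(bars["y_hi"].max()) if len(bars) else 1.0
            ax.set_ylim(0, top * 1.02)
        else:
            raise TypeError(f"cannot render {type(layer).__name__}")

        ax.set_xlim(0.5, layer.n_positions + 0.5)
        ax.set_xticks(meta["x_breaks"])
        ax.set_xlabel(meta["x_label"])
        if "y_ticks" in meta:
            ax.set_yticks(meta["y_ticks"], meta["y_tick_labels"])
        apply_theme(ax, theme)
    axes[labels[0]].set_ylabel(meta["y_label"])

    if layer.scheme.kind == "continuous" and theme.legend != "none":
        cmap, norm = _continuous_mapper(layer.scheme)
        fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap),
                     ax=list(axes.values()), shrink=0.8)
    return fig


def render_composed(layers: Sequence, offsets: Sequence[float],
                    theme: ThemeSpec | None = None,
                    figsize: tuple[float, float] = (8.0, 6.0)):
    """Draw several single-panel layers stacked in one coordinate system."""
    from .logo import compose  # table-level contract lives there

    theme = theme or theme_seq()
    fig, ax = plt.subplots(figsize=figsize)
    y_min, y_max = np.inf, -np.inf
    for layer, off in zip(layers, offsets):
        lo, hi = layer.y_extent()
        y_min, y_max = min(y_min, lo + off), max(y_max, hi + off)
        for name, tbl in layer.tables().items():
            t = tbl.copy()
            for col in ("y", "y_lo", "y_hi"):
                if col in t.columns:
                    t[col] = t[col] + off
            if name == "bg_data" or (name == "bar_data"):
                _draw_rects(ax, t, layer.scheme)
            else:
                _draw_glyphs(ax, t, layer.scheme)
    from .theme import merge_x_breaks

    ax.set_xticks(merge_x_breaks(layers))
    ax.set_xlim(0.5, max(l.n_positions for l in layers) + 0.5)
    pad = 0.02 * (y_max - y_min or 1.0)
    ax.set_ylim(y_min - pad, y_max + pad)
    ax.set_xlabel("position")
    apply_theme(ax, theme)
    return fig
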
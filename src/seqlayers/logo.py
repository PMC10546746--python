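"""The sequence-logo layer.

``build_logo`` turns any accepted input — aligned sequences, a position
frequency matrix, a signed height matrix, or a mapping of panel label to
either — into a :class:`LogoLayer` whose public ``data`` table holds the
positioned, scaled, colored letter polygons.  The table is the drawing
contract: every row is one polygon vertex, rows group into glyph pieces,
and any grammar-of-graphics style renderer (or the bundled matplotlib
one) can draw it with a grouped-polygon primitive.  Users are encouraged
to read and *mutate* the table — e.g. recolor one letter at one position —
before rendering; ``mutate_layer`` is a convenience for exactly that.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import colorschemes as cs
from . import fonts
from ._input import as_panels
from .seqstats import (FrequencyMatrix, HeightMatrix, SequenceSet, build_pfm,
                       stack, to_bits, to_probability)

__all__ = ["LogoLayer", "build_logo", "mutate_layer", "compose",
           "LETTER_WIDTH"]

#: Letter width as a fraction of the unit position slot (visible gutter).
LETTER_WIDTH = 0.9

_Y_LABELS = {"bits": "bits", "probability": "probability", "custom": ""}


def glyph_records(
    letter: str,
    font_name: str,
    x_center: float,
    width: float,
    y_lo: float,
    y_hi: float,
) -> pd.DataFrame | None:
    """Vertex rows (piece, order, x, y) for one letter filling a box."""
    try:
        outline = fonts.get_glyph(letter, font_name)
    except KeyError:
        return None
    pts, piece = fonts.place_glyph(outline, x_center, width, y_lo, y_hi - y_lo)
    return pd.DataFrame({
        "piece": piece,
        "order": np.arange(len(pts)),
        "x": pts[:, 0],
        "y": pts[:, 1],
    })


@dataclass
class LogoLayer:
    """A built sequence logo: drawing table plus axis/facet metadata.

    ``data`` columns: letter, position, piece, order, x, y, seq_group,
    col (discrete scheme) or value (continuous scheme), group.  ``group``
    is the polygon grouping key ``seq_group.position.letter``; one glyph
    is the set of rows sharing (group, piece).
    """

    data: pd.DataFrame
    method: str
    font_name: str
    scheme: cs.ColorScheme
    heights: dict[str, HeightMatrix]
    xlab: str = "position"

    @property
    def ylab(self) -> str:
        return _Y_LABELS[self.method]

    @property
    def n_positions(self) -> int:
        return max(h.n_positions for h in self.heights.values())

    @property
    def panel_labels(self) -> list[str]:
        return list(self.heights)

    @property
    def x_breaks(self) -> list[int]:
        return list(range(1, self.n_positions + 1))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"data": self.data}

    def y_extent(self) -> tuple[float, float]:
        if len(self.data) == 0:
            return (0.0, 0.0)
        return float(self.data["y"].min()), float(self.data["y"].max())


def _heights_for(item: Any, method: str,
                 small_sample_correction: bool = False) -> HeightMatrix:
    if isinstance(item, HeightMatrix):
        if method == "custom" or item.mode == method:
            return item
        raise TypeError(
            f"a {item.mode!r}-mode height matrix cannot be redrawn with "
            f"method={method!r}"
        )
    if isinstance(item, SequenceSet):
        if method == "custom":
            raise TypeError(
                "method='custom' needs matrix input (letters x positions "
                "heights), not sequences"
            )
        item = build_pfm(item)
    if isinstance(item, FrequencyMatrix):
        if method == "custom":
            return HeightMatrix(item.letters, item.counts, "custom",
                                item.panel_label)
        if method == "probability":
            return to_probability(item)
        return to_bits(item, small_sample_correction=small_sample_correction)
    raise TypeError(f"cannot build logo heights from {type(item).__name__}")


def build_logo(
    data: Any,
    method: str = "bits",
    font_name: str | None = None,
    scheme: str | cs.ColorScheme | None = None,
    namespace: Iterable[str] | None = None,
    small_sample_correction: bool = False,
) -> LogoLayer:
    """Build a sequence logo layer.

    Parameters
    ----------
    data
        Aligned sequences, a PFM, a height matrix, or a mapping
        label -> sequences/matrix (one facet panel per key).
    method
        ``"bits"`` (information content, the default), ``"probability"``
        (relative frequencies), or ``"custom"`` (matrix heights used
        verbatim; negative values draw below the axis).
    font_name
        One of :func:`seqlayers.fonts.list_fonts`; default is the
        catalog's first font.
    scheme
        Scheme name, :class:`~seqlayers.colorschemes.ColorScheme`, or
        ``None`` for the alphabet's default scheme.
    namespace
        Explicit alphabet for raw string/matrix input.
    small_sample_correction
        Subtract the Schneider-style entropy bias term from information
        content (bits method only).
    """
    if method not in ("probability", "bits", "custom"):
        raise ValueError(f"unknown method {method!r}")
    font_name = font_name or fonts.list_fonts()[0]
    panels = as_panels(data, namespace, signed=(method == "custom"))
    heights = {label: _heights_for(item, method, small_sample_correction)
               for label, item in panels}

    letters_union: list[str] = []
    for hm in heights.values():
        for l in hm.letters:
            if l not in letters_union:
                letters_union.append(l)
    scheme = _resolve_scheme(scheme, letters_union)

    frames = []
    for label, hm in heights.items():
        for iv in stack(hm):
            rec = glyph_records(iv.letter, font_name, iv.position,
                                LETTER_WIDTH, iv.y_lo, iv.y_hi)
            if rec is None:
                continue
            rec.insert(0, "letter", iv.letter)
            rec.insert(1, "position", iv.position)
            rec["seq_group"] = label
            rec["group"] = f"{label}.{iv.position}.{iv.letter}"
            frames.append(rec)
    if frames:
        table = pd.concat(frames, ignore_index=True)
        colors = cs.assign_colors(scheme, table["letter"])
        value_col = "col" if scheme.kind == "discrete" else "value"
        table[value_col] = colors[value_col].to_numpy()
    else:  # all-zero heights: an empty logo is legal
        value_col = "col" if scheme.kind == "discrete" else "value"
        table = pd.DataFrame(columns=["letter", "position", "piece", "order",
                                      "x", "y", "seq_group", "group",
                                      value_col])
    return LogoLayer(data=table, method=method, font_name=font_name,
                     scheme=scheme, heights=heights)


def _resolve_scheme(scheme, letters) -> cs.ColorScheme:
    if scheme is None:
        return cs.default_scheme(letters)
    if isinstance(scheme, str):
        return cs.get_col_scheme(scheme, letters)
    return scheme


def mutate_layer(layer: LogoLayer, edits: Sequence[Mapping[str, Any]]) -> LogoLayer:
    """Apply record-level color/value overrides to a logo's drawing table.

    Each edit selects rows by any of ``letter``, ``position``,
    ``seq_group`` and sets the remaining keys (typically ``col`` or
    ``value``) on the matching rows.  Selecting zero rows is an error.
    Geometry columns are never touched.  Returns a new layer; the input
    is left unchanged.
    """
    table = layer.data.copy()
    selectors = ("letter", "position", "seq_group")
    for edit in edits:
        mask = pd.Series(True, index=table.index)
        used = False
        for key in selectors:
            if key in edit:
                mask &= table[key] == edit[key]
                used = True
        if not used:
            raise ValueError(f"edit {edit!r} selects by none of {selectors}")
        if not mask.any():
            raise KeyError(f"edit {edit!r} matches no drawing records")
        for key, val in edit.items():
            if key in selectors:
                continue
            if key in ("x", "y", "piece", "order"):
                raise ValueError(f"refusing to edit geometry column {key!r}")
            table.loc[mask, key] = val
    return LogoLayer(data=table, method=layer.method,
                     font_name=layer.font_name, scheme=layer.scheme,
                     heights=layer.heights)


def compose(layers: Sequence[Any], offsets: Sequence[float]) -> pd.DataFrame:
    """Shift layers onto one y axis and concatenate their drawing tables.

    Every table of every layer (logo polygons, alignment tiles and
    letters, bar segments) is copied, its y-carrying columns (``y``,
    ``y_lo``, ``y_hi``) shifted by the layer's offset, and stacked into
    one long frame tagged with ``layer`` (index of the layer) and
    ``table`` (which drawing table the rows came from).  Inputs are not
    mutated; all layers share the 1-based position convention on x.
    """
    if len(layers) != len(offsets):
        raise ValueError(f"{len(layers)} layers but {len(offsets)} offsets")
    frames = []
    for i, (layer, off) in enumerate(zip(layers, offsets)):
        for name, tbl in layer.tables().items():
            t = tbl.copy()
            for col in ("y", "y_lo", "y_hi"):
                if col in t.columns:
                    t[col] = t[col] + off
            t.insert(0, "layer", i)
            t.insert(1, "table", name)
            frames.append(t)
    return pd.concat(frames, ignore_index=True, sort=False)
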
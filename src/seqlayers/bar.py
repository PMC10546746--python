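"""The per-position sequence-histogram layer.

``build_bar`` renders letter composition as stacked bar segments: per
position one segment per letter with a nonzero count, stacked with the
same tallest-on-top rule as logos.  The statistic is either raw counts
(default) or per-column proportions.  Letters can be overlaid in segments
tall enough to stay legible, or suppressed entirely (no-letter mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import colorschemes as cs
from . import fonts
from ._input import as_panels
from .logo import glyph_records, _resolve_scheme
from .seqstats import (FrequencyMatrix, HeightMatrix, SequenceSet, build_pfm,
                       stack, to_probability)

__all__ = ["BarLayer", "build_bar", "BAR_WIDTH", "LEGIBILITY_FRACTION"]

#: Bar width as a fraction of the unit position slot (matches logo letters).
BAR_WIDTH = 0.9
#: Segments shorter than this fraction of their column total get no letter.
LEGIBILITY_FRACTION = 0.05


@dataclass
class BarLayer:
    """A built sequence histogram: segment table, optional letter table.

    ``bar_data`` columns: letter, position, y_lo, y_hi, x, width,
    seq_group, col (or value), group.
    """

    bar_data: pd.DataFrame
    letter_data: pd.DataFrame | None
    statistic: str
    font_name: str
    scheme: cs.ColorScheme
    heights: dict[str, HeightMatrix]
    xlab: str = "position"

    @property
    def ylab(self) -> str:
        return {"count": "count", "proportion": "proportion"}[self.statistic]

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
        out = {"bar_data": self.bar_data}
        if self.letter_data is not None:
            out["letter_data"] = self.letter_data
        return out

    def y_extent(self) -> tuple[float, float]:
        if len(self.bar_data) == 0:
            return (0.0, 0.0)
        return 0.0, float(self.bar_data["y_hi"].max())


def build_bar(
    data: Any,
    statistic: str = "count",
    scheme: str | cs.ColorScheme | None = None,
    show_letters: bool = True,
    font_name: str | None = None,
    namespace: Iterable[str] | None = None,
) -> BarLayer:
    """Build a stacked per-position histogram of letter composition.

    ``statistic="count"`` stacks raw occurrence counts; ``"proportion"``
    rescales every column to total 1.  With ``show_letters=True`` a glyph
    is centered in each segment taller than 5% of its column total.
    """
    if statistic not in ("count", "proportion"):
        raise ValueError(f"statistic must be count/proportion, got {statistic!r}")
    font_name = font_name or fonts.list_fonts()[0]
    panels = as_panels(data, namespace)

    heights: dict[str, HeightMatrix] = {}
    for label, item in panels:
        if isinstance(item, SequenceSet):
            item = build_pfm(item)
        if isinstance(item, HeightMatrix):
            raise TypeError("build_bar needs sequences or a count matrix")
        if statistic == "proportion":
            heights[label] = to_probability(item)
        else:
            heights[label] = HeightMatrix(item.letters, item.counts, "custom",
                                          item.panel_label)

    letters_union: list[str] = []
    for hm in heights.values():
        for l in hm.letters:
            if l not in letters_union:
                letters_union.append(l)
    scheme = _resolve_scheme(scheme, letters_union)
    value_col = "col" if scheme.kind == "discrete" else "value"

    bar_rows = []
    letter_frames = []
    for label, hm in heights.items():
        totals = hm.heights.sum(axis=0)
        for iv in stack(hm):
            row = {
                "letter": iv.letter,
                "position": iv.position,
                "y_lo": iv.y_lo,
                "y_hi": iv.y_hi,
                "x": float(iv.position),
                "width": BAR_WIDTH,
                "seq_group": label,
                "group": iv.letter,
            }
            if scheme.kind == "discrete":
                row["col"] = scheme.color_of(iv.letter)
            else:
                default = min(scheme.mapping.values(), default=0.0)
                row["value"] = float(scheme.mapping.get(iv.letter, default))
            bar_rows.append(row)

            total = totals[iv.position - 1]
            if show_letters and total > 0 and iv.height > LEGIBILITY_FRACTION * total:
                # glyph centered in the segment at 60% of its height
                mid = (iv.y_lo + iv.y_hi) / 2
                half = 0.3 * iv.height
                rec = glyph_records(iv.letter, font_name, iv.position, 0.5,
                                    mid - half, mid + half)
                if rec is None:
                    continue
                rec.insert(0, "letter", iv.letter)
                rec.insert(1, "position", iv.position)
                rec["seq_group"] = label
                rec["group"] = f"{label}.{iv.position}.{iv.letter}"
                bar_col = row.get("col", cs.FALLBACK_COLOR)
                from .align import letter_ink
                rec["col"] = letter_ink(bar_col)
                letter_frames.append(rec)

    bar_data = pd.DataFrame(bar_rows)
    letter_data = None
    if show_letters:
        letter_data = (pd.concat(letter_frames, ignore_index=True)
                       if letter_frames else pd.DataFrame())
    return BarLayer(bar_data=bar_data, letter_data=letter_data,
                    statistic=statistic, font_name=font_name, scheme=scheme,
                    heights=heights)
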
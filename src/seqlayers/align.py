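"""The multiple-sequence-alignment tile layer.

``build_align`` lays every aligned sequence out as one row of unit tiles
(one tile per residue) and optionally overlays the residue letters as
glyph polygons.  The color scheme paints either the tile backgrounds
(``scheme_applied="BACKGROUND"``, letters drawn in a legible ink color)
or the letters themselves (``"LETTER"``, tiles stay neutral).  Both
drawing tables are public and mutable, like every layer in the package.

The background-tile table schema is fixed: columns ``letter, position,
y_index, x, y, width, height, seq_group`` always, plus ``col`` and
``group`` only in BACKGROUND mode with a discrete scheme (``value`` and
``group`` for a continuous one).  Geometry is fully determined: ``x =
position``, ``y = y_index - 0.5``, ``width = height = 1``, so the tiles
of a k-sequence, L-column panel exactly partition the rectangle
[0.5, L+0.5] x [0, k].
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
from .seqstats import GAP, SequenceSet

__all__ = ["AlignLayer", "build_align", "row_order", "letter_ink"]

#: Letters fill this fraction of their tile, centered.
_LETTER_FRACTION = 0.9


def row_order(seqs: SequenceSet) -> list[int]:
    """1-based y_index per sequence: the first input sequence gets 1.

    The rendered y axis is reversed so that sequence 1 reads as the top
    row, the conventional MSA orientation.
    """
    return list(range(1, len(seqs) + 1))


def letter_ink(tile_color: str) -> str:
    """Black on light tiles, white on dark, by relative luminance."""
    r, g, b = (int(tile_color[i:i + 2], 16) / 255 for i in (1, 3, 5))
    lum = 0.2126 * r + 0.7152 * g + 0.0722 * b
    return "#000000" if lum >= 0.5 else "#FFFFFF"


@dataclass
class AlignLayer:
    """A built alignment diagram: tile table, optional letter table."""

    bg_data: pd.DataFrame
    letter_data: pd.DataFrame | None
    scheme_applied: str
    font_name: str
    scheme: cs.ColorScheme
    panels: dict[str, SequenceSet]
    xlab: str = "position"
    ylab: str = ""

    @property
    def n_positions(self) -> int:
        return max(s.length for s in self.panels.values())

    @property
    def panel_labels(self) -> list[str]:
        return list(self.panels)

    @property
    def x_breaks(self) -> list[int]:
        return list(range(1, self.n_positions + 1))

    def y_ticks(self) -> tuple[list[float], list[str]]:
        """Row-center tick positions labeled by sequence index."""
        k = max(len(s) for s in self.panels.values())
        return [i - 0.5 for i in range(1, k + 1)], [str(i) for i in range(1, k + 1)]

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"bg_data": self.bg_data}
        if self.letter_data is not None:
            out["letter_data"] = self.letter_data
        return out

    def y_extent(self) -> tuple[float, float]:
        return 0.0, float(max(len(s) for s in self.panels.values()))


def build_align(
    data: Any,
    scheme: str | cs.ColorScheme | None = None,
    scheme_applied: str = "BACKGROUND",
    show_letters: bool = True,
    font_name: str | None = None,
    namespace: Iterable[str] | None = None,
) -> AlignLayer:
    """Build an alignment tile diagram from sequences or a label mapping.

    ``scheme_applied="BACKGROUND"`` colors the tiles by residue and inks
    letters black/white for contrast; ``"LETTER"`` keeps neutral tiles
    and colors the glyphs instead.  ``show_letters=False`` drops the
    letter table entirely (no-letter mode).  Gap tiles render in a pale
    neutral and never carry a glyph.
    """
    if scheme_applied not in ("BACKGROUND", "LETTER"):
        raise ValueError(
            f"scheme_applied must be 'BACKGROUND' or 'LETTER', got "
            f"{scheme_applied!r}"
        )
    font_name = font_name or fonts.list_fonts()[0]
    panels = dict(as_panels(data, namespace))
    for label, item in panels.items():
        if not isinstance(item, SequenceSet):
            raise TypeError(
                "build_align needs aligned sequences (matrix input has no "
                f"rows to draw); panel {label!r} is {type(item).__name__}"
            )

    letters_union: list[str] = []
    for s in panels.values():
        for l in s.alphabet:
            if l not in letters_union:
                letters_union.append(l)
    scheme = _resolve_scheme(scheme, letters_union)
    background = scheme_applied == "BACKGROUND"

    bg_rows = []
    letter_frames = []
    for label, seqset in panels.items():
        for y_index, seq in zip(row_order(seqset), seqset.sequences):
            for j, letter in enumerate(seq, start=1):
                row = {
                    "letter": letter,
                    "position": j,
                    "y_index": y_index,
                    "x": float(j),
                    "y": y_index - 0.5,
                    "width": 1.0,
                    "height": 1.0,
                    "seq_group": label,
                }
                if background:
                    if scheme.kind == "discrete":
                        row["col"] = (cs.GAP_TILE_COLOR if letter == GAP
                                      else scheme.color_of(letter))
                    else:
                        default = min(scheme.mapping.values(), default=0.0)
                        row["value"] = float(scheme.mapping.get(letter, default))
                    row["group"] = letter
                bg_rows.append(row)

                if show_letters and letter != GAP:
                    pad = (1 - _LETTER_FRACTION) / 2
                    rec = glyph_records(
                        letter, font_name, j, _LETTER_FRACTION,
                        y_index - 1 + pad, y_index - pad,
                    )
                    if rec is None:
                        continue
                    rec.insert(0, "letter", letter)
                    rec.insert(1, "position", j)
                    rec.insert(2, "y_index", y_index)
                    rec["seq_group"] = label
                    rec["group"] = f"{label}.{j}.{y_index}.{letter}"
                    if background:
                        tile = row.get("col", cs.FALLBACK_COLOR)
                        rec["col"] = letter_ink(tile)
                    else:
                        colors = cs.assign_colors(scheme, rec["letter"])
                        key = "col" if scheme.kind == "discrete" else "value"
                        rec[key] = colors[key].to_numpy()
                    letter_frames.append(rec)

    bg = pd.DataFrame(bg_rows)
    letter_data = (pd.concat(letter_frames, ignore_index=True)
                   if show_letters and letter_frames else
                   (pd.DataFrame() if show_letters else None))
    if not show_letters:
        letter_data = None
    return AlignLayer(bg_data=bg, letter_data=letter_data,
                      scheme_applied=scheme_applied, font_name=font_name,
                      scheme=scheme, panels=panels)
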
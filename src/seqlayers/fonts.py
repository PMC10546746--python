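"""Glyph outlines for letter drawing.

A sequence logo draws characters as filled polygons so each letter can be
stretched to exactly fill its stacked interval.  This module keeps a
catalog of 15 built-in fonts; for every printable ASCII character of every
font it stores the character's outline as one or more closed polygon
*pieces* (outer contours plus holes, filled with the even-odd rule),
normalized to the unit box [0,1] x [0,1].

The built-in catalog is extracted on first use from the TrueType fonts
that ship with matplotlib (DejaVu and STIX families): the bezier outlines
are flattened to polygons by matplotlib's text-path machinery and then
tight-box normalized.  ``build_font_catalog`` runs the same extraction on
any user-supplied TTF/OTF files, and ``save_catalog``/``load_catalog``
read and write a plain columnar text format so a frozen catalog can be
audited or shipped.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.font_manager import get_font as _freetype_font
from matplotlib.textpath import TextPath

import matplotlib

__all__ = [
    "GlyphOutline",
    "FontCatalog",
    "list_fonts",
    "get_font",
    "get_glyph",
    "place_glyph",
    "build_font_catalog",
    "save_catalog",
    "load_catalog",
    "SUPPORTED_CHARS",
]

#: Characters every built-in font covers: printable ASCII minus space.
SUPPORTED_CHARS: str = "".join(chr(c) for c in range(33, 127))

# Glyphs are flattened at TextPath's default chord tolerance for an em size
# of 100 units, i.e. curves deviate from true beziers by < 1/500 em.
_EM = 100.0


@dataclass(frozen=True)
class GlyphOutline:
    """One character's polygon outline in the unit box.

    ``points`` is an (N, 2) array of (gx, gy) vertices, ``piece_id`` an
    (N,) integer array grouping vertices into closed sub-paths: piece 0 is
    an outer contour, further pieces may be holes (the fill rule is
    even-odd, so containment decides what is a hole).  ``winding`` holds
    the signed orientation (+1 counter-clockwise, -1 clockwise) of each
    piece in piece order.
    """

    character: str
    font_name: str
    points: np.ndarray
    piece_id: np.ndarray
    winding: tuple[int, ...]

    def pieces(self) -> list[np.ndarray]:
        """The closed sub-paths as a list of (n_i, 2) arrays."""
        return [self.points[self.piece_id == p]
                for p in sorted(set(self.piece_id.tolist()))]


@dataclass(frozen=True)
class FontCatalog:
    """A named set of fonts, each mapping characters to glyph outlines."""

    entries: Mapping[str, Mapping[str, GlyphOutline]]
    default: str

    def __post_init__(self):
        if self.default not in self.entries:
            raise ValueError(f"default font {self.default!r} not in catalog")

    def names(self) -> list[str]:
        names = sorted(self.entries)
        names.remove(self.default)
        return [self.default] + names


def _mpl_ttf(basename: str) -> str:
    return os.path.join(matplotlib.get_data_path(), "fonts", "ttf", basename)


# The 15 built-in fonts, named by family and style.  First is the default.
_BUILTIN_FILES: dict[str, str] = {
    "sans-bold": "DejaVuSans-Bold.ttf",
    "sans": "DejaVuSans.ttf",
    "sans-oblique": "DejaVuSans-Oblique.ttf",
    "sans-bold-oblique": "DejaVuSans-BoldOblique.ttf",
    "serif": "DejaVuSerif.ttf",
    "serif-bold": "DejaVuSerif-Bold.ttf",
    "serif-italic": "DejaVuSerif-Italic.ttf",
    "serif-bold-italic": "DejaVuSerif-BoldItalic.ttf",
    "mono": "DejaVuSansMono.ttf",
    "mono-bold": "DejaVuSansMono-Bold.ttf",
    "mono-oblique": "DejaVuSansMono-Oblique.ttf",
    "mono-bold-oblique": "DejaVuSansMono-BoldOblique.ttf",
    "stix": "STIXGeneral.ttf",
    "stix-bold": "STIXGeneralBol.ttf",
    "stix-italic": "STIXGeneralItalic.ttf",
}

_DEFAULT_FONT = "sans-bold"

# Lazily populated cache: font name -> {char -> GlyphOutline}.
_cache: dict[str, dict[str, GlyphOutline]] = {}


def _piece_winding(poly: np.ndarray) -> int:
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    return 1 if area2 >= 0 else -1


def _extract_glyph(char: str, font_name: str, prop: FontProperties) -> GlyphOutline | None:
    """Flatten one character's outline and normalize it to the unit box."""
    path = TextPath((0, 0), char, size=_EM, prop=prop)
    polys = [np.asarray(p, dtype=float) for p in path.to_polygons()]
    polys = [p for p in polys if len(p) >= 3]
    if not polys:
        return None
    allpts = np.vstack(polys)
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    points, piece_id, winding = [], [], []
    for k, p in enumerate(polys):
        # drop a repeated closing vertex; closure is implied per piece
        if np.allclose(p[0], p[-1]):
            p = p[:-1]
        if len(p) < 3:
            continue
        q = (p - lo) / span
        points.append(q)
        piece_id.append(np.full(len(q), k))
        winding.append(_piece_winding(q))
    return GlyphOutline(
        character=char,
        font_name=font_name,
        points=np.vstack(points),
        piece_id=np.concatenate(piece_id).astype(int),
        winding=tuple(winding),
    )


def _load_font(name: str) -> dict[str, GlyphOutline]:
    if name not in _cache:
        if name not in _BUILTIN_FILES:
            raise KeyError(
                f"unknown font {name!r}; valid fonts: {', '.join(list_fonts())}"
            )
        prop = FontProperties(fname=_mpl_ttf(_BUILTIN_FILES[name]))
        glyphs = {}
        for ch in SUPPORTED_CHARS:
            g = _extract_glyph(ch, name, prop)
            if g is not None:
                glyphs[ch] = g
        _cache[name] = glyphs
    return _cache[name]


def list_fonts() -> list[str]:
    """Names of the 15 built-in fonts; the first entry is the default."""
    names = sorted(_BUILTIN_FILES)
    names.remove(_DEFAULT_FONT)
    return [_DEFAULT_FONT] + names


def get_font(name: str) -> dict[str, GlyphOutline]:
    """All glyph outlines of one built-in font, keyed by character."""
    return dict(_load_font(name))


def get_glyph(char: str, font_name: str | None = None) -> GlyphOutline:
    """One character's outline; falls back to the default font."""
    font = _load_font(font_name or _DEFAULT_FONT)
    if char not in font:
        raise KeyError(
            f"character {char!r} has no outline in font {font_name!r}"
        )
    return font[char]


def place_glyph(
    outline: GlyphOutline,
    x_center: float,
    width: float,
    y_base: float,
    height: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Affinely map a unit-box glyph into a letter slot.

    Returns ``(points, piece_id)`` with
    ``X = x_center - width/2 + gx * width`` and, for nonnegative height,
    ``Y = y_base + gy * height``.  A negative height draws the glyph
    *upright* in the interval ``[y_base + height, y_base]`` — letters
    below the axis stay readable rather than being mirrored.  Zero height
    yields a degenerate zero-area polygon (renderers draw nothing).
    """
    if width <= 0:
        raise ValueError(f"width must be positive, got {width}")
    gx = outline.points[:, 0]
    gy = outline.points[:, 1]
    X = x_center - width / 2.0 + gx * width
    if height >= 0:
        Y = y_base + gy * height
    else:
        Y = y_base + height + gy * (-height)
    return np.column_stack([X, Y]), outline.piece_id.copy()


def build_font_catalog(
    source_font_files: Iterable[str | os.PathLike],
    default: str | None = None,
    chars: str = SUPPORTED_CHARS,
) -> FontCatalog:
    """Extract a catalog from TTF/OTF files, one font per file.

    Font names are the file stems.  Outlines are flattened and unit-box
    normalized exactly as for the built-in catalog.
    """
    entries: dict[str, dict[str, GlyphOutline]] = {}
    names = []
    for f in source_font_files:
        f = Path(f)
        if not f.is_file():
            raise FileNotFoundError(f"font file not readable: {f}")
        name = f.stem
        try:
            _freetype_font(str(f))  # validates the font file via FreeType
        except Exception as exc:  # pragma: no cover - corrupt font
            raise ValueError(f"cannot parse font file {f}: {exc}") from exc
        prop = FontProperties(fname=str(f))
        glyphs = {}
        for ch in chars:
            g = _extract_glyph(ch, name, prop)
            if g is not None:
                glyphs[ch] = g
        entries[name] = glyphs
        names.append(name)
    if not entries:
        raise ValueError("no font files given")
    return FontCatalog(entries=entries, default=default or names[0])


def builtin_catalog() -> FontCatalog:
    """The full 15-font built-in catalog (forces extraction of all fonts)."""
    return FontCatalog(
        entries={name: _load_font(name) for name in list_fonts()},
        default=_DEFAULT_FONT,
    )


def save_catalog(catalog: FontCatalog, path: str | os.PathLike) -> None:
    """Write a catalog as columnar text.

    Format: a header line ``#seqlayers-font-catalog v1 default=<name>``,
    then one line per vertex: ``font<TAB>codepoint<TAB>piece<TAB>order``
    ``<TAB>gx<TAB>gy``.  Coordinates are printed with 6 decimals.
    """
    with open(path, "w") as fh:
        fh.write(f"#seqlayers-font-catalog v1 default={catalog.default}\n")
        fh.write("font\tcodepoint\tpiece\torder\tgx\tgy\n")
        for font in catalog.names():
            for ch, g in sorted(catalog.entries[font].items()):
                order = 0
                for pid, (gx, gy) in zip(g.piece_id, g.points):
                    fh.write(f"{font}\t{ord(ch)}\t{pid}\t{order}"
                             f"\t{gx:.6f}\t{gy:.6f}\n")
                    order += 1


def load_catalog(path: str | os.PathLike) -> FontCatalog:
    """Read a catalog written by :func:`save_catalog`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#seqlayers-font-catalog"):
            raise ValueError(f"{path} is not a seqlayers font catalog")
        default = header.split("default=")[1]
        fh.readline()  # column header
        rows: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
        for line in fh:
            font, cp, pid, _order, gx, gy = line.rstrip("\n").split("\t")
            rows.setdefault((font, chr(int(cp))), []).append(
                (int(pid), float(gx), float(gy))
            )
    entries: dict[str, dict[str, GlyphOutline]] = {}
    for (font, ch), verts in rows.items():
        pts = np.array([(gx, gy) for _, gx, gy in verts])
        pid = np.array([p for p, _, _ in verts], dtype=int)
        winding = tuple(
            _piece_winding(pts[pid == p]) for p in sorted(set(pid.tolist()))
        )
        entries.setdefault(font, {})[ch] = GlyphOutline(ch, font, pts, pid, winding)
    return FontCatalog(entries=entries, default=default)
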
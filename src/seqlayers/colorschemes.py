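"""Letter color schemes.

Eight named schemes ship with the package — three for nucleic-acid
alphabets (``nucleotide``, ``nucleotide2``, ``base_pairing``) and five for
the amino-acid alphabet (``chemistry``, ``chemistry2``, ``hydrophobicity``,
``clustalx``, ``taylor``).  All are discrete letter -> hex-color maps
except ``hydrophobicity``, which maps residues to the Kyte–Doolittle
hydropathy scale and renders through a two-stop gradient.  Letters a
scheme does not cover fall back to a neutral grey, so color assignment is
total over any alphabet.

``make_col_scheme`` builds custom schemes — discrete from a color list,
continuous from a value list — and layers accept them anywhere a built-in
scheme name is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ColorScheme",
    "list_schemes",
    "get_col_scheme",
    "make_col_scheme",
    "assign_colors",
    "FALLBACK_COLOR",
    "GAP_TILE_COLOR",
]

#: Neutral grey used for letters a scheme does not cover.
FALLBACK_COLOR = "#808080"
#: Pale neutral for gap tiles in alignment diagrams (distinct from fallback).
GAP_TILE_COLOR = "#F0F0F0"

_HEX_RE = re.compile(r"^#[0-9A-Fa-f]{6}$")


@dataclass(frozen=True)
class ColorScheme:
    """A named letter coloring, either discrete or continuous.

    Discrete schemes map letters straight to ``#RRGGBB`` colors.
    Continuous schemes map letters to finite numeric values which the
    renderer sends through ``gradient`` (at least two ordered color
    stops, low value first).
    """

    name: str
    kind: str  # "discrete" | "continuous"
    mapping: Mapping[str, str] | Mapping[str, float]
    gradient: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"kind must be discrete/continuous, got {self.kind!r}")
        if self.kind == "discrete":
            for letter, color in self.mapping.items():
                if not _HEX_RE.match(str(color)):
                    raise ValueError(
                        f"scheme {self.name!r}: color {color!r} for letter "
                        f"{letter!r} is not a #RRGGBB hex string"
                    )
        else:
            if len(self.gradient) < 2:
                raise ValueError("continuous scheme needs >= 2 gradient stops")
            for letter, value in self.mapping.items():
                v = float(value)
                if v != v or v in (float("inf"), float("-inf")):
                    raise ValueError(
                        f"scheme {self.name!r}: non-finite value for {letter!r}"
                    )
        object.__setattr__(self, "mapping", dict(self.mapping))

    @property
    def applies_to(self) -> frozenset[str]:
        return frozenset(self.mapping)

    def color_of(self, letter: str) -> str:
        """Discrete lookup with the neutral fallback for unknown letters."""
        if self.kind != "discrete":
            raise ValueError("color_of is only defined for discrete schemes")
        return self.mapping.get(letter, FALLBACK_COLOR)

    def restricted_to(self, alphabet: Iterable[str]) -> "ColorScheme":
        """The scheme over one alphabet; uncovered letters get the fallback."""
        alpha = list(alphabet)
        if self.kind == "discrete":
            mapping = {l: self.mapping.get(l, FALLBACK_COLOR) for l in alpha}
            return ColorScheme(self.name, "discrete", mapping)
        mapping = {l: float(self.mapping[l]) for l in alpha if l in self.mapping}
        return ColorScheme(self.name, "continuous", mapping, self.gradient)


# ---------------------------------------------------------------------------
# Built-in palettes.  The DNA background default pins T = #D62839; its
# green/blue/amber/red companions follow the widely used logo palette the
# scheme name refers to.  clustalx and taylor reproduce the canonical
# ClustalX and Taylor residue colors; chemistry groups residues by side
# chain class (polar / neutral / basic / acidic / hydrophobic).

_NT = {
    "A": "#109648", "C": "#255C99", "G": "#F7B32B",
    "T": "#D62839", "U": "#D62839",
}
_NT2 = {
    "A": "#33A02C", "C": "#1F78B4", "G": "#FF7F00",
    "T": "#E31A1C", "U": "#E31A1C",
}
_BASE_PAIRING = {  # weak A/T(U) vs strong G/C pairing
    "A": "#F7B32B", "T": "#F7B32B", "U": "#F7B32B",
    "G": "#255C99", "C": "#255C99",
}


def _by_class(classes: Mapping[str, str], colors: Mapping[str, str]) -> dict[str, str]:
    return {l: colors[cls] for cls, letters in classes.items() for l in letters}


_AA_CLASSES = {
    "polar": "GSTYC",
    "neutral": "QN",
    "basic": "KRH",
    "acidic": "DE",
    "hydrophobic": "AVLIPWFM",
}
_CHEMISTRY = _by_class(_AA_CLASSES, {
    "polar": "#109648", "neutral": "#5E239D", "basic": "#255C99",
    "acidic": "#D62839", "hydrophobic": "#221E22",
})
_CHEMISTRY2 = _by_class(_AA_CLASSES, {
    "polar": "#2FA42A", "neutral": "#9161F2", "basic": "#2D6FD9",
    "acidic": "#F04438", "hydrophobic": "#6B6B6B",
})

# Kyte & Doolittle hydropathy index, rendered blue (hydrophilic) -> red.
_HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

_CLUSTALX = {
    **{l: "#80A0F0" for l in "AILMFWV"},
    **{l: "#F01505" for l in "KR"},
    **{l: "#C048C0" for l in "ED"},
    **{l: "#15C015" for l in "NQST"},
    "C": "#F08080", "G": "#F09048", "P": "#C0C000",
    **{l: "#15A4A4" for l in "HY"},
}

_TAYLOR = {
    "A": "#CCFF00", "C": "#FFFF00", "D": "#FF0000", "E": "#FF0066",
    "F": "#00FF66", "G": "#FF9900", "H": "#0066FF", "I": "#66FF00",
    "K": "#6600FF", "L": "#33FF00", "M": "#00FF00", "N": "#CC00FF",
    "P": "#FFCC00", "Q": "#FF00CC", "R": "#0000FF", "S": "#FF3300",
    "T": "#FF6600", "V": "#99FF00", "W": "#00CCFF", "Y": "#00FFCC",
}

_SCHEMES: dict[str, ColorScheme] = {
    "chemistry": ColorScheme("chemistry", "discrete", _CHEMISTRY),
    "chemistry2": ColorScheme("chemistry2", "discrete", _CHEMISTRY2),
    "hydrophobicity": ColorScheme(
        "hydrophobicity", "continuous", _HYDROPHOBICITY,
        gradient=("#255C99", "#D62839"),
    ),
    "nucleotide": ColorScheme("nucleotide", "discrete", _NT),
    "nucleotide2": ColorScheme("nucleotide2", "discrete", _NT2),
    "base_pairing": ColorScheme("base_pairing", "discrete", _BASE_PAIRING),
    "clustalx": ColorScheme("clustalx", "discrete", _CLUSTALX),
    "taylor": ColorScheme("taylor", "discrete", _TAYLOR),
}

#: Scheme names defined over nucleic-acid alphabets.
NUCLEIC_SCHEMES = ("nucleotide", "nucleotide2", "base_pairing")
#: Scheme names defined over the amino-acid alphabet.
AMINO_SCHEMES = ("chemistry", "chemistry2", "hydrophobicity", "clustalx", "taylor")


def list_schemes() -> list[str]:
    """The 8 built-in scheme names, in a stable order."""
    return ["chemistry", "chemistry2", "hydrophobicity", "nucleotide",
            "nucleotide2", "base_pairing", "clustalx", "taylor"]


def get_col_scheme(name: str, alphabet: Iterable[str] | None = None) -> ColorScheme:
    """Fetch a built-in scheme, optionally restricted to an alphabet.

    With an alphabet given, a discrete scheme covers every alphabet letter
    (uncovered ones fall back to neutral grey); a continuous scheme keeps
    only the letters it has values for.
    """
    if name not in _SCHEMES:
        raise KeyError(
            f"unknown color scheme {name!r}; valid schemes: "
            f"{', '.join(list_schemes())}"
        )
    scheme = _SCHEMES[name]
    if alphabet is None:
        return scheme
    return scheme.restricted_to(alphabet)


def make_col_scheme(
    letters: Sequence[str],
    colors: Sequence[str] | None = None,
    values: Sequence[float] | None = None,
    name: str = "custom",
    gradient: Sequence[str] = ("#255C99", "#D62839"),
) -> ColorScheme:
    """Build a custom scheme from parallel letter/color or letter/value lists.

    Exactly one of ``colors`` (discrete) or ``values`` (continuous) must be
    supplied, with the same length as ``letters``.
    """
    if (colors is None) == (values is None):
        raise ValueError("supply exactly one of colors= or values=")
    letters = list(letters)
    if not letters:
        raise ValueError("letters must be nonempty")
    if colors is not None:
        if len(colors) != len(letters):
            raise ValueError(
                f"{len(letters)} letters but {len(colors)} colors"
            )
        return ColorScheme(name, "discrete", dict(zip(letters, colors)))
    if len(values) != len(letters):
        raise ValueError(f"{len(letters)} letters but {len(values)} values")
    return ColorScheme(
        name, "continuous",
        {l: float(v) for l, v in zip(letters, values)},
        gradient=tuple(gradient),
    )


def default_scheme(alphabet: Iterable[str]) -> ColorScheme:
    """The scheme a layer uses when none is given.

    Nucleic alphabets get ``nucleotide`` (whose T is the pinned #D62839),
    the amino-acid alphabet gets ``chemistry``; any other alphabet gets an
    all-fallback discrete scheme so custom symbols render in neutral grey
    until the user supplies colors.
    """
    alpha = [l for l in alphabet]
    members = set(alpha)
    if members and members <= set("ACGTU"):
        return get_col_scheme("nucleotide", alpha)
    if members and members <= set("ACDEFGHIKLMNPQRSTVWY"):
        return get_col_scheme("chemistry", alpha)
    return ColorScheme("none", "discrete", {l: FALLBACK_COLOR for l in alpha})


def assign_colors(scheme: ColorScheme, table_letters: Sequence[str]) -> pd.DataFrame:
    """Per-record color (or value) and fill-group columns for a letter column.

    Discrete schemes yield a ``col`` column of hex colors; continuous
    schemes yield a numeric ``value`` column the renderer maps through the
    gradient.  Both get a ``group`` column equal to the letter so fill
    aesthetics resolve per letter.
    """
    letters = list(table_letters)
    if scheme.kind == "discrete":
        return pd.DataFrame({
            "col": [scheme.color_of(l) for l in letters],
            "group": letters,
        })
    default = min(scheme.mapping.values(), default=0.0)
    return pd.DataFrame({
        "value": [float(scheme.mapping.get(l, default)) for l in letters],
        "group": letters,
    })
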
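"""The plain presentation theme and shared axis conventions.

Sequence figures want a quiet canvas: white background, no grid, integer
x breaks at the alignment positions, a y label that states the layer's
unit (bits / probability / count) and nothing else.  ``theme_seq``
returns that specification; ``apply_theme`` imposes it on a matplotlib
axes.  Theme application only touches presentation — layer drawing
tables are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

__all__ = ["ThemeSpec", "theme_seq", "axis_metadata", "apply_theme"]


@dataclass(frozen=True)
class ThemeSpec:
    """Presentation settings shared by all layers."""

    background: str = "#FFFFFF"
    grid: bool = False
    axis_text: bool = True
    axis_ticks: bool = True
    legend: str = "none"  # "none" | "right"

    def merged(self, **overrides: Any) -> "ThemeSpec":
        """A copy with user overrides; user values win."""
        return replace(self, **overrides)


def theme_seq() -> ThemeSpec:
    """The plain-white sequence theme: white panel, no grid.

    Idempotent and side-effect free; merge user overrides with
    :meth:`ThemeSpec.merged`.
    """
    return ThemeSpec()


def axis_metadata(layer) -> dict[str, Any]:
    """x/y scale and label specification for a built layer.

    x breaks sit at the integer positions 1..L; the y label follows the
    layer's method or statistic (empty for custom logos and alignments);
    alignment layers additionally get y ticks at row centers labeled by
    sequence index.
    """
    meta: dict[str, Any] = {
        "x_breaks": layer.x_breaks,
        "x_label": layer.xlab,
        "y_label": layer.ylab,
    }
    if hasattr(layer, "y_ticks"):
        ticks, labels = layer.y_ticks()
        meta["y_ticks"] = ticks
        meta["y_tick_labels"] = labels
        meta["y_reversed"] = True
    return meta


def merge_x_breaks(layers) -> list[int]:
    """The union of integer x breaks across composed layers, sorted."""
    breaks: set[int] = set()
    for layer in layers:
        breaks.update(layer.x_breaks)
    return sorted(breaks)


def apply_theme(ax, spec: ThemeSpec | None = None) -> None:
    """Impose a :class:`ThemeSpec` on a matplotlib axes (presentation only)."""
    spec = spec or theme_seq()
    ax.set_facecolor(spec.background)
    ax.grid(spec.grid)
    for side in ("top", "right", "left", "bottom"):
        ax.spines[side].set_visible(False)
    ax.tick_params(
        labelleft=spec.axis_text, labelbottom=spec.axis_text,
        left=spec.axis_ticks, bottom=spec.axis_ticks,
    )
    if spec.legend == "none":
        legend = ax.get_legend()
        if legend is not None:
            legend.remove()
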
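"""Simulated agarose-gel rendering as deterministic SVG.

Band vertical position follows a pure log-length migration model: the
well (scale top) corresponds to the largest resolvable length and the
gel bottom to ``cutoff_len``; bands shorter than the cutoff run off the
gel and are not drawn. Topology-dependent mobility (linear vs circular
vs supercoiled) is deliberately not modelled. Near-coincident bands in a
lane merge into one thicker band — as on a real gel — but every length
stays exact in the tabular report; merged bands carry a
``data-multiplicity`` attribute.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace

from .digestion import BandPattern

DEFAULT_LADDER = (
    100, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 5000, 6000, 8000, 10_000,
)

# Colorblind-friendly lane colors, one per input sequence.
DEFAULT_LANE_COLORS = ("#d95f02", "#1b9e77", "#7570b3")

_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_-]")


@dataclass(frozen=True)
class GelLayout:
    """Geometry and scale of one simulated gel."""

    top_len: int = 10_000
    cutoff_len: int = 50
    ladder: tuple[int, ...] = DEFAULT_LADDER
    lane_width: float = 60.0
    lane_gap: float = 20.0
    height: float = 400.0
    lane_colors: tuple[str, ...] = DEFAULT_LANE_COLORS
    margin: float = 30.0
    band_thickness: float = 3.0
    merge_frac: float = 0.01  # bands closer than this fraction of gel height merge

    def __post_init__(self) -> None:
        if not self.cutoff_len < self.top_len:
            raise ValueError("cutoff_len must be < top_len")
        if len(self.ladder) < 2:
            raise ValueError("ladder needs at least 2 rungs")
        if any(not 0 < r <= self.top_len for r in self.ladder):
            raise ValueError("ladder rungs must lie in (0, top_len]")


def band_y(length: int, layout: GelLayout) -> float:
    """Normalized vertical band position in [0, 1]; 0 = well, 1 = cutoff.

    y = (log10(top) - log10(length)) / (log10(top) - log10(cutoff)),
    clamped: lengths above the scale top sit at the well (unresolved),
    lengths below the cutoff clamp to 1 (but are not drawn).
    """
    if length < 1:
        raise ValueError("band length must be >= 1 bp")
    span = math.log10(layout.top_len) - math.log10(layout.cutoff_len)
    y = (math.log10(layout.top_len) - math.log10(length)) / span
    return min(1.0, max(0.0, y))


def sanitize_name(name: str) -> str:
    return _SANITIZE_RE.sub("_", name)


def _merge_bands(
    lengths: tuple[int, ...], layout: GelLayout
) -> list[tuple[float, int]]:
    """Group visible bands into (y, multiplicity) pairs, merging bands
    whose positions differ by less than the merge threshold."""
    ys = sorted(
        band_y(x, layout) for x in lengths if x >= layout.cutoff_len
    )
    merged: list[tuple[float, int]] = []
    for y in ys:
        if merged and y - merged[-1][0] < layout.merge_frac:
            prev_y, k = merged[-1]
            merged[-1] = (prev_y, k + 1)
        else:
            merged.append((y, 1))
    return merged


def render_gel(
    patterns: list[BandPattern] | tuple[BandPattern, ...],
    layout: GelLayout | None = None,
    title: str = "",
) -> str:
    """Render one gel: a ladder lane plus one lane per pattern, as SVG text.

    Pure function of its inputs: identical inputs give byte-identical
    SVG. The scale top is raised to cover the largest band or ladder
    rung so nothing is silently clipped above the well.
    """
    if not patterns:
        raise ValueError("render_gel needs at least one pattern")
    layout = layout or GelLayout()
    largest = max(
        [max(p.lengths, default=0) for p in patterns] + [max(layout.ladder)]
    )
    if largest > layout.top_len:
        layout = replace(layout, top_len=largest)

    n_lanes = 1 + len(patterns)
    width = 2 * layout.margin + n_lanes * layout.lane_width + (
        n_lanes - 1
    ) * layout.lane_gap
    total_h = layout.height + 2 * layout.margin + 20.0

    def lane_x(i: int) -> float:
        return layout.margin + i * (layout.lane_width + layout.lane_gap)

    def ypix(y: float) -> float:
        return layout.margin + 20.0 + y * layout.height

    out: list[str] = []
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width:.0f}" height="{total_h:.0f}" '
        f'viewBox="0 0 {width:.0f} {total_h:.0f}">'
    )
    out.append(f"<title>{_escape(title)}</title>")
    out.append(
        f'<rect x="0" y="0" width="{width:.0f}" height="{total_h:.0f}" '
        f'fill="#1a1a2e"/>'
    )
    out.append(
        f'<text x="{width / 2:.1f}" y="{layout.margin:.1f}" fill="#eeeeee" '
        f'font-family="sans-serif" font-size="14" '
        f'text-anchor="middle">{_escape(title)}</text>'
    )

    # Lane 1: ladder with annotated sizes.
    x0 = lane_x(0)
    for rung in sorted(layout.ladder, reverse=True):
        y = ypix(band_y(rung, layout))
        out.append(
            f'<rect x="{x0:.1f}" y="{y:.1f}" width="{layout.lane_width:.1f}" '
            f'height="{layout.band_thickness:.1f}" fill="#cccccc" '
            f'class="ladder" data-length="{rung}"/>'
        )
        out.append(
            f'<text x="{x0 - 4:.1f}" y="{y + 3:.1f}" fill="#aaaaaa" '
            f'font-family="sans-serif" font-size="8" '
            f'text-anchor="end">{rung}</text>'
        )

    # Lanes 2..: one per pattern, distinct colors, merged close bands.
    for i, pat in enumerate(patterns):
        x = lane_x(i + 1)
        color = layout.lane_colors[i % len(layout.lane_colors)]
        out.append(
            f'<text x="{x + layout.lane_width / 2:.1f}" '
            f'y="{layout.margin + 14:.1f}" fill="{color}" '
            f'font-family="sans-serif" font-size="9" '
            f'text-anchor="middle">{_escape(pat.source_id)}</text>'
        )
        for y, mult in _merge_bands(pat.lengths, layout):
            thick = layout.band_thickness * (2.0 if mult > 1 else 1.0)
            out.append(
                f'<rect x="{x:.1f}" y="{ypix(y):.1f}" '
                f'width="{layout.lane_width:.1f}" height="{thick:.1f}" '
                f'fill="{color}" class="band" data-multiplicity="{mult}"/>'
            )
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )
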
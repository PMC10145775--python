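"""Annular graphical summary of one analyzed recording.

The chart reads clockwise from 12 o'clock, one angular sector per segmented
regime with extent proportional to its duration, sectors separated by black
radial lines.  The outer ring encodes the regime type (dark blue =
non-sedentary activity, standard blue = sedentary activity, light blue =
walking); the four inner rings encode, per walking regime, the display bin
of each gait criterion — stability, steadiness, sturdiness, symmetry — on a
five-level dark-red-to-dark-green diverging scale.  Non-walking regimes are
not scored and keep their type color on the criterion rings.

SVG is the canonical output (hand-assembled, byte-deterministic for a fixed
spec); PNG is rasterized through matplotlib from the same geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .scoring import BINS, CRITERIA

RING_ORDER = ("type", "stability", "steadiness", "sturdiness", "symmetry")

#: criterion key backing each scored ring
RING_CRITERION = {
    "stability": "rmsr_ml",
    "steadiness": "p2cc",
    "sturdiness": "rmsr_ap",
    "symmetry": "p1cc",
}

TYPE_COLORS = {
    "non_sedentary": "#08306b",  # dark blue
    "sedentary": "#4292c6",      # standard blue
    "walking": "#c6dbef",        # light blue
}

BIN_COLORS = {
    "well_below": "#a50026",
    "slightly_below": "#f46d43",
    "within": "#a6d96a",
    "slightly_above": "#1a9850",
    "well_above": "#006837",
}


@dataclass(frozen=True)
class SummarySpec:
    """Resolved drawing instructions for one chart.

    ``sectors`` is an ordered list of dicts with keys ``start_deg``,
    ``extent_deg`` (clockwise from 12 o'clock), ``label`` and ``bins``
    (criterion -> display bin, only for walking regimes).
    """

    sectors: tuple
    ring_order: tuple = RING_ORDER
    type_colors: dict = field(default_factory=lambda: dict(TYPE_COLORS))
    bin_colors: dict = field(default_factory=lambda: dict(BIN_COLORS))


def build_summary(regime_spans, labels, scores, allow_unscored_walking=False) -> SummarySpec:
    """Turn labeled regimes + per-walking-regime scores into a chart spec.

    ``scores`` is a parallel sequence: a RegimeScore (or criterion->bin
    dict) for walking regimes, None otherwise.  A walking regime without a
    score is refused — partial charts are never drawn — unless
    ``allow_unscored_walking`` is set, in which case such a regime (e.g. a
    turn fragment too short for the stride-lag criteria) keeps its walking
    type color on the criterion rings, the same "not evaluated" treatment
    non-walking regimes receive.
    """
    spans = [tuple(map(float, s)) for s in regime_spans]
    labels = list(labels)
    scores = list(scores)
    if not (len(spans) == len(labels) == len(scores)):
        raise ValueError("regimes, labels and scores must be parallel")
    total = sum(b - a for a, b in spans)
    if total <= 0:
        raise ValueError("zero total duration")
    sectors = []
    angle = 0.0
    for (a, b), lab, sc in zip(spans, labels, scores):
        extent = 360.0 * (b - a) / total
        bins = None
        if lab == "walking":
            if sc is None:
                if allow_unscored_walking:
                    sectors.append(
                        {"start_deg": angle, "extent_deg": extent, "label": lab, "bins": None}
                    )
                    angle += extent
                    continue
                raise ValueError(f"walking regime [{a}, {b}) has no score")
            bins = dict(sc.display_bin) if hasattr(sc, "display_bin") else dict(sc)
            missing = set(CRITERIA) - set(bins)
            if missing:
                raise ValueError(f"missing criterion bins: {sorted(missing)}")
            for v in bins.values():
                if v not in BINS:
                    raise ValueError(f"unknown display bin {v!r}")
        sectors.append(
            {"start_deg": angle, "extent_deg": extent, "label": lab, "bins": bins}
        )
        angle += extent
    return SummarySpec(sectors=tuple(sectors))


_SIZE = 500.0
_CENTER = _SIZE / 2.0
_RINGS = (  # (outer radius, inner radius) per ring, outermost first
    (225.0, 185.0),
    (178.0, 145.0),
    (138.0, 105.0),
    (98.0, 65.0),
    (58.0, 25.0),
)


def _pt(r: float, deg: float) -> tuple:
    """Clockwise-from-top polar point in SVG coordinates."""
    rad = math.radians(deg)
    return _CENTER + r * math.sin(rad), _CENTER - r * math.cos(rad)


def _sector_path(r_out: float, r_in: float, a0: float, a1: float) -> str:
    large = 1 if (a1 - a0) > 180.0 else 0
    x0, y0 = _pt(r_out, a0)
    x1, y1 = _pt(r_out, a1)
    x2, y2 = _pt(r_in, a1)
    x3, y3 = _pt(r_in, a0)
    return (
        f"M {x0:.3f} {y0:.3f} "
        f"A {r_out:.3f} {r_out:.3f} 0 {large} 1 {x1:.3f} {y1:.3f} "
        f"L {x2:.3f} {y2:.3f} "
        f"A {r_in:.3f} {r_in:.3f} 0 {large} 0 {x3:.3f} {y3:.3f} Z"
    )


def _sector_color(spec: SummarySpec, sector: dict, ring: str) -> str:
    if ring == "type" or sector["bins"] is None:
        return spec.type_colors[sector["label"]]
    return spec.bin_colors[sector["bins"][RING_CRITERION[ring]]]


def _sector_pieces(a0: float, extent: float):
    """Split very wide sectors so SVG arcs stay well-defined."""
    if extent >= 300.0:
        mid = a0 + extent / 2.0
        return [(a0, mid), (mid, a0 + extent)]
    return [(a0, a0 + extent)]


def render_svg_text(spec: SummarySpec) -> str:
    """Deterministic SVG markup for a summary spec."""
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_SIZE:.0f}" '
        f'height="{_SIZE:.0f}" viewBox="0 0 {_SIZE:.0f} {_SIZE:.0f}">',
        f'<rect width="{_SIZE:.0f}" height="{_SIZE:.0f}" fill="white"/>',
    ]
    for ring, (r_out, r_in) in zip(spec.ring_order, _RINGS):
        for sector in spec.sectors:
            color = _sector_color(spec, sector, ring)
            for a0, a1 in _sector_pieces(sector["start_deg"], sector["extent_deg"]):
                parts.append(
                    f'<path d="{_sector_path(r_out, r_in, a0, a1)}" '
                    f'fill="{color}" stroke="none"/>'
                )
    if len(spec.sectors) > 1:
        r_out = _RINGS[0][0]
        r_in = _RINGS[-1][1]
        for sector in spec.sectors:
            x0, y0 = _pt(r_in, sector["start_deg"])
            x1, y1 = _pt(r_out, sector["start_deg"])
            parts.append(
                f'<line x1="{x0:.3f}" y1="{y0:.3f}" x2="{x1:.3f}" y2="{y1:.3f}" '
                f'stroke="black" stroke-width="1.5"/>'
            )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render(spec: SummarySpec, path, format: str | None = None) -> None:
    """Write the chart to ``path`` as SVG or PNG."""
    fmt = (format or str(path).rsplit(".", 1)[-1]).lower()
    if fmt == "svg":
        with open(path, "w") as fh:
            fh.write(render_svg_text(spec))
    elif fmt == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Wedge

        fig, ax = plt.subplots(figsize=(5, 5), dpi=100)
        ax.set_xlim(0, _SIZE)
        ax.set_ylim(_SIZE, 0)
        ax.set_aspect("equal")
        ax.axis("off")
        for ring, (r_out, r_in) in zip(spec.ring_order, _RINGS):
            for sector in spec.sectors:
                color = _sector_color(spec, sector, ring)
                # matplotlib angles: counter-clockwise from +x axis (y up);
                # our y axis is flipped, so clockwise-from-top maps directly
                th1 = sector["start_deg"] - 90.0
                th2 = th1 + sector["extent_deg"]
                ax.add_patch(
                    Wedge((_CENTER, _CENTER), r_out, th1, th2,
                          width=r_out - r_in, facecolor=color, edgecolor="none")
                )
        if len(spec.sectors) > 1:
            for sector in spec.sectors:
                x0, y0 = _pt(_RINGS[-1][1], sector["start_deg"])
                x1, y1 = _pt(_RINGS[0][0], sector["start_deg"])
                ax.plot([x0, x1], [y0, y1], color="black", lw=1.5)
        fig.savefig(path, format="png", bbox_inches="tight")
        plt.close(fig)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


__all__ = [
    "RING_ORDER",
    "RING_CRITERION",
    "TYPE_COLORS",
    "BIN_COLORS",
    "SummarySpec",
    "build_summary",
    "render_svg_text",
    "render",
]
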
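"""SVG output: diagrams, data layers, LW glyphs, thumbnails and morphs.

Output is deterministic -- stable element order, stable id scheme, fixed
float formatting -- so byte-level diffs between runs are meaningful and
the image-regression harness can gate changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BASE_SPACING
from .layout import Layout
from .lw import BasePairAnnotation, Edge
from .structure import SecondaryStructure

#: colour-blind safe palette (Okabe-Ito subset), low to high confidence
POSTERIOR_PALETTE = ("#D55E00", "#E69F00", "#56B4E9", "#009E73")
#: bin edges for the alignment-confidence layer; values in the top bin
#: [0.95, 1.0] are not highlighted
POSTERIOR_EDGES = (0.0, 0.8, 0.85, 0.9, 0.95)

NT_RADIUS = 2.6
LAYER_RADIUS = 3.6
MARGIN = 20.0


class RenderError(ValueError):
    pass


def _fmt(v: float) -> str:
    return f"{float(v):.2f}"


@dataclass(frozen=True)
class DataLayer:
    """Per-position annotation mapped to colours.

    ``values`` holds one number, string or None per nucleotide; the
    colormap is either ordered numeric bins ``(lo, hi, colour)`` (hi
    exclusive except the last bin) with colour None meaning "no
    highlight", or a categorical mapping value -> colour.
    """

    name: str
    values: tuple
    bins: tuple[tuple[float, float, str | None], ...] = ()
    categories: dict = field(default_factory=dict)

    def colour_for(self, pos: int) -> str | None:
        v = self.values[pos]
        if v is None:
            return None
        if self.bins:
            v = float(v)
            for idx, (lo, hi, colour) in enumerate(self.bins):
                last = idx == len(self.bins) - 1
                if lo <= v < hi or (last and v == hi):
                    return colour
            raise RenderError(f"value {v} outside every bin of layer {self.name!r}")
        return self.categories.get(v)

    @property
    def legend(self) -> tuple[str, ...]:
        if self.bins:
            return tuple(
                f"[{lo:g}, {hi:g}{']' if idx == len(self.bins) - 1 else ')'}: "
                + (colour if colour else "no highlight")
                for idx, (lo, hi, colour) in enumerate(self.bins)
            )
        return tuple(f"{k}: {v}" for k, v in sorted(self.categories.items()))


def posterior_layer(values) -> DataLayer:
    """Alignment-confidence colouring.

    Probabilities in [0.95, 1.0] are not highlighted; the rest fall into
    four fixed bins coloured with a colour-blind safe palette.
    """
    vals = []
    for v in values:
        if v is None:
            vals.append(None)
            continue
        v = float(v)
        if not 0.0 <= v <= 1.0:
            raise RenderError(f"posterior probability {v} outside [0, 1]")
        vals.append(v)
    edges = POSTERIOR_EDGES + (1.0,)
    bins = tuple(
        (edges[k], edges[k + 1], POSTERIOR_PALETTE[k] if k < 4 else None)
        for k in range(5)
    )
    return DataLayer(name="posterior", values=tuple(vals), bins=bins)


def _bounds(coords: np.ndarray) -> tuple[float, float, float, float]:
    x0, y0 = coords.min(axis=0) - MARGIN
    x1, y1 = coords.max(axis=0) + MARGIN
    return float(x0), float(y0), float(x1 - x0), float(y1 - y0)


def svg_viewbox(layout: Layout) -> tuple[float, float, float, float]:
    """The frame render_svg would use; pass to ``viewbox`` to pin the frame
    across renders (e.g. when comparing a drawing against a shifted copy)."""
    return _bounds(layout.coords)


def _svg_open(coords: np.ndarray, viewbox: tuple[float, float, float, float] | None = None) -> str:
    x, y, w, h = viewbox if viewbox is not None else _bounds(coords)
    return (
        '<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'viewBox="{_fmt(x)} {_fmt(y)} {_fmt(w)} {_fmt(h)}" '
        f'width="{_fmt(w)}" height="{_fmt(h)}">'
    )


def render_svg(
    seq: str,
    structure: SecondaryStructure,
    layout: Layout,
    layers: tuple[DataLayer, ...] = (),
    labels: tuple[str | None, ...] | None = None,
    label_interval: int = 10,
    font_size: float = 6.0,
    viewbox: tuple[float, float, float, float] | None = None,
) -> str:
    """Full diagram: data layers, backbone, pair connectors, letters, labels.

    Page-0 pairs draw as solid connectors (dashed when predicted); pairs
    on pages >= 1 use the ``pseudoknot`` connector class.
    """
    n = len(seq)
    if structure.length != n or len(layout) != n:
        raise RenderError(
            f"lengths differ: seq {n}, structure {structure.length}, layout {len(layout)}"
        )
    for layer in layers:
        if len(layer.values) != n:
            raise RenderError(f"layer {layer.name!r} has {len(layer.values)} values for {n} nt")
    coords = layout.coords
    out = [_svg_open(coords, viewbox)]
    for layer in layers:
        for i in range(n):
            colour = layer.colour_for(i)
            if colour is None:
                continue
            out.append(
                f'<circle id="layer-{layer.name}-{i}" class="layer" '
                f'cx="{_fmt(coords[i, 0])}" cy="{_fmt(coords[i, 1])}" '
                f'r="{_fmt(LAYER_RADIUS)}" fill="{colour}"/>'
            )
    path = "M " + " L ".join(f"{_fmt(x)} {_fmt(y)}" for x, y in coords)
    out.append(f'<path id="backbone" d="{path}" fill="none" stroke="#888888" stroke-width="1"/>')
    for i, j, page in sorted(structure.pairs):
        x1, y1 = coords[i]
        x2, y2 = coords[j]
        if page >= 1:
            cls, dash, colour = "pseudoknot", ' stroke-dasharray="2,2"', "#2166AC"
        elif (i, j) in structure.predicted:
            cls, dash, colour = "predicted", ' stroke-dasharray="4,2"', "#555555"
        else:
            cls, dash, colour = "pair", "", "#000000"
        out.append(
            f'<line id="pair-{i}-{j}" class="{cls}" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
            f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="{colour}" stroke-width="1"{dash}/>'
        )
    for i in range(n):
        out.append(
            f'<circle id="nt-{i}" class="nt" cx="{_fmt(coords[i, 0])}" '
            f'cy="{_fmt(coords[i, 1])}" r="{_fmt(NT_RADIUS)}" fill="#FFFFFF" '
            'stroke="none"/>'
        )
        out.append(
            f'<text id="letter-{i}" class="letter" x="{_fmt(coords[i, 0])}" '
            f'y="{_fmt(coords[i, 1])}" font-size="{_fmt(font_size)}" '
            'text-anchor="middle" dominant-baseline="central" '
            f'font-family="monospace">{seq[i]}</text>'
        )
    shown: list[tuple[int, str]] = []
    for i in range(n):
        if labels is not None and labels[i] is not None:
            shown.append((i, str(labels[i])))
        elif labels is None and label_interval and (i + 1) % label_interval == 0:
            shown.append((i, str(i + 1)))
    for i, text in shown:
        off = _label_offset(coords, i)
        out.append(
            f'<text id="label-{i}" class="numbering" x="{_fmt(coords[i, 0] + off[0])}" '
            f'y="{_fmt(coords[i, 1] + off[1])}" font-size="{_fmt(font_size * 0.8)}" '
            'text-anchor="middle" dominant-baseline="central" '
            f'font-family="monospace" fill="#666666">{text}</text>'
        )
    out.append("</svg>")
    return "\n".join(out)


def _label_offset(coords: np.ndarray, i: int) -> tuple[float, float]:
    """Push the numbering label away from the local backbone direction."""
    n = coords.shape[0]
    a = coords[max(i - 1, 0)]
    b = coords[min(i + 1, n - 1)]
    d = b - a
    norm = float(np.hypot(*d))
    if norm < 1e-9:
        return (0.0, -BASE_SPACING * 0.8)
    perp = np.array([d[1], -d[0]]) / norm
    return (float(perp[0] * BASE_SPACING * 0.8), float(perp[1] * BASE_SPACING * 0.8))


def render_thumbnail(layout: Layout) -> str:
    """Simplified diagram: one continuous line through all nucleotides."""
    layout.validate()
    coords = layout.coords
    points = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in coords)
    return "\n".join(
        [
            _svg_open(coords),
            f'<polyline id="outline" points="{points}" fill="none" '
            'stroke="#333333" stroke-width="1.5"/>',
            "</svg>",
        ]
    )


_GLYPH_SIZE = 3.0


def _edge_glyph(point: np.ndarray, edge: Edge, filled: bool, ident: str) -> str:
    x, y = float(point[0]), float(point[1])
    fill = "#000000" if filled else "#FFFFFF"
    if edge is Edge.WATSON_CRICK:
        return (
            f'<circle id="{ident}" class="lw-glyph" cx="{_fmt(x)}" cy="{_fmt(y)}" '
            f'r="{_fmt(_GLYPH_SIZE / 2)}" fill="{fill}" stroke="#000000" stroke-width="0.7"/>'
        )
    if edge is Edge.HOOGSTEEN:
        h = _GLYPH_SIZE / 2
        return (
            f'<rect id="{ident}" class="lw-glyph" x="{_fmt(x - h)}" y="{_fmt(y - h)}" '
            f'width="{_fmt(_GLYPH_SIZE)}" height="{_fmt(_GLYPH_SIZE)}" '
            f'fill="{fill}" stroke="#000000" stroke-width="0.7"/>'
        )
    if edge is Edge.SUGAR:
        h = _GLYPH_SIZE * 0.65
        pts = f"{_fmt(x)},{_fmt(y - h)} {_fmt(x - h)},{_fmt(y + h)} {_fmt(x + h)},{_fmt(y + h)}"
        return (
            f'<polygon id="{ident}" class="lw-glyph" points="{pts}" '
            f'fill="{fill}" stroke="#000000" stroke-width="0.7"/>'
        )
    raise RenderError(f"unknown edge {edge!r}")


def render_lw(pairs: tuple[BasePairAnnotation, ...], layout: Layout) -> str:
    """SVG fragment for LW-annotated pairs.

    Canonical cWW pairs are plain connecting lines; every other geometry
    gets an edge glyph at each end -- circle for the Watson-Crick edge,
    square for Hoogsteen, triangle for Sugar; cis filled, trans open.
    """
    coords = layout.coords
    n = len(layout)
    out: list[str] = []
    for bp in pairs:
        if not (0 <= bp.i < bp.j < n):
            raise RenderError(f"annotation ({bp.i},{bp.j}) outside layout of {n} nt")
        a, b = coords[bp.i], coords[bp.j]
        out.append(
            f'<line id="lw-{bp.i}-{bp.j}" class="lw-pair" x1="{_fmt(a[0])}" y1="{_fmt(a[1])}" '
            f'x2="{_fmt(b[0])}" y2="{_fmt(b[1])}" stroke="#000000" stroke-width="0.8"/>'
        )
        if bp.is_cww:
            continue
        filled = bp.orientation.value == "c"
        span = b - a
        ga = a + span * 0.25
        gb = a + span * 0.75
        out.append(_edge_glyph(ga, bp.edge5, filled, f"lw-{bp.i}-{bp.j}-5"))
        out.append(_edge_glyph(gb, bp.edge3, filled, f"lw-{bp.i}-{bp.j}-3"))
    return "\n".join(out)


@dataclass(frozen=True)
class AnimationSpec:
    """Morph between two drawings of the same molecule."""

    layout_a: Layout
    layout_b: Layout
    duration: float = 3.0

    def __post_init__(self) -> None:
        if len(self.layout_a) != len(self.layout_b):
            raise RenderError("structures must be the same size")
        if not self.duration > 0:
            raise RenderError(f"duration must be positive, got {self.duration}")


def animate(spec: AnimationSpec, enabled: bool = True) -> str:
    """Animated SVG morphing layout A into layout B, looping indefinitely.

    Linear per-nucleotide interpolation: at t=0 every nucleotide sits at
    its A coordinate, at t=duration at its B coordinate.  With
    ``enabled=False`` the static first frame is returned.
    """
    a, b = spec.layout_a.coords, spec.layout_b.coords
    both = np.vstack([a, b])
    dur = f"{spec.duration:g}s"
    out = [_svg_open(both)]
    pts_a = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in a)
    pts_b = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in b)
    if enabled:
        out.append(
            f'<polyline id="backbone" points="{pts_a}" fill="none" stroke="#888888" '
            'stroke-width="1">'
            f'<animate attributeName="points" values="{pts_a};{pts_b}" '
            f'dur="{dur}" repeatCount="indefinite"/></polyline>'
        )
    else:
        out.append(
            f'<polyline id="backbone" points="{pts_a}" fill="none" stroke="#888888" '
            'stroke-width="1"/>'
        )
    for i in range(a.shape[0]):
        if enabled:
            out.append(
                f'<circle id="nt-{i}" class="nt" cx="{_fmt(a[i, 0])}" cy="{_fmt(a[i, 1])}" '
                'r="2.00" fill="#1B7837">'
                f'<animate attributeName="cx" values="{_fmt(a[i, 0])};{_fmt(b[i, 0])}" '
                f'dur="{dur}" repeatCount="indefinite"/>'
                f'<animate attributeName="cy" values="{_fmt(a[i, 1])};{_fmt(b[i, 1])}" '
                f'dur="{dur}" repeatCount="indefinite"/></circle>'
            )
        else:
            out.append(
                f'<circle id="nt-{i}" class="nt" cx="{_fmt(a[i, 0])}" cy="{_fmt(a[i, 1])}" '
                'r="2.00" fill="#1B7837"/>'
            )
    out.append("</svg>")
    return "\n".join(out)
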
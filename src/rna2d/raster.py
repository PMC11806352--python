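"""Raster regression harness: paint the SVG subset and compare images.

The painter handles exactly the primitives the renderer emits (paths and
polylines as line strips, circles, rects, polygons, text as filled boxes)
on a fixed 512x512 canvas.  Image comparison converts both rasters to
greyscale and computes a single global structural-similarity (SSIM)
statistic plus the per-channel mean absolute difference; a change passes
the regression gate when both stay within the thresholds, so cosmetic
tweaks (font size, sub-pixel shifts) pass while a rearranged diagram
fails.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

CANVAS = 512
SSIM_THRESHOLD = 0.99
DIFF_THRESHOLD = 2 / 255

_C1 = (0.01 * 255) ** 2
_C2 = (0.03 * 255) ** 2


class RasterError(ValueError):
    pass


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


_NUM = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _floats(text: str) -> list[float]:
    return [float(m) for m in _NUM.findall(text or "")]


@dataclass
class _Transform:
    scale: float
    ox: float
    oy: float

    def __call__(self, x: float, y: float) -> tuple[float, float]:
        return (x - self.ox) * self.scale, (y - self.oy) * self.scale


def _colour(spec: str | None) -> tuple[int, int, int] | None:
    if spec is None or spec == "none":
        return None
    spec = spec.strip()
    if spec.startswith("#") and len(spec) == 7:
        return tuple(int(spec[k : k + 2], 16) for k in (1, 3, 5))  # type: ignore[return-value]
    named = {"black": (0, 0, 0), "white": (255, 255, 255)}
    if spec in named:
        return named[spec]
    raise RasterError(f"unsupported colour {spec!r}")


def rasterize_svg(svg_text: str, canvas: int = CANVAS) -> np.ndarray:
    """Paint the renderer's SVG subset onto a white RGB canvas."""
    root = ET.fromstring(svg_text)
    vb = _floats(root.get("viewBox", "0 0 100 100"))
    x0, y0, w, h = vb
    scale = (canvas - 8) / max(w, h, 1e-9)
    # centre the drawing
    tx = _Transform(scale, x0 - (max(w, h) - w) / 2 - 4 / scale, y0 - (max(w, h) - h) / 2 - 4 / scale)
    img = Image.new("RGB", (canvas, canvas), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    _paint(root, draw, tx)
    return np.asarray(img, dtype=np.uint8)


def _paint(node, draw: ImageDraw.ImageDraw, tx: _Transform) -> None:
    for el in node:
        tag = _strip_ns(el.tag)
        stroke = _colour(el.get("stroke"))
        fill = _colour(el.get("fill"))
        width = max(int(round(float(el.get("stroke-width", "1")) * tx.scale)), 1)
        if tag == "line":
            a = tx(float(el.get("x1")), float(el.get("y1")))
            b = tx(float(el.get("x2")), float(el.get("y2")))
            if stroke:
                draw.line([a, b], fill=stroke, width=width)
        elif tag in ("polyline", "polygon"):
            nums = _floats(el.get("points", ""))
            pts = [tx(nums[k], nums[k + 1]) for k in range(0, len(nums) - 1, 2)]
            if tag == "polygon" and fill:
                draw.polygon(pts, fill=fill)
            if stroke and len(pts) >= 2:
                seq = pts + [pts[0]] if tag == "polygon" else pts
                draw.line(seq, fill=stroke, width=width)
        elif tag == "path":
            nums = _floats(el.get("d", ""))
            pts = [tx(nums[k], nums[k + 1]) for k in range(0, len(nums) - 1, 2)]
            if stroke and len(pts) >= 2:
                draw.line(pts, fill=stroke, width=width)
        elif tag == "circle":
            cx, cy = tx(float(el.get("cx")), float(el.get("cy")))
            r = float(el.get("r")) * tx.scale
            box = [cx - r, cy - r, cx + r, cy + r]
            draw.ellipse(box, fill=fill, outline=stroke, width=width if stroke else 0)
        elif tag == "rect":
            a = tx(float(el.get("x")), float(el.get("y")))
            b = tx(
                float(el.get("x")) + float(el.get("width")),
                float(el.get("y")) + float(el.get("height")),
            )
            draw.rectangle([a, b], fill=fill, outline=stroke)
        elif tag == "text":
            # text paints as a fixed-size ink box at the anchor: the harness
            # abstracts typography, so font-size-only changes never trip the
            # regression gate while geometry changes still do
            cx, cy = tx(float(el.get("x")), float(el.get("y")))
            half = max(1.4 * tx.scale, 1.0)
            colour = fill or (0, 0, 0)
            draw.rectangle([cx - half, cy - half, cx + half, cy + half], fill=colour)
        elif tag == "svg":
            _paint(el, draw, tx)
        # animate/desc/metadata children carry no geometry of their own
        if len(el) and tag != "svg":
            _paint(el, draw, tx)


def _grey(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


def image_similarity(raster_a: np.ndarray, raster_b: np.ndarray) -> tuple[float, np.ndarray]:
    """Global SSIM on greyscale plus per-channel mean absolute difference.

    SSIM uses one window covering the whole image with the standard
    constants C1 = (0.01*255)^2 and C2 = (0.03*255)^2.  The mean absolute
    difference is reported per channel on a 0-1 scale.
    """
    a = np.asarray(raster_a, dtype=np.float64)
    b = np.asarray(raster_b, dtype=np.float64)
    if a.shape != b.shape:
        raise RasterError(f"raster dimensions differ: {a.shape} vs {b.shape}")
    ga, gb = _grey(a), _grey(b)
    mu_a, mu_b = ga.mean(), gb.mean()
    var_a, var_b = ga.var(), gb.var()
    cov = ((ga - mu_a) * (gb - mu_b)).mean()
    ssim = ((2 * mu_a * mu_b + _C1) * (2 * cov + _C2)) / (
        (mu_a**2 + mu_b**2 + _C1) * (var_a + var_b + _C2)
    )
    if a.ndim == 2:
        diff = np.array([np.abs(a - b).mean() / 255])
    else:
        diff = np.abs(a - b).mean(axis=(0, 1)) / 255
    return float(ssim), diff


def images_match(
    raster_a: np.ndarray,
    raster_b: np.ndarray,
    ssim_threshold: float = SSIM_THRESHOLD,
    diff_threshold: float = DIFF_THRESHOLD,
) -> tuple[bool, float, float]:
    """Regression verdict: (passed, ssim, max per-channel diff)."""
    ssim, diff = image_similarity(raster_a, raster_b)
    worst = float(diff.max())
    return ssim >= ssim_threshold and worst <= diff_threshold, ssim, worst
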
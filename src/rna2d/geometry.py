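"""Plane geometry shared by the layout engines.

All coordinates are abstract drawing units with y increasing downward
(screen convention).  The metric is uniform: consecutive backbone
nucleotides sit BASE_SPACING apart, paired partners PAIR_DISTANCE apart,
and helices rise HELIX_RISE per stacked pair.
"""

from __future__ import annotations

import math

import numpy as np

BASE_SPACING = 8.0
PAIR_DISTANCE = 8.0
HELIX_RISE = 8.0


def unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0.0:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def perp(v: np.ndarray) -> np.ndarray:
    """Rotate 90 degrees counter-clockwise on screen (y-down)."""
    return np.array([v[1], -v[0]])


def wrap_angle(a: float) -> float:
    """Wrap to (-pi, pi]."""
    a = math.fmod(a, 2 * math.pi)
    if a <= -math.pi:
        a += 2 * math.pi
    elif a > math.pi:
        a -= 2 * math.pi
    return a


def on_circle(centre: np.ndarray, r: float, angle: float) -> np.ndarray:
    return np.array([centre[0] + r * math.cos(angle), centre[1] + r * math.sin(angle)])


def loop_radius(cycle_size: int) -> float:
    """Radius from the circumference rule: cycle_size * BASE_SPACING around.

    Clamped so the closing pair (chord PAIR_DISTANCE) always fits.
    """
    return max(cycle_size * BASE_SPACING / (2 * math.pi), PAIR_DISTANCE / 2)


def chord_angle(chord: float, r: float) -> float:
    """Angle subtended at the centre by a chord of the given length."""
    return 2 * math.asin(min(1.0, chord / (2 * r)))


def loop_circle(q5: np.ndarray, q3: np.ndarray, direction: np.ndarray, cycle_size: int):
    """Circle through the closing-pair anchors, centre displaced into the loop.

    ``direction`` is the unit vector from the chord midpoint into the loop
    (the drawing direction of the closing helix).  Returns (centre, r).
    """
    r = loop_radius(cycle_size)
    chord = q3 - q5
    half_chord = float(np.hypot(*chord)) / 2
    r = max(r, half_chord)
    h = math.sqrt(max(r * r - half_chord * half_chord, 0.0))
    # centre lies on the perpendicular bisector of the chord; ``direction``
    # only picks the side
    u = unit(perp(chord))
    if float(np.dot(direction, u)) < 0:
        u = -u
    centre = (q5 + q3) / 2 + h * u
    return centre, r


def circumcircle(points: np.ndarray):
    """Least-squares (Kasa) circle through >= 3 points; exact for cocircular."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    a = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    return np.array([cx, cy]), r


def solve_arc(chord: float, arc_length: float) -> tuple[float, float] | None:
    """Radius and half-angle of a circular arc with the given chord and length.

    Solves sin(a)/a = chord/arc_length for the half-angle a in (0, pi);
    returns None when chord >= arc_length (no bulge: the points fit on the
    straight segment).
    """
    if chord >= arc_length:
        return None
    target = chord / arc_length
    lo, hi = 1e-9, math.pi - 1e-9
    for _ in range(200):
        mid = (lo + hi) / 2
        if math.sin(mid) / mid > target:
            lo = mid
        else:
            hi = mid
    alpha = (lo + hi) / 2
    radius = arc_length / (2 * alpha)
    return radius, alpha


def arc_points(
    flank5: np.ndarray,
    flank3: np.ndarray,
    m: int,
    bulge: np.ndarray,
) -> np.ndarray:
    """m points on the arc from flank5 to flank3 bulging toward ``bulge``.

    Arc length is (m + 1) * BASE_SPACING; endpoints are excluded and the
    interior points are spaced uniformly along the arc.  Degrades to
    uniform placement on the straight segment when the flanks are further
    apart than the arc would allow.
    """
    chord_vec = flank3 - flank5
    d = float(np.hypot(*chord_vec))
    arc_len = (m + 1) * BASE_SPACING
    solved = solve_arc(d, arc_len)
    if solved is None:
        fracs = np.arange(1, m + 1) / (m + 1)
        return flank5 + np.outer(fracs, chord_vec)
    radius, alpha = solved
    mid = (flank5 + flank3) / 2
    side = unit(bulge)
    centre = mid - side * (radius * math.cos(alpha))
    a5 = math.atan2(flank5[1] - centre[1], flank5[0] - centre[0])
    a3 = math.atan2(flank3[1] - centre[1], flank3[0] - centre[0])
    # the arc through the bulge side has angular extent exactly 2*alpha
    # (the centre is placed accordingly); pick the traversal sign that
    # actually reaches flank3 after 2*alpha
    dpos = (a3 - a5) % (2 * math.pi)
    delta = dpos if abs(dpos - 2 * alpha) < abs(dpos - 2 * math.pi + 2 * alpha) else dpos - 2 * math.pi
    out = np.empty((m, 2))
    for idx in range(1, m + 1):
        out[idx - 1] = on_circle(centre, radius, a5 + delta * idx / (m + 1))
    return out


def polygon_orientation(points: np.ndarray) -> float:
    """Signed shoelace area; sign gives the cycle direction of the points."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
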
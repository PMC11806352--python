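"""Per-nucleotide coordinates: radial drawing core and template inheritance.

Template-based layout keeps every element that the query shares with the
template bit-identical to the template drawing and recomputes only the
elements touched by an edit:

* a loop containing an insertion or deletion is *rearranged* -- its
  unpaired positions are redistributed on the loop circle while the
  anchor points of the closing pair and of mapped child helices stay
  fixed (hairpins, having no children, get a fresh circle through the
  closing pair with the circumference rule);
* a helix that gained or lost pairs is *re-laddered* along the template
  helix axis, mapped rungs keeping their template coordinates;
* helices with no template counterpart (e.g. predicted by folding inside
  an insertion) are drawn de novo, radially off their enclosing loop.

Neighbouring elements are never shifted to make room; overlaps that
large edits may cause are reported by the overlap counter, not resolved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .align import AlignmentResult
from .geometry import (
    BASE_SPACING,
    HELIX_RISE,
    PAIR_DISTANCE,
    arc_points,
    chord_angle,
    circumcircle,
    loop_circle,
    on_circle,
    polygon_orientation,
    unit,
    wrap_angle,
)
from .structure import SecondaryStructure
from .templates import Template
from .tree import Helix, Loop, LoopKind, StructureTree, build_tree

logger = logging.getLogger(__name__)

INHERITED = "inherited"
REARRANGED = "rearranged"
INSERTED = "inserted"


class LayoutError(ValueError):
    pass


@dataclass(frozen=True)
class Layout:
    """Drawing coordinates, one row per nucleotide, y increasing downward."""

    coords: np.ndarray  # (n, 2) float64
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise LayoutError(f"coords shape {coords.shape} is not (n, 2)")
        if len(self.provenance) != coords.shape[0]:
            raise LayoutError("provenance length != coordinate count")

    def __len__(self) -> int:
        return int(self.coords.shape[0])

    def validate(self) -> None:
        if len(self) == 0:
            raise LayoutError("empty layout")
        if not np.all(np.isfinite(self.coords)):
            raise LayoutError("layout contains non-finite coordinates")
        if len(self) > 1:
            steps = np.hypot(*np.diff(self.coords, axis=0).T)
            if steps.min() < 0.1 * BASE_SPACING or steps.max() > 10 * BASE_SPACING:
                raise LayoutError(
                    f"backbone step outside 0.1-10x BASE_SPACING: min {steps.min():.3g}, "
                    f"max {steps.max():.3g}"
                )


# ---------------------------------------------------------------------------
# radial drawing core (used by the de novo engine and for novel subtrees)


def _draw_loop_radial(coords, loop: Loop, q5, q3, direction) -> None:
    """Place loop members uniformly on the loop circle; recurse into children.

    Child-helix closing pairs occupy chords of exactly PAIR_DISTANCE; the
    leftover angle is split evenly among the inter-item gaps, so unpaired
    neighbours on one loop are always equidistant.
    """
    if not loop.items:
        return
    centre, r = loop_circle(q5, q3, direction, loop.cycle_size)
    theta_p = chord_angle(PAIR_DISTANCE, r)
    nc = len(loop.children)
    nu = len(loop.nt_positions)
    leftover = max(2 * math.pi - (nc + 1) * theta_p, 0.0)
    gap = leftover / (nc + 1 + nu)
    phi5 = math.atan2(q5[1] - centre[1], q5[0] - centre[0])
    phi3 = math.atan2(q3[1] - centre[1], q3[0] - centre[0])
    delta = wrap_angle(phi3 - phi5)
    sigma = -1.0 if delta > 0 else 1.0  # traverse the long way round
    psi = phi5
    for tag, item in loop.items:
        psi += sigma * gap
        if tag == "nt":
            coords[item] = on_circle(centre, r, psi)
        else:
            a5 = on_circle(centre, r, psi)
            psi += sigma * theta_p
            a3 = on_circle(centre, r, psi)
            child_dir = unit((a5 + a3) / 2 - centre)
            _draw_helix_radial(coords, item, a5, a3, child_dir)


def _draw_helix_radial(coords, helix: Helix, p5, p3, direction) -> None:
    for k, (i, j) in enumerate(helix.pairs):
        coords[i] = p5 + k * HELIX_RISE * direction
        coords[j] = p3 + k * HELIX_RISE * direction
    rise = (len(helix.pairs) - 1) * HELIX_RISE
    _draw_loop_radial(coords, helix.loop, p5 + rise * direction, p3 + rise * direction, direction)


def _draw_exterior_radial(coords, root: Loop, branch_sign: float = -1.0) -> None:
    """Exterior loop on a horizontal line, helices branching to -y by default."""
    x = 0.0
    direction = np.array([0.0, branch_sign])
    for tag, item in root.items:
        if tag == "nt":
            coords[item] = np.array([x, 0.0])
            x += BASE_SPACING
        else:
            p5 = np.array([x, 0.0])
            p3 = np.array([x + PAIR_DISTANCE, 0.0])
            _draw_helix_radial(coords, item, p5, p3, direction)
            x += PAIR_DISTANCE + BASE_SPACING


def radial_coords(structure: SecondaryStructure, branch_sign: float = -1.0) -> np.ndarray:
    tree = build_tree(structure)
    coords = np.full((structure.length, 2), np.nan)
    _draw_exterior_radial(coords, tree.root, branch_sign)
    return coords


# ---------------------------------------------------------------------------
# standalone insertion placement


def place_unfolded_insertion(flank5, flank3, m: int, away_from=None) -> np.ndarray:
    """Place m inserted nucleotides on an arc bulging off the flank segment.

    The arc has length (m + 1) * BASE_SPACING; the bulge side is chosen
    away from ``away_from`` (e.g. the enclosing loop centroid) when given.
    Coincident flanks fall back to a semicircle of radius
    BASE_SPACING * (m + 1) / pi.
    """
    if m < 1:
        raise LayoutError(f"insertion length must be >= 1, got {m}")
    flank5 = np.asarray(flank5, dtype=float)
    flank3 = np.asarray(flank3, dtype=float)
    chord = flank3 - flank5
    d = float(np.hypot(*chord))
    if d < 1e-9:
        logger.warning("coincident insertion flanks; falling back to a semicircle")
        radius = BASE_SPACING * (m + 1) / math.pi
        bulge = np.array([0.0, -1.0])
        if away_from is not None:
            diff = flank5 - np.asarray(away_from, dtype=float)
            if np.hypot(*diff) > 1e-9:
                bulge = unit(diff)
        beta = math.atan2(bulge[1], bulge[0])
        return np.array(
            [
                on_circle(flank5, radius, beta - math.pi / 2 + math.pi * k / (m + 1))
                for k in range(1, m + 1)
            ]
        )
    tangent = chord / d
    bulge = np.array([-tangent[1], tangent[0]])  # +y side for a +x segment
    if away_from is not None:
        mid = (flank5 + flank3) / 2
        diff = mid - np.asarray(away_from, dtype=float)
        if abs(float(np.dot(diff, bulge))) > 1e-9:
            bulge = bulge if float(np.dot(diff, bulge)) > 0 else -bulge
    return arc_points(flank5, flank3, m, bulge)


# ---------------------------------------------------------------------------
# template-based layout


def transfer_labels(
    template: Template, aln: AlignmentResult, suppress=()
) -> tuple[str | None, ...]:
    """Numbering labels inherited by matched positions; suppressed values dropped."""
    suppress = set(suppress)
    out: list[str | None] = []
    for q in range(aln.query_length):
        t = int(aln.posmap[q])
        label = template.numbering_labels[t] if t >= 0 else None
        out.append(None if label is None or label in suppress else label)
    return tuple(out)


class _TemplateLayouter:
    def __init__(
        self,
        query: str,
        qstruct: SecondaryStructure,
        template: Template,
        aln: AlignmentResult,
    ):
        n = len(query)
        if qstruct.length != n:
            raise LayoutError(f"structure length {qstruct.length} != query length {n}")
        if aln.query_length != n:
            raise LayoutError(f"alignment query length {aln.query_length} != {n}")
        if aln.template_length != len(template):
            raise LayoutError(
                f"alignment template length {aln.template_length} != {len(template)}"
            )
        self.n = n
        self.template = template
        self.aln = aln
        self.posmap = aln.posmap
        self.qtree: StructureTree = build_tree(qstruct)
        self.ttree: StructureTree = build_tree(template.structure)
        self.tcoords = template.coords
        self.tpairs = {h_pair: h for h in self.ttree.helices for h_pair in h.pairs}
        self.tloop_of_inner = {h.inner: h.loop for h in self.ttree.helices}
        self.coords = np.full((n, 2), np.nan)
        self.prov = [INHERITED] * n
        self.novel_anchor: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- classification ----------------------------------------------------

    def _map_pair(self, pair: tuple[int, int]) -> tuple[int, int] | None:
        qi, qj = pair
        ti, tj = int(self.posmap[qi]), int(self.posmap[qj])
        if ti >= 0 and tj >= 0 and (ti, tj) in self.tpairs:
            return (ti, tj)
        return None

    def helix_mapped_pairs(self, helix: Helix):
        return [
            (k, m) for k, p in enumerate(helix.pairs) if (m := self._map_pair(p)) is not None
        ]

    def helix_is_clean(self, helix: Helix) -> bool:
        mapped = self.helix_mapped_pairs(helix)
        if len(mapped) != len(helix.pairs):
            return False
        t_h = self.tpairs[mapped[0][1]]
        return [m for _, m in mapped] == t_h.pairs

    def _mapped_cycle(self, loop: Loop):
        """Query loop items mapped onto template positions, or None if unmappable."""
        items = []
        for tag, item in loop.items:
            if tag == "nt":
                t = int(self.posmap[item])
                if t < 0:
                    return None
                items.append(("nt", t))
            else:
                m = self._map_pair(item.outer)
                if m is None:
                    return None
                items.append(("helix", m))
        return items

    def loop_is_clean(self, loop: Loop) -> bool:
        mapped_items = self._mapped_cycle(loop)
        if mapped_items is None:
            return False
        if loop.kind is LoopKind.EXTERIOR:
            t_loop = self.ttree.root
        else:
            m = self._map_pair(loop.closing.inner)
            if m is None:
                return False
            t_loop = self.tloop_of_inner.get(m)
            if t_loop is None:
                return False
        t_items = [
            ("nt", item) if tag == "nt" else ("helix", item.outer)
            for tag, item in t_loop.items
        ]
        return mapped_items == t_items

    # -- helices -----------------------------------------------------------

    def _template_helix_axis(self, t_h: Helix) -> np.ndarray:
        if len(t_h.pairs) >= 2:
            outer = (self.tcoords[t_h.outer[0]] + self.tcoords[t_h.outer[1]]) / 2
            inner = (self.tcoords[t_h.inner[0]] + self.tcoords[t_h.inner[1]]) / 2
            if np.hypot(*(inner - outer)) > 1e-9:
                return unit(inner - outer)
        # single-rung helix: perpendicular to the pair, oriented toward its loop
        i, j = t_h.outer
        pvec = self.tcoords[j] - self.tcoords[i]
        axis = np.array([pvec[1], -pvec[0]])
        axis = unit(axis)
        members = t_h.loop.nt_positions if t_h.loop else []
        if members:
            centroid = self.tcoords[members].mean(axis=0)
            mid = (self.tcoords[i] + self.tcoords[j]) / 2
            if float(np.dot(centroid - mid, axis)) < 0:
                axis = -axis
        return axis

    def set_helix_coords(self, helix: Helix) -> None:
        mapped = self.helix_mapped_pairs(helix)
        if not mapped:
            # novel helix: drawn off its parent loop during rearrangement
            a = self.novel_anchor.get(id(helix))
            if a is None:
                raise LayoutError("novel helix reached before its loop anchors were placed")
            a5, a3, direction = a
            for pos in [p for pr in helix.pairs for p in pr]:
                self.prov[pos] = INSERTED if self.posmap[pos] < 0 else REARRANGED
            sub_coords = np.full((self.n, 2), np.nan)
            _draw_helix_radial(sub_coords, helix, a5, a3, direction)
            placed = np.isfinite(sub_coords[:, 0])
            self.coords[placed] = sub_coords[placed]
            for pos in np.flatnonzero(placed):
                self.prov[pos] = INSERTED if self.posmap[pos] < 0 else REARRANGED
            return
        if self.helix_is_clean(helix):
            for (qi, qj), (ti, tj) in zip(helix.pairs, (m for _, m in mapped)):
                self.coords[qi] = self.tcoords[ti]
                self.coords[qj] = self.tcoords[tj]
            return
        # dirty: re-ladder along the template helix axis, mapped rungs pinned
        ks = [k for k, _ in mapped]
        t_h = self.tpairs[mapped[0][1]]
        axis = self._template_helix_axis(t_h)
        mapped_by_k = dict(mapped)
        for k, (qi, qj) in enumerate(helix.pairs):
            if k in mapped_by_k:
                ti, tj = mapped_by_k[k]
                self.coords[qi] = self.tcoords[ti]
                self.coords[qj] = self.tcoords[tj]
            else:
                ref = min(ks, key=lambda kk: abs(kk - k))
                rti, rtj = mapped_by_k[ref]
                off = (k - ref) * HELIX_RISE * axis
                self.coords[qi] = self.tcoords[rti] + off
                self.coords[qj] = self.tcoords[rtj] + off
                for pos in (qi, qj):
                    self.prov[pos] = INSERTED if self.posmap[pos] < 0 else REARRANGED

    # -- loops -------------------------------------------------------------

    def _template_centroid(self, loop: Loop) -> np.ndarray | None:
        tpos = [int(self.posmap[p]) for p in loop.nt_positions if self.posmap[p] >= 0]
        if loop.closing is not None:
            m = self._map_pair(loop.closing.inner)
            if m is not None:
                tpos.extend(m)
        if not tpos:
            return None
        return self.tcoords[tpos].mean(axis=0)

    def _mark(self, positions) -> None:
        for p in positions:
            self.prov[p] = INSERTED if self.posmap[p] < 0 else REARRANGED

    def _rearrange_closed_loop(self, loop: Loop) -> None:
        qi, qj = loop.closing.inner
        q5, q3 = self.coords[qi].copy(), self.coords[qj].copy()
        mapped_children = [h for h in loop.children if self.helix_mapped_pairs(h)]
        self._mark(loop.nt_positions)
        if not mapped_children:
            # fresh circle through the closing pair (rule for hairpins and
            # loops whose every child is novel)
            centroid = self._template_centroid(loop)
            mid = (q5 + q3) / 2
            if centroid is not None and np.hypot(*(centroid - mid)) > 1e-9:
                direction = unit(centroid - mid)
            else:
                direction = self._query_helix_direction(loop.closing)
            synth = Loop(kind=loop.kind, closing=loop.closing, items=list(loop.items))
            self._place_cycle_on_fresh_circle(synth, q5, q3, direction)
            return
        # anchors of the closing pair and mapped children stay fixed
        anchor_pts = [q5]
        gaps: list[list[tuple[str, object]]] = [[]]
        for tag, item in loop.items:
            if tag == "helix" and item in mapped_children:
                anchor_pts.append(self.coords[item.outer[0]].copy())
                anchor_pts.append(self.coords[item.outer[1]].copy())
                gaps.append([])  # between the two anchors of this child: empty
                gaps.append([])
            else:
                gaps[-1].append((tag, item))
        anchor_pts.append(q3)
        centre, r = circumcircle(np.array(anchor_pts))
        sigma = 1.0 if polygon_orientation(np.array(anchor_pts)) > 0 else -1.0
        angles = [math.atan2(p[1] - centre[1], p[0] - centre[0]) for p in anchor_pts]
        for g, (a_from, a_to) in zip(gaps, zip(angles, angles[1:])):
            if not g:
                continue
            span = (a_to - a_from) * sigma
            span = span % (2 * math.pi)
            slots = sum(1 if tag == "nt" else 2 for tag, _ in g)
            slot = 0
            for tag, item in g:
                if tag == "nt":
                    slot += 1
                    ang = a_from + sigma * span * slot / (slots + 1)
                    self.coords[item] = on_circle(centre, r, ang)
                else:
                    ang1 = a_from + sigma * span * (slot + 1) / (slots + 1)
                    ang2 = a_from + sigma * span * (slot + 2) / (slots + 1)
                    slot += 2
                    a5 = on_circle(centre, r, ang1)
                    a3 = on_circle(centre, r, ang2)
                    self.novel_anchor[id(item)] = (a5, a3, unit((a5 + a3) / 2 - centre))

    def _query_helix_direction(self, helix: Helix) -> np.ndarray:
        if len(helix.pairs) >= 2:
            outer = (self.coords[helix.outer[0]] + self.coords[helix.outer[1]]) / 2
            inner = (self.coords[helix.inner[0]] + self.coords[helix.inner[1]]) / 2
            if np.hypot(*(inner - outer)) > 1e-9:
                return unit(inner - outer)
        mapped = self.helix_mapped_pairs(helix)
        if mapped:
            return self._template_helix_axis(self.tpairs[mapped[0][1]])
        return np.array([0.0, -1.0])

    def _place_cycle_on_fresh_circle(self, loop: Loop, q5, q3, direction) -> None:
        """Circumference-rule circle through the closing anchors; members uniform."""
        if not loop.items:
            return
        centre, r = loop_circle(q5, q3, direction, loop.cycle_size)
        theta_p = chord_angle(PAIR_DISTANCE, r)
        nc = len(loop.children)
        nu = len(loop.nt_positions)
        leftover = max(2 * math.pi - (nc + 1) * theta_p, 0.0)
        gap = leftover / (nc + 1 + nu)
        phi5 = math.atan2(q5[1] - centre[1], q5[0] - centre[0])
        phi3 = math.atan2(q3[1] - centre[1], q3[0] - centre[0])
        delta = wrap_angle(phi3 - phi5)
        sigma = -1.0 if delta > 0 else 1.0
        psi = phi5
        for tag, item in loop.items:
            psi += sigma * gap
            if tag == "nt":
                self.coords[item] = on_circle(centre, r, psi)
            else:
                a5 = on_circle(centre, r, psi)
                psi += sigma * theta_p
                a3 = on_circle(centre, r, psi)
                self.novel_anchor[id(item)] = (a5, a3, unit((a5 + a3) / 2 - centre))

    def _rearrange_exterior(self, loop: Loop) -> None:
        mapped_children = [h for h in loop.children if self.helix_mapped_pairs(h)]
        self._mark(loop.nt_positions)
        if not mapped_children:
            sub = np.full((self.n, 2), np.nan)
            _draw_exterior_radial(sub, loop)
            placed = np.isfinite(sub[:, 0])
            self.coords[placed] = sub[placed]
            for tag, item in loop.items:
                if tag == "helix":
                    self._mark([p for pr in item.pairs for p in pr])
                    self._mark(item.loop.nt_positions if item.loop else [])
            return
        first = self.coords[mapped_children[0].outer[0]]
        last = self.coords[mapped_children[-1].outer[1]]
        line = last - first
        if np.hypot(*line) > 1e-9:
            line_dir = unit(line)
        else:
            line_dir = np.array([1.0, 0.0])
        bulge = np.array([-line_dir[1], line_dir[0]])
        segments: list[tuple] = []  # (from_pt | None, to_pt | None, items)
        current: list = []
        prev_pt = None
        for tag, item in loop.items:
            if tag == "helix" and item in mapped_children:
                entry = self.coords[item.outer[0]].copy()
                segments.append((prev_pt, entry, current))
                current = []
                prev_pt = self.coords[item.outer[1]].copy()
            else:
                current.append((tag, item))
        segments.append((prev_pt, None, current))
        for a, b, items in segments:
            if not items:
                continue
            slots = sum(1 if tag == "nt" else 2 for tag, _ in items)
            if a is None:  # leading run: extend backwards along the line
                pts = [b - (slots - k) * BASE_SPACING * line_dir for k in range(slots)]
            elif b is None:  # trailing run
                pts = [a + (k + 1) * BASE_SPACING * line_dir for k in range(slots)]
            else:
                pts = list(arc_points(a, b, slots, bulge))
            slot = 0
            for tag, item in items:
                if tag == "nt":
                    self.coords[item] = pts[slot]
                    slot += 1
                else:
                    a5, a3 = pts[slot], pts[slot + 1]
                    slot += 2
                    self.novel_anchor[id(item)] = (a5, a3, -bulge)

    # -- driver ------------------------------------------------------------

    def process_loop(self, loop: Loop) -> None:
        for child in loop.children:
            if self.helix_mapped_pairs(child):
                self.set_helix_coords(child)
        if self.loop_is_clean(loop):
            for p in loop.nt_positions:
                self.coords[p] = self.tcoords[int(self.posmap[p])]
        elif loop.kind is LoopKind.EXTERIOR:
            self._rearrange_exterior(loop)
        else:
            self._rearrange_closed_loop(loop)
        for child in loop.children:
            if self.helix_mapped_pairs(child):
                self.process_loop(child.loop)
            else:
                # novel subtree: drawn in one piece off its anchors
                if not np.all(np.isfinite(self.coords[child.outer[0]])):
                    self.set_helix_coords(child)

    def run(self) -> Layout:
        self.process_loop(self.qtree.root)
        if not np.all(np.isfinite(self.coords)):
            missing = np.flatnonzero(~np.isfinite(self.coords[:, 0]))
            raise LayoutError(f"layout left positions unplaced: {missing[:10]}")
        for p in range(self.n):
            if self.posmap[p] < 0:
                self.prov[p] = INSERTED
        return Layout(self.coords, tuple(self.prov))


def layout_from_template(
    query: str,
    qstruct: SecondaryStructure,
    template: Template,
    aln: AlignmentResult,
) -> Layout:
    """Inherit template coordinates; locally rearrange around indels."""
    return _TemplateLayouter(query, qstruct, template, aln).run()
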
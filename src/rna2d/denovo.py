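"""Template-free layout, overlap scoring and template creation.

The radial engine draws the exterior loop on a horizontal line with
helices branching upward, every loop as a circle sized by the
circumference rule.  Alternative candidate layouts (e.g. the mirrored
variant, or layouts imported from other engines) are compared by overlap
count and the least-overlapping one is kept; a forced name bypasses the
choice.  Any layout can be frozen into a reusable template so that other
sequences inherit the same diagram.
"""

from __future__ import annotations

import numpy as np

from .geometry import BASE_SPACING
from .layout import Layout, LayoutError, radial_coords
from .structure import SecondaryStructure
from .templates import Template, write_template


def layout_radial(seq: str, structure: SecondaryStructure, flip: bool = False) -> Layout:
    """Deterministic template-free layout; ``flip`` mirrors the branch side."""
    if structure.length != len(seq):
        raise LayoutError(
            f"structure length {structure.length} != sequence length {len(seq)}"
        )
    coords = radial_coords(structure, branch_sign=1.0 if flip else -1.0)
    layout = Layout(coords, ("rearranged",) * len(seq))
    layout.validate()
    return layout


def _segments(layout: Layout, structure: SecondaryStructure):
    """Drawn segments as (endpoint index a, endpoint index b)."""
    segs = [(k, k + 1) for k in range(len(layout) - 1)]
    segs += [(i, j) for i, j in structure.page0_pairs()]
    return segs


def _orient(p, q, r) -> float:
    return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])


def _on_segment(p, q, r) -> bool:
    return (
        min(p[0], q[0]) <= r[0] <= max(p[0], q[0])
        and min(p[1], q[1]) <= r[1] <= max(p[1], q[1])
    )


def segments_intersect(a, b, c, d) -> bool:
    """True if segment ab intersects segment cd (touching counts)."""
    o1, o2 = _orient(a, b, c), _orient(a, b, d)
    o3, o4 = _orient(c, d, a), _orient(c, d, b)
    if ((o1 > 0) != (o2 > 0) and (o1 != 0 and o2 != 0)) and (
        (o3 > 0) != (o4 > 0) and (o3 != 0 and o4 != 0)
    ):
        return True
    if o1 == 0 and _on_segment(a, b, c):
        return True
    if o2 == 0 and _on_segment(a, b, d):
        return True
    if o3 == 0 and _on_segment(c, d, a):
        return True
    if o4 == 0 and _on_segment(c, d, b):
        return True
    return False


def count_overlaps(layout: Layout, structure: SecondaryStructure) -> int:
    """Crossing drawn segments plus nucleotide clashes.

    Counts intersecting pairs among backbone and page-0 pair segments
    (pairs of segments sharing a nucleotide are exempt) plus pairs of
    nucleotides closer than 0.5 * BASE_SPACING that are neither backbone
    neighbours nor partners.
    """
    coords = layout.coords
    segs = _segments(layout, structure)
    count = 0
    for s in range(len(segs)):
        ia, ib = segs[s]
        for t in range(s + 1, len(segs)):
            ic, id_ = segs[t]
            if len({ia, ib, ic, id_}) < 4:
                continue
            if segments_intersect(coords[ia], coords[ib], coords[ic], coords[id_]):
                count += 1
    partner = structure.partner
    threshold = 0.5 * BASE_SPACING
    n = len(layout)
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or partner[i] == j:
                continue
            if float(np.hypot(*(coords[i] - coords[j]))) < threshold:
                count += 1
    return count


def choose_layout(
    candidates: list[tuple[str, Layout]],
    structure: SecondaryStructure,
    forced: str | None = None,
) -> tuple[str, Layout]:
    """Pick the candidate with the fewest overlaps; ties keep input order."""
    if not candidates:
        raise LayoutError("no layout candidates")
    lengths = {len(lo) for _, lo in candidates}
    if len(lengths) != 1:
        raise LayoutError(f"candidate layouts differ in length: {sorted(lengths)}")
    if forced is not None:
        for name, lo in candidates:
            if name == forced:
                return name, lo
        raise LayoutError(f"forced layout {forced!r} not among candidates")
    best = min(candidates, key=lambda c: count_overlaps(c[1], structure))
    return best


def make_template(
    template_id: str,
    seq: str,
    structure: SecondaryStructure,
    layout: Layout,
    library=None,
    name: str | None = None,
    overwrite: bool = False,
) -> Template:
    """Freeze a layout into a reusable template (category ``family``).

    Laying the same sequence out on the returned template with the
    identity alignment reproduces the coordinates exactly.
    """
    if not (len(seq) == structure.length == len(layout)):
        raise LayoutError("sequence, structure and layout lengths differ")
    template = Template(
        id=template_id,
        name=name or template_id,
        sequence=seq,
        structure=structure,
        coords=np.array(layout.coords, dtype=float),
        numbering_labels=(None,) * len(seq),
        category="family",
    )
    if library is not None:
        write_template(template, library, overwrite=overwrite)
    return template
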
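"""Secondary structures as paired positions partitioned into pages.

A *page* is a set of mutually non-crossing base pairs.  Page 0 is the
nested skeleton used for geometry; pages >= 1 hold pseudoknotted pairs,
which are drawn as connectors but never influence the layout.

Dot-bracket text uses a fixed order of bracket families: ``()``, ``[]``,
``{}``, ``<>``, then ``Aa`` .. ``Zz`` (29 families), the k-th family
encoding page k.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

#: open/close character of each bracket family, in page order.
BRACKET_FAMILIES: tuple[tuple[str, str], ...] = (
    ("(", ")"),
    ("[", "]"),
    ("{", "}"),
    ("<", ">"),
) + tuple(zip(string.ascii_uppercase, string.ascii_lowercase))

_OPEN = {o: page for page, (o, _) in enumerate(BRACKET_FAMILIES)}
_CLOSE = {c: page for page, (_, c) in enumerate(BRACKET_FAMILIES)}

UNPAIRED = -1


class StructureError(ValueError):
    """Raised for malformed dot-bracket text or inconsistent pair sets."""


def pairs_cross(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True if pairs (i,j) and (k,l) interleave (i < k < j < l or vice versa)."""
    i, j = a
    k, l = b
    return (i < k < j < l) or (k < i < l < j)


@dataclass(frozen=True)
class SecondaryStructure:
    """Base pairs of a sequence with per-pair page assignment.

    Attributes
    ----------
    length:
        Number of nucleotides.
    pairs:
        Tuples ``(i, j, page)`` with ``0 <= i < j < length``.
    predicted:
        Subset of ``{(i, j)}`` that was added by folding rather than
        inherited from a template; rendered dashed.
    """

    length: int
    pairs: tuple[tuple[int, int, int], ...]
    predicted: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        by_page: dict[int, list[tuple[int, int]]] = {}
        for i, j, page in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise StructureError(f"position reused by pair ({i},{j})")
            if page < 0:
                raise StructureError(f"negative page for pair ({i},{j})")
            seen.update((i, j))
            by_page.setdefault(page, []).append((i, j))
        for page, ps in by_page.items():
            ps.sort()
            for a in range(len(ps)):
                for b in range(a + 1, len(ps)):
                    if pairs_cross(ps[a], ps[b]):
                        raise StructureError(
                            f"pairs {ps[a]} and {ps[b]} cross within page {page}"
                        )

    @property
    def partner(self) -> np.ndarray:
        """Array mapping each position to its partner, or -1 if unpaired."""
        out = np.full(self.length, UNPAIRED, dtype=np.int64)
        for i, j, _ in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def page0_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, page in self.pairs if page == 0]

    def with_predicted(self, new_pairs, page: int = 0) -> "SecondaryStructure":
        """Return a copy with ``new_pairs`` added and flagged as predicted."""
        added = tuple((i, j, page) for i, j in new_pairs)
        return SecondaryStructure(
            self.length,
            tuple(self.pairs) + added,
            self.predicted | frozenset((i, j) for i, j in new_pairs),
        )


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse dot-bracket notation, pseudoknot families included.

    Each bracket family is matched independently with a stack; the page of
    a pair is the index of its family.
    """
    stacks: dict[int, list[int]] = {}
    pairs: list[tuple[int, int, int]] = []
    for pos, ch in enumerate(text):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            page = _CLOSE[ch]
            stack = stacks.get(page)
            if not stack:
                raise StructureError(f"unbalanced '{ch}' at position {pos}")
            pairs.append((stack.pop(), pos, page))
        else:
            raise StructureError(f"illegal character '{ch}' at position {pos}")
    for page, stack in stacks.items():
        if stack:
            opener = BRACKET_FAMILIES[page][0]
            raise StructureError(f"unbalanced '{opener}' at position {stack[0]}")
    return SecondaryStructure(len(text), tuple(sorted(pairs)))


def to_dotbracket(structure: SecondaryStructure) -> str:
    """Inverse of :func:`parse_dotbracket`; page k uses the k-th family."""
    out = ["."] * structure.length
    for i, j, page in structure.pairs:
        if page >= len(BRACKET_FAMILIES):
            raise StructureError(
                f"page {page} exceeds the {len(BRACKET_FAMILIES)} available bracket families"
            )
        o, c = BRACKET_FAMILIES[page]
        out[i], out[j] = o, c
    return "".join(out)


def assign_pages(pairs) -> "SecondaryStructure | tuple":
    """Greedy page assignment for a bare list of (i, j) pairs.

    Pairs are processed in order of increasing i (ties: decreasing j) and
    each is placed on the lowest page where it crosses nothing already
    there.  Returns the list of (i, j, page) triples; wrap in a
    SecondaryStructure yourself if you know the length.
    """
    seen: set[int] = set()
    for i, j in pairs:
        if i == j:
            raise StructureError(f"self-pair ({i},{j})")
        if i in seen or j in seen:
            raise StructureError(f"position reused by pair ({min(i, j)},{max(i, j)})")
        seen.update((i, j))
    ordered = sorted(((min(i, j), max(i, j)) for i, j in pairs), key=lambda p: (p[0], -p[1]))
    pages: list[list[tuple[int, int]]] = []
    assigned: list[tuple[int, int, int]] = []
    for p in ordered:
        for k, page in enumerate(pages):
            if not any(pairs_cross(p, q) for q in page):
                page.append(p)
                assigned.append((p[0], p[1], k))
                break
        else:
            pages.append([p])
            assigned.append((p[0], p[1], len(pages) - 1))
    return sorted(assigned)
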
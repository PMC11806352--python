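"""Decomposition of a nested structure into helices and loops.

Both layout engines work on the same tree: maximal helices are runs of
directly stacked page-0 pairs; each helix closes a loop holding the
unpaired positions and child helices between its innermost pair.  The
exterior loop is the root.  Pseudoknot pairs (pages >= 1) are ignored
here; they are drawn as connectors, never used for geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .structure import UNPAIRED, SecondaryStructure


class LoopKind(Enum):
    EXTERIOR = "exterior"
    HAIRPIN = "hairpin"
    INTERNAL = "internal"
    MULTIBRANCH = "multibranch"


@dataclass
class Helix:
    """Run of directly stacked pairs, outermost first."""

    pairs: list[tuple[int, int]]
    loop: "Loop" = None  # the loop closed by the innermost pair
    parent: "Loop" = None

    @property
    def outer(self) -> tuple[int, int]:
        return self.pairs[0]

    @property
    def inner(self) -> tuple[int, int]:
        return self.pairs[-1]

    @property
    def positions(self) -> list[int]:
        out = [i for i, _ in self.pairs]
        out += [j for _, j in reversed(self.pairs)]
        return sorted(out)


@dataclass
class Loop:
    """Loop region: cycle items in backbone order (nt positions / child helices)."""

    kind: LoopKind
    closing: Helix | None = None  # helix whose innermost pair closes this loop
    items: list[tuple[str, object]] = field(default_factory=list)  # ("nt", pos) | ("helix", Helix)

    @property
    def children(self) -> list[Helix]:
        return [h for tag, h in self.items if tag == "helix"]

    @property
    def nt_positions(self) -> list[int]:
        return [p for tag, p in self.items if tag == "nt"]

    @property
    def cycle_size(self) -> int:
        """Number of nucleotides on the loop cycle, closing pair included."""
        base = 2 if self.closing is not None else 0
        return base + sum(1 if tag == "nt" else 2 for tag, _ in self.items)


@dataclass
class StructureTree:
    root: Loop
    helices: list[Helix]
    loops: list[Loop]

    def element_of(self) -> dict[int, object]:
        """Map every position to the unique element that owns it."""
        owner: dict[int, object] = {}
        for h in self.helices:
            for p in h.positions:
                owner[p] = h
        for lp in self.loops:
            for p in lp.nt_positions:
                owner[p] = lp
        return owner


def build_tree(structure: SecondaryStructure) -> StructureTree:
    """Decompose the page-0 skeleton into helices and classified loops."""
    n = structure.length
    partner = np.full(n, UNPAIRED, dtype=np.int64)
    for i, j, page in structure.pairs:
        if page == 0:
            partner[i] = j
            partner[j] = i
    helices: list[Helix] = []
    loops: list[Loop] = []

    def parse_region(loop: Loop, lo: int, hi: int) -> None:
        pos = lo
        while pos < hi:
            p = int(partner[pos])
            if p == UNPAIRED:
                loop.items.append(("nt", pos))
                pos += 1
            else:
                helix = parse_helix(pos, p, loop)
                loop.items.append(("helix", helix))
                pos = p + 1

    def parse_helix(i: int, j: int, parent: Loop) -> Helix:
        pairs = [(i, j)]
        while i + 1 < j - 1 and partner[i + 1] == j - 1:
            i, j = i + 1, j - 1
            pairs.append((i, j))
        helix = Helix(pairs=pairs, parent=parent)
        helices.append(helix)
        inner = Loop(kind=LoopKind.HAIRPIN, closing=helix)
        parse_region(inner, i + 1, j)
        nchild = len(inner.children)
        inner.kind = (
            LoopKind.HAIRPIN
            if nchild == 0
            else LoopKind.INTERNAL
            if nchild == 1
            else LoopKind.MULTIBRANCH
        )
        loops.append(inner)
        helix.loop = inner
        return helix

    root = Loop(kind=LoopKind.EXTERIOR)
    loops.append(root)
    parse_region(root, 0, n)
    return StructureTree(root=root, helices=helices, loops=loops)
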
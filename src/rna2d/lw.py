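"""Leontis-Westhof base-pair annotation.

Non-canonical base pairs are classified by the interacting edge of each
nucleotide (Watson-Crick, Hoogsteen or Sugar) and the glycosidic-bond
orientation (cis or trans), giving 12 geometric families written as codes
like ``cWW`` or ``tHS``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Edge(Enum):
    WATSON_CRICK = "W"
    HOOGSTEEN = "H"
    SUGAR = "S"


class Orientation(Enum):
    CIS = "c"
    TRANS = "t"


class LwError(ValueError):
    pass


@dataclass(frozen=True)
class BasePairAnnotation:
    """One annotated pair: positions are 0-based, i < j."""

    i: int
    j: int
    edge5: Edge
    edge3: Edge
    orientation: Orientation
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise LwError(f"annotation requires i < j, got ({self.i},{self.j})")

    @property
    def code(self) -> str:
        return format_lw(self.orientation, self.edge5, self.edge3)

    @property
    def is_cww(self) -> bool:
        return (
            self.orientation is Orientation.CIS
            and self.edge5 is Edge.WATSON_CRICK
            and self.edge3 is Edge.WATSON_CRICK
        )


def parse_lw(code: str) -> tuple[Orientation, Edge, Edge]:
    """Decode an LW code such as ``cWW`` or ``tHS`` (case-insensitive)."""
    if len(code) != 3:
        raise LwError(f"unknown Leontis-Westhof code {code!r}")
    o, e5, e3 = code[0].lower(), code[1].upper(), code[2].upper()
    try:
        return (
            Orientation(o),
            Edge(e5),
            Edge(e3),
        )
    except ValueError:
        raise LwError(f"unknown Leontis-Westhof code {code!r}") from None


def format_lw(orientation: Orientation, edge5: Edge, edge3: Edge) -> str:
    """Canonical form: lowercase orientation, uppercase edges."""
    return f"{orientation.value}{edge5.value}{edge3.value}"


def annotation_from_code(i: int, j: int, code: str, canonical: bool = False) -> BasePairAnnotation:
    orientation, e5, e3 = parse_lw(code)
    return BasePairAnnotation(i, j, e5, e3, orientation, canonical)
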
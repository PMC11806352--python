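"""FASTA input with an optional dot-bracket structure line.

The dialect accepted here is plain FASTA where the lines following the
sequence of a record may include one structure line in dot-bracket
notation (pseudoknot bracket families allowed).  A line counts as a
structure line when all of its characters belong to the bracket alphabet
and it is not the first line after the header (an all-``A`` sequence is a
sequence, not a run of page-A brackets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .structure import BRACKET_FAMILIES, SecondaryStructure, StructureError, parse_dotbracket

logger = logging.getLogger(__name__)

_BRACKET_CHARS = {"."} | {c for fam in BRACKET_FAMILIES for c in fam}
_NUCLEOTIDES = set("ACGUN")


class FastaError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A named RNA sequence with an optional secondary structure."""

    id: str
    sequence: str
    structure: SecondaryStructure | None = None

    def __post_init__(self) -> None:
        if self.structure is not None and self.structure.length != len(self.sequence):
            raise FastaError(
                f"structure length {self.structure.length} != sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase, DNA T mapped to U; anything outside ACGUN becomes N."""
    seq = raw.upper().replace("T", "U")
    cleaned = []
    for ch in seq:
        if ch in _NUCLEOTIDES:
            cleaned.append(ch)
        else:
            logger.warning("replacing unexpected character %r with N", ch)
            cleaned.append("N")
    return "".join(cleaned)


def _looks_like_structure(line: str) -> bool:
    chars = set(line)
    return bool(chars) and chars <= _BRACKET_CHARS and not chars <= _NUCLEOTIDES


def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text; a bracket-alphabet line after the sequence is a structure."""
    records: list[SequenceRecord] = []
    header: str | None = None
    seq_parts: list[str] = []
    struct_parts: list[str] = []
    after_header = False

    def flush() -> None:
        nonlocal header, seq_parts, struct_parts
        if header is None:
            return
        seq = normalize_sequence("".join(seq_parts))
        if not seq:
            raise FastaError(f"record {header!r} has no sequence")
        structure = None
        if struct_parts:
            db = "".join(struct_parts)
            if len(db) != len(seq):
                raise FastaError(
                    f"structure length {len(db)} != sequence length {len(seq)} in record {header!r}"
                )
            try:
                structure = parse_dotbracket(db)
            except StructureError as exc:
                raise FastaError(f"bad structure line in record {header!r}: {exc}") from exc
        records.append(SequenceRecord(header, seq, structure))
        header, seq_parts, struct_parts = None, [], []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            after_header = True
            continue
        if header is None:
            raise FastaError("sequence data before first header")
        # ambiguity between sequence and letter-family brackets resolves to
        # sequence directly after the header
        if (not after_header and _looks_like_structure(line)) or struct_parts:
            struct_parts.append(line)
        else:
            seq_parts.append(line)
        after_header = False
    flush()
    if not records:
        raise FastaError("empty FASTA input")
    return records


def write_fasta(records: list[SequenceRecord]) -> str:
    from .structure import to_dotbracket

    lines: list[str] = []
    for rec in records:
        lines.append(f">{rec.id}")
        lines.append(rec.sequence)
        if rec.structure is not None:
            lines.append(to_dotbracket(rec.structure))
    return "\n".join(lines) + "\n"
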
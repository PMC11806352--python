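"""Synthetic template library and query generators.

Stands in for real template collections so the whole pipeline is testable
offline: a tRNA-style cloverleaf with Sprinzl-style numbering labels, a
5S-like three-helix molecule, a long multi-stem molecule and a small
pseudoknotted hairpin.  Coordinates are produced by the radial engine and
frozen to disk in the library format.

All randomness flows through numpy's seeded PCG64 generator, so the same
seed yields byte-identical fixture files on every platform.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .align import AlignmentResult, AlignParams
from .denovo import layout_radial
from .io import SequenceRecord
from .structure import SecondaryStructure, parse_dotbracket
from .templates import Template, TemplateLibrary, write_template

_PAIR_CHOICES = ("AU", "UA", "GC", "CG", "GC", "CG")  # GC-rich stems
_BASES = "ACGU"


class FixtureError(ValueError):
    pass


def _sequence_for(structure: SecondaryStructure, rng: np.random.Generator) -> str:
    """Random sequence whose paired positions are complementary."""
    seq = [""] * structure.length
    partner = structure.partner
    for i in range(structure.length):
        if seq[i]:
            continue
        j = int(partner[i])
        if j >= 0:
            a, b = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
            seq[i], seq[j] = a, b
        else:
            seq[i] = _BASES[rng.integers(4)]
    return "".join(seq)


def _cloverleaf_db() -> str:
    db = (
        "(((((((" + ".." + "((((" + "........" + "))))" + "."
        + "(((((" + "......." + ")))))" + "....."
        + "(((((" + "......." + ")))))" + ")))))))" + "...."
    )
    assert len(db) == 76
    return db


def _fives_db() -> str:
    db = (
        "......" + "((((((((((((((" + "....."
        + "((((((((((((" + "........" + "))))))))))))" + "....."
        + "((((((((((((" + "........" + "))))))))))))" + "...."
        + "))))))))))))))" + "........"
    )
    assert len(db) == 120
    return db


def _long_db() -> str:
    stem_loop = lambda s, l: "(" * s + "." * l + ")" * s
    db = (
        "........"
        + stem_loop(15, 10) + "....."
        + stem_loop(20, 12) + "....."
        + "((((((((((" + "..." + stem_loop(12, 10) + "..." + "))))))))))" + "....."
        + stem_loop(18, 9)
    )
    db += "." * (300 - len(db))
    assert len(db) == 300
    return db


def _pseudoknot_db() -> str:
    db = ".((..[..)).].."
    assert len(db) == 14
    return db


def make_toy_templates(seed: int, outdir: Path | None = None) -> TemplateLibrary:
    """Deterministic four-template library; written to ``outdir`` if given."""
    rng = np.random.default_rng(seed)
    specs = [
        ("tmpl_long", "long multi-stem fixture", _long_db(), "long", False),
        ("tmpl_5s", "5S-like three-helix fixture", _fives_db(), "family", False),
        ("tmpl_pk", "pseudoknotted hairpin fixture", _pseudoknot_db(), "family", False),
        ("tmpl_trna", "cloverleaf fixture", _cloverleaf_db(), "trna", True),
    ]
    templates: dict[str, Template] = {}
    for tid, name, db, category, sprinzl in specs:
        structure = parse_dotbracket(db)
        seq = _sequence_for(structure, rng)
        layout = layout_radial(seq, structure)
        labels = tuple(str(k + 1) for k in range(len(seq))) if sprinzl else (None,) * len(seq)
        templates[tid] = Template(
            id=tid,
            name=name,
            sequence=seq,
            structure=structure,
            coords=np.array(layout.coords, dtype=float),
            numbering_labels=labels,
            category=category,
        )
    library = TemplateLibrary(templates, stages=["long", "family", "trna"])
    if outdir is not None:
        for t in templates.values():
            write_template(t, Path(outdir), overwrite=True)
    return library


def mutate_query(
    template: Template,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    seed: int,
) -> tuple[SequenceRecord, AlignmentResult]:
    """Mutated copy of the template sequence plus the true edit script.

    Point substitutions, single-nucleotide insertions and deletions are
    drawn independently per position; rates are capped at 0.2 so the
    planted template remains recoverable in principle.
    """
    for name, rate in (("sub", sub_rate), ("ins", ins_rate), ("del", del_rate)):
        if not 0.0 <= rate <= 0.2:
            raise FixtureError(f"{name}_rate {rate} outside [0, 0.2]")
    rng = np.random.default_rng(seed)
    params = AlignParams()
    chars: list[str] = []
    ops: list[str] = []
    score = 0

    def emit_insert() -> None:
        chars.append(_BASES[rng.integers(4)])
        ops.append("I")

    if rng.random() < ins_rate:
        emit_insert()
    for t, base in enumerate(template.sequence):
        if rng.random() < del_rate:
            ops.append("D")
        else:
            if rng.random() < sub_rate:
                base = _BASES[rng.integers(4)]
            chars.append(base)
            ops.append("M")
        if rng.random() < ins_rate:
            emit_insert()

    n, m = len(chars), len(template.sequence)
    posmap = np.full(n, -1, dtype=np.int64)
    revmap = np.full(m, -1, dtype=np.int64)
    qi = ti = 0
    runs: list[tuple[str, int]] = []
    for op in ops:
        if op == "M":
            posmap[qi] = ti
            revmap[ti] = qi
            score += (
                params.match if chars[qi] == template.sequence[ti] else params.mismatch
            )
            qi += 1
            ti += 1
        elif op == "I":
            qi += 1
        else:
            ti += 1
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
    for op, count in runs:
        if op != "M":
            score += params.gap_open + params.gap_extend * count
    record = SequenceRecord(f"{template.id}_mut{seed}", "".join(chars))
    truth = AlignmentResult(tuple(runs), score, posmap, revmap)
    return record, truth


def loop_indel_query(
    template: Template, seed: int
) -> tuple[SequenceRecord, AlignmentResult, int]:
    """Single insertion or deletion planted at an unpaired loop position.

    Returns the query record, the true alignment and the edited template
    position (useful for locality checks: everything outside the edited
    loop must keep its template coordinates).
    """
    rng = np.random.default_rng(seed)
    partner = template.structure.partner
    unpaired = [p for p in range(len(template)) if partner[p] < 0]
    if not unpaired:
        raise FixtureError("template has no unpaired positions")
    pos = int(unpaired[rng.integers(len(unpaired))])
    insert = bool(rng.integers(2))
    seq = template.sequence
    params = AlignParams()
    if insert:
        chars = seq[: pos + 1] + _BASES[rng.integers(4)] + seq[pos + 1 :]
        ops = [("M", pos + 1), ("I", 1), ("M", len(seq) - pos - 1)]
    else:
        chars = seq[:pos] + seq[pos + 1 :]
        ops = [("M", pos), ("D", 1), ("M", len(seq) - pos - 1)]
        ops = [(op, c) for op, c in ops if c > 0]
    n, m = len(chars), len(seq)
    posmap = np.full(n, -1, dtype=np.int64)
    revmap = np.full(m, -1, dtype=np.int64)
    qi = ti = 0
    score = 0
    for op, count in ops:
        for _ in range(count):
            if op == "M":
                posmap[qi] = ti
                revmap[ti] = qi
                score += params.match
                qi += 1
                ti += 1
            elif op == "I":
                qi += 1
            else:
                ti += 1
        if op != "M":
            score += params.gap_open + params.gap_extend * count
    record = SequenceRecord(f"{template.id}_indel{seed}", chars)
    return record, AlignmentResult(tuple(ops), score, posmap, revmap), pos
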
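"""Template selection: k-mer seed filtering plus affine-gap alignment.

Selection runs in stages over template categories (by default ``long``,
then ``family``, then ``trna``).  Within a stage, candidate templates are
ranked by a seed-and-extend style filter counting shared k-mers binned by
diagonal band, the top candidates are aligned with a semi-global
affine-gap DP, and the best hit is accepted when its normalized score
(score / (2 * query length)) reaches the threshold tau.  Unmatched
queries fall through to the next stage; a query matches at most one
template.  Selection can be bypassed by naming a template directly.

The alignment is semi-global with free end gaps on the *template*, so a
fragment query maps into the interior of a long template without paying
for the overhangs.  A gap of length L costs ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .structure import SecondaryStructure
from .templates import Template, TemplateLibrary

NEG = -(10**9)

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

MATCH = "M"
INSERT = "I"  # query-only
DELETE = "D"  # template-only


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1


@dataclass(frozen=True)
class AlignmentResult:
    """Query <-> template position map with run-length operations.

    ``ops`` is a run-length list like ``[("M", 10), ("I", 2), ...]``;
    ``posmap[q]`` is the template position matched to query position q or
    -1 if q is inserted; ``revmap[t]`` is the query position matched to
    template position t or -1 if t is deleted.
    """

    ops: tuple[tuple[str, int], ...]
    score: int
    posmap: np.ndarray
    revmap: np.ndarray

    @property
    def query_length(self) -> int:
        return int(self.posmap.shape[0])

    @property
    def template_length(self) -> int:
        return int(self.revmap.shape[0])

    def normalized_score(self, params: AlignParams = AlignParams()) -> float:
        return self.score / (params.match * self.query_length)

    @classmethod
    def identity(cls, n: int) -> "AlignmentResult":
        idx = np.arange(n, dtype=np.int64)
        return cls(((MATCH, n),), 2 * n, idx, idx.copy())


def encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE.get(c, 4) for c in seq], dtype=np.int8)


@njit(cache=False)
def _gotoh_fill(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = q.shape[0], t.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # insert state (query-only)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # delete state (template-only)
    M[0, 0] = 0
    for j in range(1, m + 1):
        Y[0, j] = 0  # leading template overhang is free
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * i
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == t[j - 1] and qi != 4 and t[j - 1] != 4) else mismatch
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if best_prev > NEG:
                M[i, j] = best_prev + s
            x = max(
                M[i - 1, j] + gap_open + gap_extend,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open + gap_extend,
            )
            X[i, j] = x
            y = max(
                M[i, j - 1] + gap_open + gap_extend,
                Y[i, j - 1] + gap_extend,
                X[i, j - 1] + gap_open + gap_extend,
            )
            Y[i, j] = y
    return M, X, Y


def align(query: str, template_seq: str, params: AlignParams = AlignParams()) -> AlignmentResult:
    """Semi-global affine-gap alignment, free end gaps on the template.

    Traceback is deterministic: on ties prefer Match, then Delete, then
    Insert; among equally scoring end columns, the rightmost is used.
    """
    if not query or not template_seq:
        raise AlignmentError("cannot align an empty sequence")
    q, t = encode(query), encode(template_seq)
    n, m = len(q), len(t)
    M, X, Y = _gotoh_fill(
        q, t, params.match, params.mismatch, params.gap_open, params.gap_extend
    )
    # trailing template overhang is free: end anywhere on the last row
    ends = np.maximum(np.maximum(M[n], X[n]), Y[n])
    score = int(ends.max())
    j_end = int(np.flatnonzero(ends == score)[-1])

    go, ge = params.gap_open, params.gap_extend
    ops_rev: list[str] = ["D"] * (m - j_end)
    i, j = n, j_end
    # pick the state at the end cell: Match > Delete > Insert on ties
    if M[i, j] == score:
        state = "M"
    elif Y[i, j] == score:
        state = "D"
    else:
        state = "I"
    while i > 0 or j > 0:
        if state == "M":
            if i == 0 or j == 0:
                break
            ops_rev.append("M")
            prev = M[i, j] - (
                params.match
                if q[i - 1] == t[j - 1] and q[i - 1] != 4 and t[j - 1] != 4
                else params.mismatch
            )
            i, j = i - 1, j - 1
            if M[i, j] == prev:
                state = "M"
            elif Y[i, j] == prev:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            if i == 0:
                # leading free template overhang
                ops_rev.extend("D" * j)
                j = 0
                break
            ops_rev.append("D")
            val = Y[i, j]
            j -= 1
            if M[i, j] + go + ge == val:
                state = "M"
            elif Y[i, j] + ge == val:
                state = "D"
            else:
                state = "I"
        else:  # Insert
            ops_rev.append("I")
            val = X[i, j]
            i -= 1
            if M[i, j] + go + ge == val:
                state = "M"
            elif Y[i, j] + go + ge == val:
                state = "D"
            else:
                state = "I"
        if i == 0 and j == 0:
            break
    ops_chars = ops_rev[::-1]

    posmap = np.full(n, -1, dtype=np.int64)
    revmap = np.full(m, -1, dtype=np.int64)
    qi = ti = 0
    runs: list[tuple[str, int]] = []
    for op in ops_chars:
        if op == "M":
            posmap[qi] = ti
            revmap[ti] = qi
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
    if qi != n or ti != m:
        raise AssertionError("traceback did not consume both sequences")
    return AlignmentResult(tuple(runs), score, posmap, revmap)


def seed_filter(
    query: str,
    templates: list[Template],
    k: int = 12,
    min_seeds: int = 2,
) -> list[tuple[Template, int]]:
    """Rank templates by shared k-mers voting in diagonal bands of width 2k.

    Returns (template, band score) pairs with band score >= ``min_seeds``,
    sorted by descending score, ties broken by template id.
    """
    if k < 4:
        raise AlignmentError(f"seed length {k} < 4")
    if k > len(query):
        raise AlignmentError(f"seed length {k} exceeds query length {len(query)}")
    band = 2 * k
    qmers: dict[str, list[int]] = {}
    for p in range(len(query) - k + 1):
        mer = query[p : p + k]
        if "N" in mer:
            continue
        qmers.setdefault(mer, []).append(p)
    scored: list[tuple[Template, int]] = []
    for t in templates:
        votes: dict[int, int] = {}
        for p in range(len(t.sequence) - k + 1):
            hits = qmers.get(t.sequence[p : p + k])
            if not hits:
                continue
            for qp in hits:
                b = (qp - p) // band
                votes[b] = votes.get(b, 0) + 1
        if votes:
            best = max(votes.values())
            if best >= min_seeds:
                scored.append((t, best))
    scored.sort(key=lambda pair: (-pair[1], pair[0].id))
    return scored


@dataclass
class SelectionConfig:
    stages: list[str] = field(default_factory=lambda: ["long", "family", "trna"])
    k: dict[str, int] = field(default_factory=lambda: {"long": 12, "family": 8, "trna": 8})
    min_seeds: int = 2
    tau: float = 0.5
    max_candidates: int = 3
    template_id: str | None = None  # bypass selection entirely
    params: AlignParams = field(default_factory=AlignParams)


def select_template(
    query: str, library: TemplateLibrary, config: SelectionConfig | None = None
) -> tuple[Template, AlignmentResult] | None:
    """Staged template selection; returns the single best hit or None."""
    config = config or SelectionConfig()
    if config.template_id is not None:
        if config.template_id not in library.templates:
            raise AlignmentError(f"bypass template {config.template_id!r} not in library")
        t = library.templates[config.template_id]
        return t, align(query, t.sequence, config.params)
    for stage in config.stages:
        templates = library.by_category(stage)
        if not templates:
            continue
        k = config.k.get(stage, 8)
        if k > len(query):
            continue
        candidates = seed_filter(query, templates, k=k, min_seeds=config.min_seeds)
        hits: list[tuple[float, str, Template, AlignmentResult]] = []
        for t, _ in candidates[: config.max_candidates]:
            aln = align(query, t.sequence, config.params)
            hits.append((aln.normalized_score(config.params), t.id, t, aln))
        if hits:
            hits.sort(key=lambda h: (-h[0], h[1]))
            best_score, _, best_t, best_aln = hits[0]
            if best_score >= config.tau:
                return best_t, best_aln
    return None


def transfer_structure(template: Template, aln: AlignmentResult) -> SecondaryStructure:
    """Map the template's pairs (pseudoknot pages included) onto the query.

    Pairs whose partner is deleted are dropped; inserted query positions
    stay unpaired.
    """
    revmap = aln.revmap
    pairs = []
    for i, j, page in template.structure.pairs:
        qi, qj = int(revmap[i]), int(revmap[j])
        if qi >= 0 and qj >= 0:
            pairs.append((qi, qj, page))
    return SecondaryStructure(aln.query_length, tuple(sorted(pairs)))
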
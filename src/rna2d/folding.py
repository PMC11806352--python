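"""Constrained maximum-base-pair folding.

A Nussinov-style dynamic program maximizes the number of base pairs
subject to constraints: pairs come from the canonical + wobble alphabet
{AU, UA, GC, CG, GU, UG}, hairpin loops keep j - i > 3, required pairs
must appear, masked positions may not pair, and new pairs may be confined
to a region.  Three pipeline modes mirror how diagrams use it: local
(fold each long insertion on its own), global (refold the whole molecule
with the template pairs fixed) and global with an exclusion mask.

This is a pure pair-counting model: no thermodynamic energies, no
pseudoknotted output (all predicted pairs are nested, page 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentResult
from .structure import SecondaryStructure, pairs_cross
from .templates import Template

MIN_HAIRPIN = 3  # pairs require j - i > 3
MIN_LOCAL_FOLD = 6  # insertions shorter than this stay unfolded loops

_CAN_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


class FoldingError(ValueError):
    pass


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


@dataclass(frozen=True)
class FoldConstraint:
    """Constraints for :func:`fold_max_pairs`.

    fixed_pairs must appear in the output; forbidden positions may not
    pair; region (half-open) confines where *new* pairs may form.
    """

    fixed_pairs: tuple[tuple[int, int], ...] = ()
    forbidden: frozenset[int] = field(default_factory=frozenset)
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        fixed = tuple(sorted((min(i, j), max(i, j)) for i, j in self.fixed_pairs))
        object.__setattr__(self, "fixed_pairs", fixed)
        for i, j in fixed:
            if i == j:
                raise FoldingError(f"fixed self-pair ({i},{j})")
            if i in seen or j in seen:
                raise FoldingError(f"position reused by fixed pair ({i},{j})")
            seen.update((i, j))
            if i in self.forbidden or j in self.forbidden:
                raise FoldingError(f"fixed pair ({i},{j}) touches a forbidden position")
        for a in range(len(fixed)):
            for b in range(a + 1, len(fixed)):
                if pairs_cross(fixed[a], fixed[b]):
                    raise FoldingError(f"fixed pairs {fixed[a]} and {fixed[b]} cross")


def fold_max_pairs(seq: str, constraint: FoldConstraint | None = None) -> SecondaryStructure:
    """Maximum-pairing DP under the constraint; deterministic traceback.

    On ties the traceback prefers pairing position i with the smallest
    admissible j, then bifurcating at the smallest k.  Fixed pairs carry a
    dominating weight so every feasible optimum retains all of them; the
    reported structure flags only the non-fixed additions as predicted.
    """
    n = len(seq)
    constraint = constraint or FoldConstraint()
    fixed = set(constraint.fixed_pairs)
    fixed_pos = {p for pr in fixed for p in pr}
    for i, j in fixed:
        if j >= n:
            raise FoldingError(f"fixed pair ({i},{j}) out of range for length {n}")
        if j - i <= MIN_HAIRPIN:
            raise FoldingError(f"fixed pair ({i},{j}) violates the hairpin rule j - i > {MIN_HAIRPIN}")
        if not can_pair(seq[i], seq[j]):
            raise FoldingError(
                f"fixed pair ({i},{j}) joins non-complementary {seq[i]}-{seq[j]}"
            )
    lo, hi = constraint.region if constraint.region is not None else (0, n)
    big = n + 1  # weight making every fixed pair dominate any set of new pairs

    def admissible(i: int, j: int) -> int:
        """Weight of pairing (i, j), or 0 if not allowed."""
        if (i, j) in fixed:
            return big
        if i in fixed_pos or j in fixed_pos:
            return 0
        if i in constraint.forbidden or j in constraint.forbidden:
            return 0
        if not (lo <= i and j < hi):
            return 0
        if j - i <= MIN_HAIRPIN or not can_pair(seq[i], seq[j]):
            return 0
        # never cross a fixed pair
        for f in fixed:
            if pairs_cross((i, j), f):
                return 0
        return 1

    W = [[0] * n for _ in range(n)]
    allowed = [[admissible(i, j) for j in range(n)] for i in range(n)]
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1][j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                w = allowed[i][k]
                if not w:
                    continue
                inner = W[i + 1][k - 1] if k - 1 > i else 0
                rest = W[k + 1][j] if k + 1 <= j else 0
                cand = w + inner + rest
                if cand > best:
                    best = cand
            W[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_HAIRPIN and W[i][j] == 0:
            continue
        best = W[i][j]
        if best == 0:
            continue
        paired = False
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            w = allowed[i][k]
            if not w:
                continue
            inner = W[i + 1][k - 1] if k - 1 > i else 0
            rest = W[k + 1][j] if k + 1 <= j else 0
            if w + inner + rest == best:
                pairs.append((i, k))
                if k - 1 > i:
                    stack.append((i + 1, k - 1))
                if k + 1 < j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))

    missing = fixed - set(pairs)
    if missing:  # cannot happen when the weights dominate; guard regardless
        raise FoldingError(f"infeasible constraint: fixed pairs {sorted(missing)} lost")
    new_pairs = sorted(set(pairs) - fixed)
    structure = SecondaryStructure(
        n, tuple(sorted((i, j, 0) for i, j in pairs)), frozenset(new_pairs)
    )
    return structure


def inserted_runs(aln: AlignmentResult) -> list[tuple[int, int]]:
    """Maximal runs of inserted query positions as half-open intervals."""
    runs: list[tuple[int, int]] = []
    start = None
    for q in range(aln.query_length):
        if aln.posmap[q] < 0:
            if start is None:
                start = q
        elif start is not None:
            runs.append((start, q))
            start = None
    if start is not None:
        runs.append((start, aln.query_length))
    return runs


def fold_local(
    seq: str, qstruct: SecondaryStructure, aln: AlignmentResult
) -> SecondaryStructure:
    """Fold each inserted run of >= MIN_LOCAL_FOLD nt on its own.

    Template-derived pairs are untouched; predicted pairs never leave
    their run.
    """
    out = qstruct
    for lo, hi in inserted_runs(aln):
        if hi - lo < MIN_LOCAL_FOLD:
            continue
        forbidden = frozenset(range(0, lo)) | frozenset(range(hi, len(seq)))
        sub = fold_max_pairs(seq, FoldConstraint(forbidden=forbidden, region=(lo, hi)))
        out = out.with_predicted(sorted(sub.predicted))
    return out


def _pseudoknotted_positions(qstruct: SecondaryStructure) -> frozenset[int]:
    return frozenset(p for i, j, page in qstruct.pairs if page > 0 for p in (i, j))


def _split_fixable(seq: str, qstruct: SecondaryStructure):
    """Template pairs the DP can enforce vs. those it can only protect.

    A transferred pair whose bases mutated apart (or whose span shrank
    below the hairpin limit) stays in the drawing, but the DP cannot fix
    it; its positions are simply barred from re-pairing.
    """
    fixable: list[tuple[int, int]] = []
    blocked: set[int] = set(_pseudoknotted_positions(qstruct))
    for i, j in qstruct.page0_pairs():
        if j - i > MIN_HAIRPIN and can_pair(seq[i], seq[j]):
            fixable.append((i, j))
        else:
            blocked.update((i, j))
    return tuple(fixable), frozenset(blocked)


def fold_global(seq: str, qstruct: SecondaryStructure) -> SecondaryStructure:
    """Refold the whole molecule with the existing page-0 pairs fixed."""
    fixed, blocked = _split_fixable(seq, qstruct)
    folded = fold_max_pairs(seq, FoldConstraint(fixed_pairs=fixed, forbidden=blocked))
    return qstruct.with_predicted(sorted(folded.predicted))


def build_default_mask(aln: AlignmentResult, template: Template) -> frozenset[int]:
    """Query positions aligned to template positions that are unpaired there."""
    t_partner = template.structure.partner
    mask = set()
    for q in range(aln.query_length):
        t = int(aln.posmap[q])
        if t >= 0 and t_partner[t] < 0:
            mask.add(q)
    return frozenset(mask)


def fold_global_masked(
    seq: str, qstruct: SecondaryStructure, mask: frozenset[int]
) -> SecondaryStructure:
    """Global folding with an exclusion mask barring positions from pairing."""
    fixed, blocked = _split_fixable(seq, qstruct)
    for i, j in fixed:
        if i in mask or j in mask:
            raise FoldingError(f"mask forbids fixed pair ({i},{j})")
    folded = fold_max_pairs(
        seq, FoldConstraint(fixed_pairs=fixed, forbidden=frozenset(mask) | blocked)
    )
    return qstruct.with_predicted(sorted(folded.predicted))
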
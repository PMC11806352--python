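"""Independent oracles and random-input generators for the test suite.

Everything here is deliberately written without reusing the package's own
algorithms: brute-force enumeration, closed forms, or exhaustive search at
small n, so the tests check the implementation against a second route.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

from rna2d.structure import SecondaryStructure, pairs_cross

_CAN = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


# -- secondary-structure generators -----------------------------------------


def random_nested_structure(rng: np.random.Generator, n: int) -> SecondaryStructure:
    """Random non-crossing structure via a stack walk (hairpin rule kept)."""
    stack: list[int] = []
    pairs: list[tuple[int, int, int]] = []
    for pos in range(n):
        r = rng.random()
        if r < 0.35 and pos < n - 4:
            stack.append(pos)
        elif r < 0.7 and stack and pos - stack[-1] > 3:
            pairs.append((stack.pop(), pos, 0))
    return SecondaryStructure(n, tuple(sorted(pairs)))


def random_pair_set(rng: np.random.Generator, n_pairs: int, span: int):
    """Disjoint (possibly crossing) pairs on positions 0..span-1."""
    positions = rng.permutation(span)[: 2 * n_pairs]
    it = iter(positions)
    return sorted((min(a, b), max(a, b)) for a, b in zip(it, it))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGU"[int(k)] for k in rng.integers(0, 4, n))


# -- page-minimization oracle ------------------------------------------------


def min_pages_bruteforce(pairs: list[tuple[int, int]]) -> int:
    """Smallest number of mutually non-crossing classes covering the pairs."""
    if not pairs:
        return 0
    for k in range(1, len(pairs) + 1):
        for assignment in itertools.product(range(k), repeat=len(pairs)):
            ok = True
            for a in range(len(pairs)):
                for b in range(a + 1, len(pairs)):
                    if assignment[a] == assignment[b] and pairs_cross(pairs[a], pairs[b]):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                return k
    raise AssertionError("unreachable")


# -- alignment oracle ---------------------------------------------------------


def align_score_bruteforce(
    query: str,
    template: str,
    match: int = 2,
    mismatch: int = -1,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> int:
    """Max score over all alignments; template end gaps free, affine internal.

    Enumerates every monotone op string (practical for lengths <= 8) and
    scores runs: a gap run of length L costs gap_open + L * gap_extend,
    except template-only runs touching either end, which are free.
    """
    n, m = len(query), len(template)
    best = -(10**9)
    stack: list[tuple[int, int, tuple[str, ...]]] = [(0, 0, ())]
    while stack:
        i, j, ops = stack.pop()
        if i == n and j == m:
            score = 0
            runs = [(op, len(list(g))) for op, g in itertools.groupby(ops)]
            for idx, (op, length) in enumerate(runs):
                if op == "M":
                    qi = sum(r[1] for r in runs[:idx] if r[0] in "MI")
                    ti = sum(r[1] for r in runs[:idx] if r[0] in "MD")
                    for k in range(length):
                        a, b = query[qi + k], template[ti + k]
                        score += match if (a == b and a != "N") else mismatch
                elif op == "D" and (idx == 0 or idx == len(runs) - 1):
                    continue  # free template overhang
                else:
                    score += gap_open + gap_extend * length
            best = max(best, score)
            continue
        if i < n and j < m:
            stack.append((i + 1, j + 1, ops + ("M",)))
        if i < n:
            stack.append((i + 1, j, ops + ("I",)))
        if j < m:
            stack.append((i, j + 1, ops + ("D",)))
    return best


# -- folding oracle -----------------------------------------------------------


def max_pairs_bruteforce(seq: str, forbidden: frozenset[int] = frozenset()) -> int:
    """Maximum nested pairing count by memoized interval recursion."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= 3:
            return 0
        out = best(i + 1, j)
        if i not in forbidden:
            for k in range(i + 4, j + 1):
                if k in forbidden:
                    continue
                if (seq[i], seq[k]) in _CAN:
                    inner = best(i + 1, k - 1)
                    rest = best(k + 1, j) if k < j else 0
                    out = max(out, 1 + inner + rest)
        return out

    return best(0, len(seq) - 1) if seq else 0


# -- overlap oracle -----------------------------------------------------------


def _seg_intersect(p1, p2, p3, p4) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True

    def between(a, b, c):
        return min(a[0], b[0]) <= c[0] <= max(a[0], b[0]) and min(a[1], b[1]) <= c[1] <= max(
            a[1], b[1]
        )

    for d, (a, b, c) in (
        (d1, (p3, p4, p1)),
        (d2, (p3, p4, p2)),
        (d3, (p1, p2, p3)),
        (d4, (p1, p2, p4)),
    ):
        if d == 0 and between(a, b, c):
            return True
    return False


def count_overlaps_bruteforce(coords: np.ndarray, structure: SecondaryStructure) -> int:
    n = coords.shape[0]
    segs = [(k, k + 1) for k in range(n - 1)]
    segs += [(i, j) for i, j, page in structure.pairs if page == 0]
    total = 0
    for a in range(len(segs)):
        for b in range(a + 1, len(segs)):
            ids = {*segs[a], *segs[b]}
            if len(ids) < 4:
                continue
            if _seg_intersect(
                coords[segs[a][0]], coords[segs[a][1]], coords[segs[b][0]], coords[segs[b][1]]
            ):
                total += 1
    partner = structure.partner
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or partner[i] == j:
                continue
            if math.hypot(*(coords[i] - coords[j])) < 4.0:
                total += 1
    return total


# -- SSIM closed form ---------------------------------------------------------


def ssim_closed_form(a: np.ndarray, b: np.ndarray) -> float:
    """Direct evaluation of the single-window SSIM formula on greyscale."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim == 3:
        a = 0.299 * a[..., 0] + 0.587 * a[..., 1] + 0.114 * a[..., 2]
        b = 0.299 * b[..., 0] + 0.587 * b[..., 1] + 0.114 * b[..., 2]
    c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    va, vb = ((a - mu_a) ** 2).mean(), ((b - mu_b) ** 2).mean()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
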
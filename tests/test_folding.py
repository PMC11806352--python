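"""Constrained maximum-pair folding against brute-force enumeration."""

import numpy as np
import pytest

from helpers import max_pairs_bruteforce, random_sequence
from rna2d.align import AlignmentResult, transfer_structure
from rna2d.folding import (
    FoldConstraint,
    FoldingError,
    build_default_mask,
    fold_global,
    fold_global_masked,
    fold_local,
    fold_max_pairs,
    inserted_runs,
)
from rna2d.structure import SecondaryStructure, parse_dotbracket


class TestFoldMaxPairs:
    def test_worked_example(self):
        s = fold_max_pairs("GGGAAACCC")
        assert {(i, j) for i, j, _ in s.pairs} == {(0, 8), (1, 7), (2, 6)}
        assert len(s.pairs) == max_pairs_bruteforce("GGGAAACCC") == 3

    def test_no_complementary_pairs(self):
        assert fold_max_pairs("AAAA").pairs == ()

    def test_full_mask_blocks_everything(self):
        c = FoldConstraint(forbidden=frozenset(range(9)))
        assert fold_max_pairs("GGGAAACCC", c).pairs == ()

    def test_fixed_pair_retained(self):
        c = FoldConstraint(fixed_pairs=((0, 8),))
        s = fold_max_pairs("GAAAAAAAC", c)
        assert (0, 8, 0) in s.pairs
        assert (0, 8) not in s.predicted

    @pytest.mark.parametrize(
        "seq,pair,message",
        [
            ("GAAC", (0, 3), "hairpin"),
            ("GAAAAAAAG", (0, 8), "non-complementary"),
        ],
    )
    def test_infeasible_fixed_pair(self, seq, pair, message):
        with pytest.raises(FoldingError, match=message):
            fold_max_pairs(seq, FoldConstraint(fixed_pairs=(pair,)))

    def test_constraint_invariants(self):
        with pytest.raises(FoldingError, match="cross"):
            FoldConstraint(fixed_pairs=((0, 8), (4, 12)))
        with pytest.raises(FoldingError, match="forbidden"):
            FoldConstraint(fixed_pairs=((0, 8),), forbidden=frozenset({8}))
        with pytest.raises(FoldingError, match="reused"):
            FoldConstraint(fixed_pairs=((0, 8), (8, 12)))

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_bruteforce(self, seed):
        """Optimal pair count equals exhaustive enumeration for n <= 14."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        seq = random_sequence(rng, n)
        forbidden = frozenset(
            int(p) for p in rng.choice(n, size=int(rng.integers(0, n // 3 + 1)), replace=False)
        )
        got = fold_max_pairs(seq, FoldConstraint(forbidden=forbidden))
        assert len(got.pairs) == max_pairs_bruteforce(seq, forbidden)

    @pytest.mark.parametrize("seed", range(15))
    def test_monotone_in_forbidden_set(self, seed):
        """Enlarging the mask never increases the optimum."""
        rng = np.random.default_rng(100 + seed)
        seq = random_sequence(rng, 20)
        masked = set()
        prev = len(fold_max_pairs(seq).pairs)
        for p in rng.permutation(20)[:8]:
            masked.add(int(p))
            now = len(fold_max_pairs(seq, FoldConstraint(forbidden=frozenset(masked))).pairs)
            assert now <= prev
            prev = now

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 30)
        assert fold_max_pairs(seq).pairs == fold_max_pairs(seq).pairs


def _aln_with_insertion(m, after, count):
    posmap = np.concatenate([np.arange(after + 1), np.full(count, -1), np.arange(after + 1, m)])
    revmap = np.concatenate([np.arange(after + 1), np.arange(after + 1, m) + count])
    ops = ((("M", after + 1)), ("I", count), ("M", m - after - 1))
    return AlignmentResult(ops, 0, posmap, revmap)


class TestFoldLocal:
    def test_no_insertions_unchanged(self, library):
        t = library.templates["tmpl_5s"]
        aln = AlignmentResult.identity(len(t))
        qs = transfer_structure(t, aln)
        assert fold_local(t.sequence, qs, aln) is qs

    def test_short_insertion_stays_unfolded(self):
        qs = SecondaryStructure(9, ())
        aln = _aln_with_insertion(4, 1, 5)
        out = fold_local("A" * 9, qs, aln)
        assert out.pairs == ()

    def test_insertion_folds_within_run_only(self):
        m = 10
        count = 8
        aln = _aln_with_insertion(m, 4, count)
        seq = "A" * 5 + "GGGAAACC" + "A" * 5
        qs = SecondaryStructure(m + count, ())
        out = fold_local(seq, qs, aln)
        assert out.pairs != ()
        for i, j in out.predicted:
            assert 5 <= i < 13 and 5 <= j < 13

    def test_two_insertions_fold_independently(self):
        m = 12
        posmap = np.concatenate(
            [np.arange(4), np.full(6, -1), np.arange(4, 8), np.full(6, -1), np.arange(8, 12)]
        )
        revmap = np.array([0, 1, 2, 3, 10, 11, 12, 13, 20, 21, 22, 23])
        ops = (("M", 4), ("I", 6), ("M", 4), ("I", 6), ("M", 4))
        aln = AlignmentResult(ops, 0, posmap, revmap)
        seq = "AAAA" + "GGAACC" + "AAAA" + "GCAAGC" + "AAAA"
        qs = SecondaryStructure(24, ())
        out = fold_local(seq, qs, aln)
        runs = inserted_runs(aln)
        assert runs == [(4, 10), (14, 20)]
        for i, j in out.predicted:
            assert any(lo <= i and j < hi for lo, hi in runs)


class TestFoldGlobal:
    def test_already_maximal_adds_nothing(self):
        seq = "GGGAAACCC"
        qs = fold_max_pairs(seq)
        out = fold_global(seq, SecondaryStructure(9, qs.pairs))
        assert out.predicted == frozenset()

    def test_empty_constraint_equals_unconstrained(self):
        rng = np.random.default_rng(8)
        seq = random_sequence(rng, 25)
        free = fold_max_pairs(seq)
        out = fold_global(seq, SecondaryStructure(25, ()))
        assert len(out.pairs) == len(free.pairs)

    def test_template_pairs_always_present(self, library):
        t = library.templates["tmpl_5s"]
        aln = AlignmentResult.identity(len(t))
        qs = transfer_structure(t, aln)
        out = fold_global(t.sequence, qs)
        assert set(qs.pairs) <= set(out.pairs)
        assert out.predicted == frozenset(
            (i, j) for i, j, _ in set(out.pairs) - set(qs.pairs)
        )


class TestFoldGlobalMasked:
    def test_full_mask_no_pairs(self):
        out = fold_global_masked("GGGAAACCC", SecondaryStructure(9, ()), frozenset(range(9)))
        assert out.pairs == ()

    def test_default_mask_limits_new_pairs(self, library):
        t = library.templates["tmpl_5s"]
        aln = AlignmentResult.identity(len(t))
        qs = transfer_structure(t, aln)
        mask = build_default_mask(aln, t)
        t_partner = t.structure.partner
        assert mask == frozenset(p for p in range(len(t)) if t_partner[p] < 0)
        out = fold_global_masked(t.sequence, qs, mask)
        paired_in_template = {p for p in range(len(t)) if t_partner[p] >= 0}
        for i, j in out.predicted:
            assert i in paired_in_template and j in paired_in_template

    def test_insertion_may_pair_while_masked_may_not(self, library):
        t = library.templates["tmpl_5s"]
        aln = _aln_with_insertion(len(t), 30, 6)
        seq = t.sequence[:31] + "GGGCCC"[:6] + t.sequence[31:]
        qs = transfer_structure(t, aln)
        mask = build_default_mask(aln, t)
        out = fold_global_masked(seq, qs, mask)
        for i, j in out.predicted:
            assert i not in mask and j not in mask

    def test_mask_conflicting_with_fixed_pair(self):
        seq = "GGGAAACCC"
        qs = fold_max_pairs(seq)
        with pytest.raises(FoldingError, match="mask forbids"):
            fold_global_masked(seq, SecondaryStructure(9, qs.pairs), frozenset({0}))
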
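"""Radial layout geometry, overlap counting, layout choice, template export."""

import numpy as np
import pytest

from helpers import count_overlaps_bruteforce, random_nested_structure
from rna2d.align import AlignmentResult, transfer_structure
from rna2d.denovo import choose_layout, count_overlaps, layout_radial, make_template
from rna2d.geometry import BASE_SPACING, PAIR_DISTANCE
from rna2d.layout import Layout, LayoutError, layout_from_template
from rna2d.structure import SecondaryStructure, parse_dotbracket
from rna2d.templates import TemplateError


class TestRadial:
    def test_hairpin_geometry(self):
        seq = "GGGGAAAACCCC"
        st = parse_dotbracket("((((....))))")
        lo = layout_radial(seq, st)
        for i, j, _ in st.pairs:
            assert np.hypot(*(lo.coords[i] - lo.coords[j])) == pytest.approx(
                PAIR_DISTANCE, abs=1e-9
            )
        # loop nucleotides equidistant on the circle
        chords = [np.hypot(*(lo.coords[k + 1] - lo.coords[k])) for k in range(4, 7)]
        assert np.allclose(chords, chords[0], rtol=1e-9)
        # helix rungs rise uniformly
        for k in range(3):
            assert np.hypot(*(lo.coords[k + 1] - lo.coords[k])) == pytest.approx(
                BASE_SPACING, abs=1e-9
            )

    def test_unpaired_sequence_collinear(self):
        lo = layout_radial("A" * 10, SecondaryStructure(10, ()))
        assert np.allclose(lo.coords[:, 1], 0.0)
        assert np.allclose(np.diff(lo.coords[:, 0]), BASE_SPACING)

    def test_deterministic(self):
        seq = "GGGGAAAACCCCAAA" * 3
        st = parse_dotbracket("((((....))))..." * 3)
        a = layout_radial(seq, st)
        b = layout_radial(seq, st)
        assert np.array_equal(a.coords, b.coords)

    def test_flip_mirrors_branch_side(self):
        seq = "GGGGAAAACCCC"
        st = parse_dotbracket("((((....))))")
        up = layout_radial(seq, st)
        down = layout_radial(seq, st, flip=True)
        assert np.allclose(up.coords[:, 0], down.coords[:, 0])
        assert np.allclose(up.coords[:, 1], -down.coords[:, 1])

    @pytest.mark.parametrize("seed", range(8))
    def test_random_structures_valid(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        st = random_nested_structure(rng, n)
        seq = "".join("ACGU"[int(k)] for k in rng.integers(0, 4, n))
        lo = layout_radial(seq, st)
        lo.validate()
        assert np.all(np.isfinite(lo.coords))

    def test_length_mismatch(self):
        with pytest.raises(LayoutError):
            layout_radial("ACGU", SecondaryStructure(5, ()))

    def test_pure_hairpins_never_overlap(self):
        for stem, loop in [(3, 4), (6, 5), (10, 8), (2, 12)]:
            db = "(" * stem + "." * loop + ")" * stem
            seq = "G" * stem + "A" * loop + "C" * stem
            st = parse_dotbracket(db)
            assert count_overlaps(layout_radial(seq, st), st) == 0


class TestCountOverlaps:
    def test_constructed_crossing(self):
        # backbone segment 1-2 crosses the (0,3) pair connector
        st = SecondaryStructure(4, ((0, 3, 0),))
        coords = np.array([[0.0, 0.0], [4.0, -5.0], [4.0, 5.0], [8.0, 0.0]])
        assert count_overlaps(Layout(coords, ("rearranged",) * 4), st) == 1

    def test_straight_polyline_no_overlap(self):
        st = SecondaryStructure(6, ())
        coords = np.column_stack([np.arange(6) * 8.0, np.zeros(6)])
        assert count_overlaps(Layout(coords, ("rearranged",) * 6), st) == 0

    def test_clash_counted(self):
        st = SecondaryStructure(4, ())
        coords = np.array([[0.0, 0.0], [8.0, 0.0], [16.0, 0.0], [1.0, 1.0]])
        # nt 3 sits closer than 4 units to nt 0 and is not its neighbour
        assert count_overlaps(Layout(coords, ("rearranged",) * 4), st) == 1

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        st = random_nested_structure(rng, n)
        coords = rng.uniform(0, 40, size=(n, 2))
        lo = Layout(coords, ("rearranged",) * n)
        assert count_overlaps(lo, st) == count_overlaps_bruteforce(coords, st)


class TestChooseLayout:
    def _candidates(self):
        st = SecondaryStructure(4, ((0, 3, 0),))
        crossing = Layout(
            np.array([[0.0, 0.0], [4.0, -5.0], [4.0, 5.0], [8.0, 0.0]]),
            ("rearranged",) * 4,
        )
        square = Layout(
            np.array([[0.0, 0.0], [8.0, 0.0], [8.0, 8.0], [0.0, 8.0]]),
            ("rearranged",) * 4,
        )
        return st, [("a", crossing), ("b", square)]

    def test_minimal_overlap_wins(self):
        st, cands = self._candidates()
        assert choose_layout(cands, st)[0] == "b"

    def test_forced_bypasses_counting(self):
        st, cands = self._candidates()
        assert choose_layout(cands, st, forced="a")[0] == "a"

    def test_tie_keeps_input_order(self):
        st, cands = self._candidates()
        tied = [("x", cands[1][1]), ("y", cands[1][1])]  # identical counts
        assert choose_layout(tied, st)[0] == "x"

    def test_empty_and_unknown_forced(self):
        st, cands = self._candidates()
        with pytest.raises(LayoutError, match="no layout"):
            choose_layout([], st)
        with pytest.raises(LayoutError, match="forced"):
            choose_layout(cands, st, forced="zzz")


class TestMakeTemplate:
    def test_roundtrip_identity_layout(self):
        seq = "GGGGAAAACCCC"
        st = parse_dotbracket("((((....))))")
        lo = layout_radial(seq, st)
        t = make_template("hp", seq, st, lo)
        assert t.category == "family"
        again = layout_from_template(seq, st, t, AlignmentResult.identity(12))
        assert np.array_equal(again.coords, lo.coords)

    def test_substitutions_do_not_move_nucleotides(self):
        seq = "GGGGAAAACCCC"
        st = parse_dotbracket("((((....))))")
        t = make_template("hp", seq, st, layout_radial(seq, st))
        mutated = "GGGGAUAACCCC"  # 1 loop substitution keeps pairing valid
        lo = layout_from_template(mutated, st, t, AlignmentResult.identity(12))
        assert np.array_equal(lo.coords, t.coords)

    def test_insertion_rearranges_only_its_loop(self):
        seq = "GGGGAAAACCCC"
        st = parse_dotbracket("((((....))))")
        t = make_template("hp", seq, st, layout_radial(seq, st))
        posmap = np.array([0, 1, 2, 3, 4, 5, -1, 6, 7, 8, 9, 10, 11])
        revmap = np.array([0, 1, 2, 3, 4, 5, 7, 8, 9, 10, 11, 12])
        aln = AlignmentResult((("M", 6), ("I", 1), ("M", 6)), 0, posmap, revmap)
        qseq = seq[:6] + "A" + seq[6:]
        qs = transfer_structure(t, aln)
        lo = layout_from_template(qseq, qs, t, aln)
        for q, tpos in enumerate(posmap):
            if tpos in (0, 1, 2, 3, 8, 9, 10, 11):
                assert np.array_equal(lo.coords[q], t.coords[tpos])

    def test_library_write_and_collision(self, tmp_path):
        seq = "GGGGAAAACCCC"
        st = parse_dotbracket("((((....))))")
        lo = layout_radial(seq, st)
        make_template("hp", seq, st, lo, library=tmp_path)
        with pytest.raises(TemplateError, match="already exists"):
            make_template("hp", seq, st, lo, library=tmp_path)
        make_template("hp", seq, st, lo, library=tmp_path, overwrite=True)
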
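"""Structure tree decomposition and template-based coordinate inheritance."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from helpers import random_nested_structure
from rna2d.align import AlignmentResult, transfer_structure
from rna2d.denovo import layout_radial, make_template
from rna2d.fixtures import loop_indel_query, make_toy_templates, mutate_query
from rna2d.geometry import BASE_SPACING, PAIR_DISTANCE
from rna2d.layout import (
    INHERITED,
    INSERTED,
    LayoutError,
    layout_from_template,
    place_unfolded_insertion,
    transfer_labels,
)
from rna2d.structure import parse_dotbracket
from rna2d.tree import LoopKind, build_tree


class TestBuildTree:
    def test_single_hairpin(self):
        tree = build_tree(parse_dotbracket("(((...)))"))
        assert len(tree.helices) == 1
        assert tree.helices[0].pairs == [(0, 8), (1, 7), (2, 6)]
        inner = tree.helices[0].loop
        assert inner.kind is LoopKind.HAIRPIN
        assert inner.nt_positions == [3, 4, 5]
        assert tree.root.kind is LoopKind.EXTERIOR

    def test_internal_loop(self):
        tree = build_tree(parse_dotbracket("((..((...))..))"))
        assert len(tree.helices) == 2
        kinds = sorted(lp.kind.value for lp in tree.loops if lp.closing)
        assert kinds == ["hairpin", "internal"]

    def test_multibranch(self):
        tree = build_tree(parse_dotbracket("((.((...)).((...)).))"))
        outer_loop = tree.helices[0].loop
        assert outer_loop.kind is LoopKind.MULTIBRANCH
        assert len(outer_loop.children) == 2

    @pytest.mark.parametrize("seed", range(25))
    def test_elements_partition_positions(self, seed):
        """Helix and loop position sets partition 0..n-1 exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        s = random_nested_structure(rng, n)
        tree = build_tree(s)
        owner = tree.element_of()
        assert sorted(owner) == list(range(n))
        all_positions = [p for h in tree.helices for p in h.positions]
        all_positions += [p for lp in tree.loops for p in lp.nt_positions]
        assert sorted(all_positions) == list(range(n))


def _hairpin_template():
    seq = "GGGGAAAACCCC"
    st = parse_dotbracket("((((....))))")
    return make_template("hp", seq, st, layout_radial(seq, st))


def _aln_delete(m, pos):
    """Identity alignment on m template positions minus a deletion at pos."""
    posmap = np.array([t for t in range(m) if t != pos])
    revmap = np.full(m, -1)
    for q, t in enumerate(posmap):
        revmap[t] = q
    ops = [("M", pos), ("D", 1), ("M", m - pos - 1)]
    return AlignmentResult(tuple((o, c) for o, c in ops if c), 0, posmap, revmap)


def _aln_insert(m, after, count):
    """Identity alignment plus `count` query-only positions after template pos."""
    posmap = np.concatenate([np.arange(after + 1), np.full(count, -1), np.arange(after + 1, m)])
    revmap = np.concatenate([np.arange(after + 1), np.arange(after + 1, m) + count])
    ops = [("M", after + 1), ("I", count), ("M", m - after - 1)]
    return AlignmentResult(tuple(ops), 0, posmap, revmap)


def _circumcentre(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    return np.array([ux, uy])


class TestTemplateLayout:
    def test_identity_is_exact(self, library):
        for t in library.templates.values():
            aln = AlignmentResult.identity(len(t))
            lo = layout_from_template(t.sequence, t.structure, t, aln)
            assert np.array_equal(lo.coords, t.coords)
            assert set(lo.provenance) == {INHERITED}

    def test_hairpin_deletion_recomputes_loop_circle(self):
        t = _hairpin_template()
        aln = _aln_delete(12, 5)  # drop one loop nucleotide
        qs = transfer_structure(t, aln)
        lo = layout_from_template(t.sequence[:5] + t.sequence[6:], qs, t, aln)
        # helix coordinates stay bit-identical
        for q, tpos in enumerate(aln.posmap):
            if tpos in (0, 1, 2, 3, 8, 9, 10, 11):
                assert np.array_equal(lo.coords[q], t.coords[tpos])
        # remaining 3 loop nts on the circumference-rule circle through anchors
        q5, q3 = t.coords[3], t.coords[8]
        loop_pts = lo.coords[4:7]
        r_expected = max(5 * BASE_SPACING / (2 * math.pi), PAIR_DISTANCE / 2)
        centre = _circumcentre(loop_pts[0], loop_pts[1], loop_pts[2])
        for p in (q5, q3, *loop_pts):
            assert np.hypot(*(p - centre)) == pytest.approx(r_expected, abs=1e-9)
        # consecutive members equidistant
        chords = [np.hypot(*(loop_pts[k + 1] - loop_pts[k])) for k in range(2)]
        assert chords[0] == pytest.approx(chords[1], rel=1e-9)

    def test_hairpin_insertion_grows_loop_circle(self):
        t = _hairpin_template()
        aln = _aln_insert(12, 5, 4)  # 4 extra loop nucleotides
        qseq = t.sequence[:6] + "AAAA" + t.sequence[6:]
        qs = transfer_structure(t, aln)
        lo = layout_from_template(qseq, qs, t, aln)
        for q, tpos in enumerate(aln.posmap):
            if tpos in (0, 1, 2, 3, 8, 9, 10, 11):
                assert np.array_equal(lo.coords[q], t.coords[tpos])
        loop_idx = list(range(4, 12))
        pts = lo.coords[loop_idx]
        centre = _circumcentre(pts[0], pts[3], pts[7])
        r_expected = 10 * BASE_SPACING / (2 * math.pi)  # cycle of 8 members + 2
        for p in pts:
            assert np.hypot(*(p - centre)) == pytest.approx(r_expected, abs=1e-9)
        assert [lo.provenance[k] for k in range(6, 10)] == [INSERTED] * 4
        # grew relative to the template's own loop radius (cycle size 6)
        assert r_expected > 6 * BASE_SPACING / (2 * math.pi)

    def test_length_mismatch_rejected(self, library):
        t = library.templates["tmpl_5s"]
        aln = AlignmentResult.identity(len(t))
        with pytest.raises(LayoutError):
            layout_from_template(t.sequence + "A", t.structure, t, aln)

    @pytest.mark.parametrize("seed", range(30))
    def test_single_indel_moves_only_the_edited_loop(self, library, seed):
        """Positions outside the edited loop keep template coordinates exactly."""
        ids = ("tmpl_trna", "tmpl_5s", "tmpl_long")
        t = library.templates[ids[seed % 3]]
        rec, truth, pos = loop_indel_query(t, seed)
        qs = transfer_structure(t, truth)
        lo = layout_from_template(rec.sequence, qs, t, truth)
        lo.validate()
        ttree = build_tree(t.structure)
        edited_loop = next(lp for lp in ttree.loops if pos in lp.nt_positions)
        allowed = set(edited_loop.nt_positions)
        for q in range(len(rec.sequence)):
            tpos = int(truth.posmap[q])
            if tpos < 0:
                continue
            if not np.array_equal(lo.coords[q], t.coords[tpos]):
                assert tpos in allowed, f"position {tpos} moved outside the edited loop"

    @pytest.mark.parametrize("seed", [3, 11, 19])
    def test_no_clashes_on_mutated_fixtures(self, library, seed):
        t = library.templates["tmpl_5s"]
        rec, truth = mutate_query(t, 0.03, 0.02, 0.02, seed=seed)
        qs = transfer_structure(t, truth)
        lo = layout_from_template(rec.sequence, qs, t, truth)
        d = np.hypot(
            *(lo.coords[:, None, :] - lo.coords[None, :, :]).transpose(2, 0, 1)
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 0.25 * BASE_SPACING


class TestUnfoldedInsertion:
    def test_single_point_sagitta_closed_form(self):
        (pt,) = place_unfolded_insertion((0.0, 0.0), (8.0, 0.0), 1)
        # arc of length 2s over chord 8: solve sin(a)/a = 0.5 independently
        alpha = brentq(lambda a: math.sin(a) / a - 8.0 / 16.0, 1e-9, math.pi - 1e-9)
        radius = 16.0 / (2 * alpha)
        sagitta = radius * (1 - math.cos(alpha))
        assert pt[0] == pytest.approx(4.0, abs=1e-9)
        assert abs(pt[1]) == pytest.approx(sagitta, abs=1e-6)

    def test_three_points_symmetric(self):
        pts = place_unfolded_insertion((0.0, 0.0), (8.0, 0.0), 3)
        assert pts[1][0] == pytest.approx(4.0, abs=1e-9)
        assert pts[0][0] + pts[2][0] == pytest.approx(8.0, abs=1e-9)
        # uniform spacing along the arc, endpoints included
        chain = np.vstack([[0, 0], pts, [8, 0]])
        steps = np.hypot(*np.diff(chain, axis=0).T)
        assert np.allclose(steps, steps[0], rtol=1e-9)

    def test_zero_count_rejected(self):
        with pytest.raises(LayoutError, match=">= 1"):
            place_unfolded_insertion((0.0, 0.0), (8.0, 0.0), 0)

    def test_coincident_flanks_fall_back_to_semicircle(self, caplog):
        pts = place_unfolded_insertion((5.0, 5.0), (5.0, 5.0), 4)
        radius = BASE_SPACING * 5 / math.pi
        for p in pts:
            assert np.hypot(*(p - np.array([5.0, 5.0]))) == pytest.approx(radius, abs=1e-9)


class TestTransferLabels:
    def test_identity_with_suppression(self, library):
        t = library.templates["tmpl_trna"]
        labels = transfer_labels(t, AlignmentResult.identity(len(t)), suppress={"13", "26"})
        assert labels[12] is None and labels[25] is None
        assert labels[0] == "1" and labels[75] == "76"
        assert sum(1 for v in labels if v is None) == 2

    def test_all_inserted_positions_unlabelled(self, library):
        t = library.templates["tmpl_trna"]
        posmap = np.full(5, -1)
        revmap = np.full(len(t), -1)
        aln = AlignmentResult((("I", 5), ("D", len(t))), 0, posmap, revmap)
        assert transfer_labels(t, aln) == (None,) * 5

    def test_deleted_position_label_absent(self, library):
        t = library.templates["tmpl_trna"]
        aln = _aln_delete(len(t), 12)  # delete Sprinzl position "13"
        labels = transfer_labels(t, aln)
        assert "13" not in labels
        assert labels[12] == "14"
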
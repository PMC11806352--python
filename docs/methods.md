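# Methods

This note documents the models and numerical choices behind `rna2d`:
what each stage computes, which parameters matter, what the synthetic
fixtures do and do not emulate, and where the design was genuinely open.

## Coordinate model

All drawing happens in abstract units with y increasing downward (screen
convention).  The metric is uniform and fixed in `rna2d.geometry`:

| constant | value | meaning |
|---|---|---|
| `BASE_SPACING` | 8 | target distance between backbone neighbours |
| `PAIR_DISTANCE` | 8 | distance between paired partners |
| `HELIX_RISE` | 8 | rise per stacked pair along a helix |

The absolute scale is arbitrary in SVG; a uniform metric keeps the
geometry amenable to closed-form checks (loop radii, chord lengths,
sagittas) that the test suite exploits.

## Structure model

A secondary structure is a set of base pairs partitioned into *pages*:
page 0 is the nested (non-crossing) skeleton, pages >= 1 hold
pseudoknotted pairs.  Dot-bracket text encodes page k with the k-th
bracket family in the fixed order `()`, `[]`, `{}`, `<>`, `Aa`..`Zz`.
Bare pair lists are paged by first-fit: pairs in order of increasing i
(ties by decreasing j) land on the lowest page where they cross nothing.
First-fit is *not* a global minimum over all pagings -- 5-pair
counterexamples exist -- but it is deterministic, stable, and minimal
for the small knot counts that occur in practice (it is provably minimal
for up to 3 pairs, which the tests verify by exhaustion).

Only page-0 pairs influence geometry.  Pseudoknot pairs are drawn as a
separate connector class; any number of pages is supported up to the 30
available bracket families.

## Template selection

Stages run in the order `long` -> `family` -> `trna` (configurable).
Within a stage:

1. **Seed filter.**  Exact shared k-mers between query and template vote
   in diagonal bands of width 2k (band index `(qpos - tpos) // 2k`), so
   co-linear seeds reinforce each other while scattered chance matches do
   not.  Defaults: k = 12 for `long` templates, k = 8 otherwise,
   `min_seeds` = 2.  k-mers containing N are skipped.
2. **Alignment.**  Candidates (up to 3) are aligned with a semi-global
   affine-gap (Gotoh) DP: match +2, mismatch -1 (N matches nothing), a
   gap of length L costs -(5 + L).  End gaps on the **template** are
   free, so a fragment maps into the interior of a long template without
   penalty; the query itself is always fully aligned.  Traceback is
   deterministic (ties: Match, then Delete, then Insert; rightmost end
   column).  The DP inner loops are compiled with numba.
3. **Acceptance.**  The best candidate is kept if its normalized score
   `score / (2 |query|)` reaches tau = 0.5 (an exact full-length match
   scores exactly 1.0).  Otherwise the query falls through to the next
   stage; a query never matches more than one template.  Naming a
   template id bypasses selection entirely.

tau, k and `min_seeds` are package constants chosen for the synthetic
fixture regime (about 5% substitutions and 2% indels), not calibrated
against any external tool.  Covariance-model alignment is out of scope;
the consequence is that the query's structure comes from transferring
template pairs through the alignment (pairs with a deleted partner are
dropped, inserted positions stay unpaired, pages are preserved).

## Template-based layout

The query structure is decomposed into maximal helices and loops; each
query element is compared with its template counterpart through the
alignment:

* **Clean elements** (same composition, all positions matched) copy
  template coordinates **bit-identically**.  This is the core promise:
  drawing a template's own sequence reproduces the template exactly, and
  a single edit leaves every untouched element unmoved.
* **Dirty loops** are rearranged.  The closing-pair anchors and the
  anchors of every child helix that still maps to the template stay
  fixed; unpaired members are redistributed along the circle fitted
  through those anchors (least-squares fit; arc gaps keep their original
  angular spans, so spacing changes only inside the gap that gained or
  lost members).  A loop with no mapped children (hairpins, or loops
  whose children are all new) gets a fresh circle through its closing
  pair with the circumference rule `radius = cycle * 8 / 2pi`, centre on
  the chord's perpendicular bisector on the side of the original loop
  centroid.  The radius is clamped to at least half the anchor chord so
  the circle always exists, even for loops shrunk below the usual
  minimum.
* **Dirty helices** re-ladder along the template helix axis: mapped
  rungs keep their template coordinates, gained or lost rungs are
  extrapolated from the nearest mapped rung at 8 units per pair.
* **Novel helices** (typically folded insertions) have no template
  reference: their outer pair is given a chord on the enclosing loop's
  circle and the whole subtree is drawn radially outward from there.
* The **exterior loop** is handled on a line: mapped child anchors stay
  put, runs of unpaired positions between anchors are placed on a
  circular arc of length `(m + 1) * 8` bulging away from the helices
  (degrading to uniform placement on the segment when the anchors are
  too far apart), and leading/trailing runs extend along the line.

Neighbouring elements are never shifted to make room.  A large insertion
can therefore overlap its surroundings; overlaps are *counted*
(`count_overlaps`: crossing drawn segments, plus non-neighbour,
non-partner nucleotides closer than 4 units) and reported, not resolved.
Per-position provenance flags (`inherited` / `rearranged` / `inserted`)
record exactly which rule placed each nucleotide.

## Template-free layout

The radial engine draws the exterior loop left to right on a horizontal
line with helices branching upward (y negative); each loop is a circle
sized by the circumference rule, with every pair chord (closing pair and
child helices) subtending exactly `2 asin(4 / r)` so partners are always
exactly 8 units apart, and the leftover angle split evenly among the
gaps -- unpaired neighbours on one loop are equidistant.  The layout is
a pure function of the input.  A mirrored variant (helices branching
down) provides a second candidate; `choose_layout` keeps whichever has
fewer overlaps, with ties resolved by input order and a `forced` name
bypassing the count.  "Overlap" here is this package's own quantitative
definition (crossings + clashes as above).

Any layout can be frozen into a template (`make_template`, category
`family`); re-drawing the same sequence on it with the identity
alignment reproduces the coordinates exactly, so substitution-only
variants render in precisely the original shape.

## Constrained folding

`fold_max_pairs` is a Nussinov-style interval DP maximizing pair count
over {AU, UA, GC, CG, GU, UG} with the hairpin rule j - i > 3.
Constraints: required pairs (enforced by giving them a weight larger
than any attainable number of ordinary pairs, so every optimum retains
them; infeasible required pairs -- wrong alphabet or span -- error
before the DP), forbidden positions, and an optional half-open region
confining *new* pairs.  The traceback is deterministic: prefer pairing i
with the smallest admissible j, bifurcate at the smallest k.  Energy
models, partition functions and pseudoknotted predictions are explicit
non-goals; predicted pairs are always nested, flagged, and drawn dashed.

Pipeline modes:

* **local** -- each maximal inserted run of >= 6 nt is folded on its own
  (region = the run, everything else forbidden).  Six is this package's
  constant: the hairpin rule makes runs under 5 unfoldable anyway, and 6
  leaves a margin.  Shorter insertions stay unfolded loops.
* **global** -- the whole molecule is refolded with the transferred
  page-0 pairs required.  Transferred pairs whose bases have mutated
  apart (or whose span shrank below the hairpin limit) cannot be
  enforced by the DP; they remain in the drawing and their positions are
  simply barred from re-pairing.
* **global-masked** -- as global with a forbidden set; the default mask
  is exactly the query positions aligned to template positions that are
  unpaired in the template.

## Rendering and the regression harness

SVG output is deterministic: fixed element order, stable id scheme,
2-decimal coordinate formatting, so byte-level diffs are meaningful.
Data layers paint filled circles behind the nucleotides.  The
alignment-confidence palette uses bin edges {0, 0.8, 0.85, 0.9, 0.95}
with four Okabe-Ito colours below 0.95 and *no* highlight in
[0.95, 1.0]; only the top edge of that rule is externally fixed, the
lower edges and colours are package constants.  Non-canonical pairs draw
Leontis-Westhof edge glyphs at both ends (circle / square / triangle for
the Watson-Crick / Hoogsteen / Sugar edge; cis filled, trans open);
canonical cWW pairs are plain lines.  Animated morphs embed declarative
per-element animation (no scripting), linearly interpolating each
nucleotide from layout A at t = 0 to layout B at t = duration, looping
indefinitely; both layouts must have the same length.

The regression harness paints the renderer's SVG subset onto a fixed
512x512 canvas with simple primitives (line strips, ellipses, rects,
polygons).  Text paints as a small fixed-size ink box at its anchor: the
harness deliberately abstracts typography (font-metric fidelity is a
non-goal), so changing only the font size leaves the raster unchanged
and passes the gate, while geometric changes do not.  Comparison is a
*single-window* SSIM on luma (0.299 R + 0.587 G + 0.114 B) with the
standard constants C1 = (0.01 * 255)^2, C2 = (0.03 * 255)^2, plus the
per-channel mean absolute difference; one global window keeps the
statistic deterministic and closed-form checkable.  The gate passes at
SSIM >= 0.99 and max channel difference <= 2/255 -- package constants:
identical drawings score exactly 1.0, a 20-unit translation of a
120-nt diagram scores about 0.03, far below the threshold.

## Synthetic fixtures

`make_toy_templates(seed)` builds a deterministic four-template library:
a 76-nt cloverleaf (7-bp acceptor-like stem, three hairpin arms around a
multibranch loop, numbering labels "1".."76", category `trna`), a 120-nt
three-helix molecule (category `family`), a 300-nt multi-stem molecule
(category `long`), and a 14-nt pseudoknotted hairpin with one page-1
pair.  Stems are complementarity-consistent (GC-rich), loops random;
coordinates come from the radial engine and are frozen to disk.  All
randomness uses numpy's PCG64 generator, so the same seed produces
byte-identical fixture files on any platform.

`mutate_query` plants independent per-position substitutions and
single-nucleotide indels and returns the true edit script, so selection
and layout accuracy can be scored against ground truth.
`loop_indel_query` plants exactly one indel at an *unpaired loop*
position -- the regime in which "the edited loop" is well defined, since
deleting a paired nucleotide necessarily changes both a helix and its
neighbouring loop.

What the fixtures do **not** emulate: real covariation, modified
nucleotides, biological sequence composition, realistic indel length
distributions, or the scale of real template libraries (thousands of
entries).  Passing the suite therefore demonstrates the correctness of
the algorithms and their contracts, not recovery rates on real RNA
families.

Problem sizes throughout (200 folding oracles at n <= 14, 200 selection
queries, 100 locality queries, 500 overlap cases) were chosen as the
smallest sets at which the stochastic checks are stable across seeds.

## Known limitations

* Sequence alignment stands in for covariance-model alignment, so remote
  homologs that only a profile model would find are missed; the 14-nt
  pseudoknot fixture is at the edge of what k-mer seeding can recover
  under mutation.
* Large insertions can overlap neighbouring elements (reported, not
  resolved); there is no force-directed or intersection-free refinement.
* The folding model counts pairs, not energies.
* The rasterizer handles exactly the primitives the renderer emits; it
  is not a general SVG consumer.
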
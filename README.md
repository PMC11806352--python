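# rna2d

Consistent, reproducible RNA secondary-structure diagrams.

RNA 2D diagrams are most useful when related molecules are drawn the same
way: a biologist comparing two tRNAs, or a mutated 5S rRNA against a
reference, wants corresponding nucleotides in corresponding places.
`rna2d` achieves this with **coordinate templates**: a template stores a
reference sequence, its secondary structure, and an (x, y) position for
every nucleotide.  A query sequence is matched to the best template by a
staged k-mer filter plus affine-gap alignment, inherits the template's
structure and coordinates, and only the elements actually touched by
insertions or deletions are locally rearranged -- everything else stays
bit-identical to the template drawing.

The package is a desk-scale engine for this idea, aimed at
bioinformaticians who need deterministic, scriptable structure drawings:

* **Template-based layout** with dynamic rearrangement: loops that gain or
  lose nucleotides are redistributed on their loop circle, helices that
  gain or lose pairs are re-laddered along the template helix axis.
* **Template-free (radial) layout** for sequences that carry their own
  dot-bracket structure, and conversion of any layout into a reusable
  template.
* **Constrained folding** of regions the template does not cover, by a
  Nussinov-style maximum-base-pair dynamic program: local (fold each
  insertion), global (refold everything with template pairs fixed), and
  global with an exclusion mask.
* **Pseudoknots**: dot-bracket input may use extra bracket families
  (`[]`, `{}`, `<>`, `Aa`..`Zz`); crossing pairs are carried through
  alignment transfer and drawn as a distinct connector class, never used
  for geometry.
* **Data layers**: per-nucleotide numeric or textual annotations mapped to
  colours, including the alignment-confidence palette in which
  probabilities in [0.95, 1.0] are deliberately *not* highlighted.
* **Leontis-Westhof glyphs** for non-canonical pairs (circle = Watson-Crick
  edge, square = Hoogsteen, triangle = Sugar; cis filled, trans open).
* An **interchange JSON document** carrying molecules, residues with
  coordinates, LW-annotated base pairs and styling classes
  (`docs/rna2d-schema.json` freezes the dialect).
* **Animated SVG morphs** between two drawings of the same molecule.
* An **image-regression harness**: SVGs are painted onto a fixed 512x512
  canvas and compared by a single-window structural similarity index
  (SSIM) plus per-channel mean absolute difference.

## The core computations

**Selection.**  Templates are grouped in stages (`long`, then `family`,
then `trna`).  Within a stage, shared k-mers vote in diagonal bands of
width 2k; candidates with a band score >= 2 are aligned with a
semi-global Gotoh DP (match +2, mismatch -1, gap open -5, gap extend -1,
template overhangs free) and the best hit is accepted when
score / (2 |query|) >= 0.5.  A query matches at most one template.

**Folding.**  `fold_max_pairs` maximizes the number of base pairs over
{AU, UA, GC, CG, GU, UG} with hairpin rule j - i > 3, subject to required
pairs, forbidden positions and an optional region, with a deterministic
traceback.  It is a pair-counting model, not a thermodynamic one.

**Layout.**  A structure decomposes into helices (runs of stacked pairs)
and loops.  Loops are circles sized by the circumference rule
`(cycle size) x BASE_SPACING`; paired partners sit exactly 8 units apart;
helices ladder at 8 units per pair; y grows downward.

## Worked example

```bash
rna2d fixtures --seed 1 --out library --queries 2
rna2d draw library/queries.fasta --library library --out diagrams
```

prints one structured log line per record:

```
INFO rna2d.pipeline: record=tmpl_5s_mut100003 template=tmpl_5s score=0.817 fold_mode=off overlaps=0
INFO rna2d.pipeline: record=tmpl_long_mut100004 template=tmpl_long score=0.783 fold_mode=off overlaps=0
```

Each mutated query was matched back to the template it was generated
from; `score` is the normalized alignment score (1.0 would be a perfect
full-length match, 0.5 is the acceptance threshold) and `overlaps=0`
says the rearranged drawing has no crossing segments or clashing
nucleotides.  For every record three files appear in `diagrams/`: the
full diagram (`<id>.svg`), a simplified thumbnail with one continuous
line through all nucleotides (`<id>.thumb.svg`), and the interchange
document (`<id>.json`).

Folding the classic toy hairpin:

```bash
$ printf '>hairpin\nGGGAAACCC\n' > hairpin.fasta && rna2d fold hairpin.fasta
>hairpin
GGGAAACCC
(((...)))
```

Three pairs -- (0,8), (1,7), (2,6) -- which is the maximum the hairpin
rule j - i > 3 admits for this sequence.

Records that carry their own structure line take the template-free path;
`--save-template` freezes the resulting layout into the library so later
sequences can be drawn in the same shape.  Other commands: `select`
(report the chosen template per query), `compare` (regression-gate two
SVGs), `animate` (morph two documents), `template-from-structure`,
`fixtures`.

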
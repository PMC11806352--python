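"""End-to-end drawing pipeline: records in, diagrams out.

Two main steps per record: template selection and diagram generation.
Records carrying their own structure line take the template-free path
(radial layout, optionally saved as a new template); the rest are matched
against the library, inherit the template structure and coordinates, and
may be refolded in one of the constrained-folding modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import AlignmentResult, select_template, transfer_structure
from .config import PipelineConfig
from .denovo import choose_layout, count_overlaps, layout_radial, make_template
from .document import DocPair, Molecule, Residue, Rna2dDocument, write_document
from .folding import build_default_mask, fold_global, fold_global_masked, fold_local
from .io import SequenceRecord
from .layout import Layout, layout_from_template, transfer_labels
from .render import DataLayer, render_svg, render_thumbnail
from .structure import SecondaryStructure
from .templates import Template, TemplateLibrary

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class DrawResult:
    record_id: str
    svg: str
    thumbnail: str
    document: str
    template_id: str | None
    score: float | None
    fold_mode: str
    overlaps: int
    layout: Layout
    structure: SecondaryStructure


def build_document(
    record_id: str,
    seq: str,
    structure: SecondaryStructure,
    layout: Layout,
    labels: tuple[str | None, ...] | None = None,
) -> Rna2dDocument:
    residues = tuple(
        Residue(
            char=seq[k],
            index=k + 1,
            x=float(layout.coords[k, 0]),
            y=float(layout.coords[k, 1]),
            labels=(labels[k],) if labels is not None and labels[k] is not None else (),
        )
        for k in range(len(seq))
    )
    pairs = tuple(
        DocPair(i, j, "canonical", predicted=(i, j) in structure.predicted)
        for i, j, _ in sorted(structure.pairs)
    )
    return Rna2dDocument((Molecule(record_id, residues, pairs),), {})


def apply_folding(
    seq: str,
    qstruct: SecondaryStructure,
    aln: AlignmentResult,
    template: Template,
    mode: str,
) -> SecondaryStructure:
    if mode == "off":
        return qstruct
    if mode == "local":
        return fold_local(seq, qstruct, aln)
    if mode == "global":
        return fold_global(seq, qstruct)
    if mode == "global-masked":
        return fold_global_masked(seq, qstruct, build_default_mask(aln, template))
    raise PipelineError(f"unknown fold mode {mode!r}")


def draw_record(
    record: SequenceRecord,
    library: TemplateLibrary | None,
    config: PipelineConfig | None = None,
    layers: tuple[DataLayer, ...] = (),
    save_library=None,
) -> DrawResult:
    config = config or PipelineConfig()
    seq = record.sequence
    if record.structure is not None:
        candidates = [
            ("radial", layout_radial(seq, record.structure)),
            ("radial-flipped", layout_radial(seq, record.structure, flip=True)),
        ]
        name, layout = choose_layout(candidates, record.structure, config.forced_layout)
        structure = record.structure
        template_id = None
        score = None
        labels = None
        if config.save_template and save_library is not None:
            make_template(record.id, seq, structure, layout, library=save_library)
    else:
        if library is None or not library.templates:
            raise PipelineError(
                f"record {record.id!r} has no structure line and no template library was given"
            )
        hit = select_template(seq, library, config.selection)
        if hit is None:
            raise PipelineError(f"no template matched record {record.id!r}")
        template, aln = hit
        structure = transfer_structure(template, aln)
        structure = apply_folding(seq, structure, aln, template, config.fold_mode)
        layout = layout_from_template(seq, structure, template, aln)
        labels = transfer_labels(template, aln, config.suppress_labels)
        template_id = template.id
        score = aln.normalized_score(config.selection.params)
    layout.validate()
    overlaps = count_overlaps(layout, structure)
    svg = render_svg(
        seq,
        structure,
        layout,
        layers=layers,
        labels=labels,
        label_interval=config.label_interval,
    )
    thumb = render_thumbnail(layout)
    doc = write_document(build_document(record.id, seq, structure, layout, labels))
    logger.info(
        "record=%s template=%s score=%s fold_mode=%s overlaps=%d",
        record.id,
        template_id,
        f"{score:.3f}" if score is not None else "-",
        config.fold_mode,
        overlaps,
    )
    return DrawResult(
        record_id=record.id,
        svg=svg,
        thumbnail=thumb,
        document=doc,
        template_id=template_id,
        score=score,
        fold_mode=config.fold_mode,
        overlaps=overlaps,
        layout=layout,
        structure=structure,
    )
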
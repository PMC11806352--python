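"""Template records and the on-disk template library.

A template is a reference record of sequence, secondary structure and
per-nucleotide drawing coordinates; laying out a related sequence on the
template reproduces the familiar diagram.  Libraries live on disk as one
directory per template::

    library/
      index.yaml            # {"stages": ["long", "family", "trna"]}
      tmpl_01/
        template.fasta      # sequence + dot-bracket structure line
        coords.tsv          # index<TAB>x<TAB>y<TAB>label
        meta.yaml           # {"id": ..., "name": ..., "category": ...}
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import SequenceRecord, read_fasta, write_fasta
from .structure import SecondaryStructure

CATEGORIES = ("long", "family", "trna")
DEFAULT_STAGES = list(CATEGORIES)


class TemplateError(ValueError):
    pass


@dataclass(frozen=True)
class Template:
    id: str
    name: str
    sequence: str
    structure: SecondaryStructure
    coords: np.ndarray  # (n, 2) float64, y increasing downward
    numbering_labels: tuple[str | None, ...] = ()
    category: str = "family"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if self.structure.length != n:
            raise TemplateError(f"structure length {self.structure.length} != sequence length {n}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (n, 2):
            raise TemplateError(f"coords shape {coords.shape} != ({n}, 2)")
        if not np.all(np.isfinite(coords)):
            raise TemplateError("coords contain NaN or infinity")
        object.__setattr__(self, "coords", coords)
        labels = self.numbering_labels or (None,) * n
        if len(labels) != n:
            raise TemplateError(f"{len(labels)} labels for {n} nucleotides")
        object.__setattr__(self, "numbering_labels", tuple(labels))
        if self.category not in CATEGORIES:
            raise TemplateError(f"unknown category {self.category!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def write_template(template: Template, library: Path, overwrite: bool = False) -> Path:
    library = Path(library)
    tdir = library / template.id
    if tdir.exists() and not overwrite:
        raise TemplateError(f"template id {template.id!r} already exists in {library}")
    tdir.mkdir(parents=True, exist_ok=True)
    record = SequenceRecord(template.id, template.sequence, template.structure)
    (tdir / "template.fasta").write_text(write_fasta([record]))
    lines = ["index\tx\ty\tlabel"]
    for k, (x, y) in enumerate(template.coords):
        label = template.numbering_labels[k] or ""
        lines.append(f"{k}\t{float(x)!r}\t{float(y)!r}\t{label}")
    (tdir / "coords.tsv").write_text("\n".join(lines) + "\n")
    meta = {"id": template.id, "name": template.name, "category": template.category}
    (tdir / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    index = library / "index.yaml"
    if not index.exists():
        index.write_text(yaml.safe_dump({"stages": DEFAULT_STAGES}))
    return tdir


def read_template(tdir: Path) -> Template:
    tdir = Path(tdir)
    meta = yaml.safe_load((tdir / "meta.yaml").read_text())
    record = read_fasta((tdir / "template.fasta").read_text())[0]
    if record.structure is None:
        raise TemplateError(f"{tdir}: template.fasta lacks a structure line")
    coords: list[tuple[float, float]] = []
    labels: list[str | None] = []
    rows = (tdir / "coords.tsv").read_text().splitlines()
    for row in rows[1:]:
        if not row.strip():
            continue
        _, x, y, label = row.split("\t")
        coords.append((float(x), float(y)))
        labels.append(label or None)
    arr = np.array(coords, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise TemplateError(f"{tdir}: non-finite coordinates")
    return Template(
        id=meta["id"],
        name=meta.get("name", meta["id"]),
        sequence=record.sequence,
        structure=record.structure,
        coords=arr,
        numbering_labels=tuple(labels),
        category=meta.get("category", "family"),
    )


@dataclass
class TemplateLibrary:
    templates: dict[str, Template]
    stages: list[str]

    @classmethod
    def load(cls, root: Path) -> "TemplateLibrary":
        root = Path(root)
        stages = list(DEFAULT_STAGES)
        index = root / "index.yaml"
        if index.exists():
            stages = list(yaml.safe_load(index.read_text()).get("stages", DEFAULT_STAGES))
        templates = {}
        for tdir in sorted(p for p in root.iterdir() if p.is_dir()):
            t = read_template(tdir)
            templates[t.id] = t
        return cls(templates, stages)

    def by_category(self, category: str) -> list[Template]:
        if category not in CATEGORIES:
            raise TemplateError(f"unknown category {category!r}")
        return sorted(
            (t for t in self.templates.values() if t.category == category),
            key=lambda t: t.id,
        )

    def __len__(self) -> int:
        return len(self.templates)
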
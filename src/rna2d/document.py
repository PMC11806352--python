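"""The RNA 2D interchange document.

A JSON dialect carrying one or more RNA molecules with per-residue
coordinates, base pairs in Leontis-Westhof notation, numbering labels and
styling classes.  The exact field vocabulary is frozen in
``docs/rna2d-schema.json``; serialization is canonical (sorted keys, fixed
separators) so that write -> read -> write is byte-identical.

Layout of a document::

    {"rnaComplexes": [{"name": ...,
                       "rnaMolecules": [{"name": ...,
                                         "sequence":  [residue, ...],
                                         "basePairs": [pair, ...],
                                         "labels":    [label, ...]}]}],
     "classes": [styleClass, ...]}

Residues use 1-based display indices in the file; base pairs and labels
reference residues by 0-based position within the molecule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field


class DocumentError(ValueError):
    """Validation failure; the message names the offending JSON path."""


@dataclass(frozen=True)
class Residue:
    char: str
    index: int  # 1-based display index
    x: float
    y: float
    labels: tuple[str, ...] = ()
    style_class: str | None = None


@dataclass(frozen=True)
class DocPair:
    i: int  # 0-based residue positions
    j: int
    lw: str  # an LW code like "cWW"/"tHS", or "canonical"
    predicted: bool = False


@dataclass(frozen=True)
class StyleClass:
    colour: str = "#000000"
    font_size: float = 8.0
    visibility: str = "visible"


@dataclass(frozen=True)
class Molecule:
    name: str
    residues: tuple[Residue, ...]
    base_pairs: tuple[DocPair, ...] = ()


@dataclass(frozen=True)
class Rna2dDocument:
    molecules: tuple[Molecule, ...]
    classes: dict[str, StyleClass] = field(default_factory=dict)


_LW_VALUES = {"canonical"} | {
    f"{o}{a}{b}" for o in "ct" for a in "WHS" for b in "WHS"
}


def _fail(path: str, message: str) -> None:
    raise DocumentError(f"{path}: {message}")


def _require(obj: dict, key: str, types, path: str):
    if key not in obj:
        _fail(path, f"missing required field {key!r}")
    value = obj[key]
    if not isinstance(value, types) or isinstance(value, bool) and types is not bool:
        _fail(f"{path}.{key}", f"expected {types}, got {type(value).__name__}")
    return value


def _check_number(value, path: str) -> float:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        _fail(path, "expected a number")
    if math.isnan(value) or math.isinf(value):
        _fail(path, "coordinate is not finite")
    return float(value)


def validate_document_dict(data: dict) -> None:
    """Structural validation against the frozen dialect; raises DocumentError."""
    if not isinstance(data, dict):
        raise DocumentError("$: document must be a JSON object")
    complexes = _require(data, "rnaComplexes", list, "$")
    if not complexes:
        _fail("$.rnaComplexes", "at least one complex required")
    for ci, cx in enumerate(complexes):
        cpath = f"$.rnaComplexes[{ci}]"
        if not isinstance(cx, dict):
            _fail(cpath, "expected an object")
        _require(cx, "name", str, cpath)
        mols = _require(cx, "rnaMolecules", list, cpath)
        for mi, mol in enumerate(mols):
            mpath = f"{cpath}.rnaMolecules[{mi}]"
            if not isinstance(mol, dict):
                _fail(mpath, "expected an object")
            _require(mol, "name", str, mpath)
            seq = _require(mol, "sequence", list, mpath)
            if not seq:
                _fail(f"{mpath}.sequence", "molecule has no residues")
            for ri, res in enumerate(seq):
                rpath = f"{mpath}.sequence[{ri}]"
                if not isinstance(res, dict):
                    _fail(rpath, "expected an object")
                name = _require(res, "residueName", str, rpath)
                if len(name) != 1:
                    _fail(f"{rpath}.residueName", "expected a single character")
                idx = _require(res, "residueIndex", int, rpath)
                if idx < 1:
                    _fail(f"{rpath}.residueIndex", "display indices are 1-based")
                _check_number(res.get("x"), f"{rpath}.x")
                _check_number(res.get("y"), f"{rpath}.y")
                if "classes" in res:
                    classes = res["classes"]
                    if not isinstance(classes, list) or not all(
                        isinstance(c, str) for c in classes
                    ):
                        _fail(f"{rpath}.classes", "expected a list of class names")
            n = len(seq)
            for pi, bp in enumerate(_require(mol, "basePairs", list, mpath)):
                ppath = f"{mpath}.basePairs[{pi}]"
                if not isinstance(bp, dict):
                    _fail(ppath, "expected an object")
                i = _require(bp, "residueIndex1", int, ppath)
                j = _require(bp, "residueIndex2", int, ppath)
                if not (0 <= i < j < n):
                    _fail(ppath, f"base pair ({i},{j}) references nonexistent residues (n={n})")
                lw = _require(bp, "lw", str, ppath)
                if lw not in _LW_VALUES:
                    _fail(f"{ppath}.lw", f"unknown annotation {lw!r}")
                if "predicted" in bp and not isinstance(bp["predicted"], bool):
                    _fail(f"{ppath}.predicted", "expected a boolean")
            for li, lab in enumerate(_require(mol, "labels", list, mpath)):
                lpath = f"{mpath}.labels[{li}]"
                if not isinstance(lab, dict):
                    _fail(lpath, "expected an object")
                ridx = _require(lab, "residueIndex", int, lpath)
                if not 0 <= ridx < n:
                    _fail(lpath, f"label references nonexistent residue {ridx}")
                texts = _require(lab, "texts", list, lpath)
                if not all(isinstance(t, str) for t in texts):
                    _fail(f"{lpath}.texts", "expected a list of strings")
    for si, cls in enumerate(data.get("classes", [])):
        spath = f"$.classes[{si}]"
        if not isinstance(cls, dict):
            _fail(spath, "expected an object")
        _require(cls, "name", str, spath)
        _require(cls, "colour", str, spath)
        _check_number(cls.get("fontSize", 8.0), f"{spath}.fontSize")
        vis = cls.get("visibility", "visible")
        if vis not in ("visible", "hidden"):
            _fail(f"{spath}.visibility", f"unknown visibility {vis!r}")


def document_to_dict(doc: Rna2dDocument) -> dict:
    mols = []
    for mol in doc.molecules:
        seq = []
        labels = []
        for pos, res in enumerate(mol.residues):
            entry: dict = {
                "residueName": res.char,
                "residueIndex": res.index,
                "x": float(res.x),
                "y": float(res.y),
            }
            if res.style_class is not None:
                entry["classes"] = [res.style_class]
            seq.append(entry)
            if res.labels:
                labels.append({"residueIndex": pos, "texts": list(res.labels)})
        pairs = [
            {
                "residueIndex1": bp.i,
                "residueIndex2": bp.j,
                "lw": bp.lw,
                "predicted": bp.predicted,
            }
            for bp in mol.base_pairs
        ]
        mols.append(
            {"name": mol.name, "sequence": seq, "basePairs": pairs, "labels": labels}
        )
    classes = [
        {
            "name": name,
            "colour": cls.colour,
            "fontSize": float(cls.font_size),
            "visibility": cls.visibility,
        }
        for name, cls in sorted(doc.classes.items())
    ]
    return {
        "rnaComplexes": [{"name": "complex", "rnaMolecules": mols}],
        "classes": classes,
    }


def document_from_dict(data: dict) -> Rna2dDocument:
    validate_document_dict(data)
    molecules: list[Molecule] = []
    for cx in data["rnaComplexes"]:
        for mol in cx["rnaMolecules"]:
            label_map: dict[int, tuple[str, ...]] = {
                lab["residueIndex"]: tuple(lab["texts"]) for lab in mol["labels"]
            }
            residues = tuple(
                Residue(
                    char=res["residueName"],
                    index=res["residueIndex"],
                    x=float(res["x"]),
                    y=float(res["y"]),
                    labels=label_map.get(pos, ()),
                    style_class=(res.get("classes") or [None])[0],
                )
                for pos, res in enumerate(mol["sequence"])
            )
            pairs = tuple(
                DocPair(
                    bp["residueIndex1"],
                    bp["residueIndex2"],
                    bp["lw"],
                    bool(bp.get("predicted", False)),
                )
                for bp in mol["basePairs"]
            )
            molecules.append(Molecule(mol["name"], residues, pairs))
    classes = {
        cls["name"]: StyleClass(
            colour=cls["colour"],
            font_size=float(cls.get("fontSize", 8.0)),
            visibility=cls.get("visibility", "visible"),
        )
        for cls in data.get("classes", [])
    }
    return Rna2dDocument(tuple(molecules), classes)


def write_document(doc: Rna2dDocument) -> str:
    """Canonical JSON serialization (sorted keys, compact separators)."""
    data = document_to_dict(doc)
    validate_document_dict(data)
    return json.dumps(data, sort_keys=True, separators=(",", ":"), allow_nan=False)


def read_document(text: str) -> Rna2dDocument:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise DocumentError(f"not valid JSON: {exc}") from exc
    return document_from_dict(data)
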
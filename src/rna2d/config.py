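"""Pipeline configuration, overridable from a YAML file and CLI flags."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .align import SelectionConfig

FOLD_MODES = ("off", "local", "global", "global-masked")


@dataclass
class PipelineConfig:
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fold_mode: str = "off"
    forced_layout: str | None = None
    save_template: bool = False
    suppress_labels: tuple[str, ...] = ()
    label_interval: int = 10
    ssim_threshold: float = 0.99
    diff_threshold: float = 2 / 255
    animation_duration: float = 3.0

    def __post_init__(self) -> None:
        if self.fold_mode not in FOLD_MODES:
            raise ValueError(f"unknown fold mode {self.fold_mode!r}; expected one of {FOLD_MODES}")


def load_config(path: Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    sel_data = data.pop("selection", {})
    selection = replace(SelectionConfig(), **sel_data)
    known = {f for f in PipelineConfig.__dataclass_fields__ if f != "selection"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "suppress_labels" in data:
        data["suppress_labels"] = tuple(str(s) for s in data["suppress_labels"])
    return PipelineConfig(selection=selection, **data)
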
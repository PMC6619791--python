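"""Run configuration: YAML/JSON-loadable settings for a full pipeline run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .encoding import CodingScheme
from .validation import ValidationConfig


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    output_dir: str = "edflow_out"
    column_map: dict[str, str] = field(default_factory=dict)  # CSV header -> field
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    ties: str = "efron"
    confidence_level: float = 0.95
    #: prediction profiles: list of {name?, covariates...}; a profile may hold
    #: piecewise segments under "segments": [{start: 0.0, ...}, ...]
    profiles: list[dict[str, Any]] = field(default_factory=list)
    tau: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"
    #: categorical references / merge targets; None keeps the defaults
    references: Optional[dict[str, Any]] = None
    merge_map: Optional[dict[str, dict[Any, Any]]] = None

    def coding_scheme(self) -> CodingScheme:
        kwargs: dict = {}
        if self.references:
            refs = dict(CodingScheme().references)
            refs.update(self.references)
            kwargs["references"] = refs
        if self.merge_map is not None:
            kwargs["merge_map"] = {
                col: {_maybe_int(k): _maybe_int(v) for k, v in m.items()}
                for col, m in self.merge_map.items()
            }
        return CodingScheme(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _maybe_int(v):
    try:
        return int(v)
    except (TypeError, ValueError):
        return v


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("run config must be a mapping")
    vconf = data.pop("validation", None)
    cfg = RunConfig(**data)
    if vconf:
        cfg.validation = ValidationConfig(**vconf)
    return cfg
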
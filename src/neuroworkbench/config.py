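"""Run configuration: one validated, serialisable object per pipeline stage."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    """Stage parameters with the workbench defaults; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    stage: Literal[
        "simulate",
        "synapse-density",
        "calcium-activity",
        "sholl",
        "ephys",
        "brainfuse",
        "edit-stats",
    ]
    inputs: dict[str, str] = Field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0

    # stage parameters (shared defaults)
    fdr: float = 0.01
    radius_px: float = 2.0
    pixel_nm: float = 180.0
    pixel_um: float = 0.5
    prominence: float = 0.023
    min_width_s: float = 0.1
    max_length_frames: float = 37.0
    min_variance: float = 1e-4
    resample: int = 150
    block: int = 15
    percentile: float = 60.0
    p_per_guide: float = 0.3
    n_guides: int = 4

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def param_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
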
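"""Run configuration: one strict YAML document covering the whole pipeline.

Unknown keys are rejected so a typo in a hyperparameter name fails loudly
instead of silently falling back to a default.  The configuration hash is
recorded in every output manifest, making artifacts traceable to the
exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field

from .model import BlockConfig
from .preprocess import PreprocessConfig
from .synthetic import CohortSpec
from .training import TrainConfig

__all__ = ["RunConfig"]


class RunConfig(BaseModel):
    """Merged settings for simulate / preprocess / train / evaluate."""

    model_config = {"extra": "forbid"}

    seed: int = 0
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    model: BlockConfig = Field(default_factory=BlockConfig)
    train: TrainConfig = Field(default_factory=TrainConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True),
            encoding="utf-8")

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()
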
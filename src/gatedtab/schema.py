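"""Feature-table schema: column names, roles, clinical groups, vocabularies.

A :class:`FeatureSchema` describes one structured clinical feature table:
which columns are categorical / continuous / datetime, which are binary
adverse-event outcomes, and which of the six clinical variable groups
(basic information, medical history, laboratory tests, follow-up,
echocardiography, angiography) each belongs to.  Categorical columns carry
an ordered vocabulary; one extra code slot is always reserved for
categories unseen at fit time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Literal

from pydantic import BaseModel, field_validator, model_validator

Role = Literal["categorical", "continuous", "datetime", "outcome"]
Group = Literal["basic", "history", "lab", "followup", "echo", "angio"]

GROUPS: tuple[Group, ...] = ("basic", "history", "lab", "followup", "echo", "angio")

#: Default number of non-outcome variables per clinical group.
DEFAULT_GROUP_SIZES: dict[Group, int] = {
    "basic": 8,
    "history": 31,
    "lab": 30,
    "followup": 25,
    "echo": 20,
    "angio": 20,
}

#: The five adverse-event outcomes evaluated by the metrics suite.
DEFAULT_EVENTS: tuple[str, ...] = (
    "ischemic", "bleeding", "infectious", "febrile", "revascularization",
)


class ColumnSpec(BaseModel):
    name: str
    role: Role
    group: Group
    vocabulary: list[str] = []

    @model_validator(mode="after")
    def _check_vocab(self) -> "ColumnSpec":
        if self.role == "categorical" and not self.vocabulary:
            raise ValueError(f"categorical column {self.name!r} needs a vocabulary")
        if self.role != "categorical" and self.vocabulary:
            raise ValueError(f"non-categorical column {self.name!r} must not carry a vocabulary")
        return self

    @property
    def cardinality(self) -> int:
        """Vocabulary size including the reserved unknown slot."""
        return len(self.vocabulary) + 1


class FeatureSchema(BaseModel):
    """Ordered column descriptions for one feature table."""

    columns: list[ColumnSpec]

    @field_validator("columns")
    @classmethod
    def _unique_names(cls, v: list[ColumnSpec]) -> list[ColumnSpec]:
        names = [c.name for c in v]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate column names: {dupes}")
        return v

    # -- selectors -----------------------------------------------------
    def by_role(self, role: Role) -> list[ColumnSpec]:
        return [c for c in self.columns if c.role == role]

    @property
    def categorical(self) -> list[ColumnSpec]:
        return self.by_role("categorical")

    @property
    def continuous(self) -> list[ColumnSpec]:
        return self.by_role("continuous")

    @property
    def datetime_cols(self) -> list[ColumnSpec]:
        return self.by_role("datetime")

    @property
    def outcomes(self) -> list[ColumnSpec]:
        return self.by_role("outcome")

    @property
    def feature_columns(self) -> list[ColumnSpec]:
        return [c for c in self.columns if c.role != "outcome"]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def __iter__(self) -> Iterator[ColumnSpec]:  # type: ignore[override]
        return iter(self.columns)

    def group_counts(self) -> dict[Group, int]:
        counts: dict[Group, int] = {g: 0 for g in GROUPS}
        for c in self.feature_columns:
            counts[c.group] += 1
        return counts

    def group_shares(self, ndigits: int = 1) -> dict[Group, float]:
        """Percentage of non-outcome variables per group, rounded."""
        total = len(self.feature_columns)
        return {g: round(100.0 * n / total, ndigits)
                for g, n in self.group_counts().items()}

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.model_dump(), indent=2) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        return cls.model_validate(json.loads(Path(path).read_text(encoding="utf-8")))
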
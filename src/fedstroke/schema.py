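"""Schema of the clinical stroke-risk tabular record.

The 12-attribute layout mirrors the public stroke-prediction EHR table:
a unique patient id, demographics, comorbidity flags, lifestyle
categoricals, two continuous clinical measurements (average glucose,
BMI) and the binary stroke outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

MISSING = ""  # on-disk missing marker: empty CSV field

#: Attribute kinds understood by the schema.
KINDS = ("integer-id", "categorical", "continuous", "binary")


@dataclass(frozen=True)
class Attribute:
    """One column of the tabular schema."""

    name: str
    kind: str  # one of KINDS
    #: allowed values for categoricals, (low, high) hint for continuous
    values: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown attribute kind {self.kind!r}")


@dataclass(frozen=True)
class TabularSchema:
    """Ordered attribute list; defaults to the 12-column stroke layout."""

    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def __getitem__(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    def categorical_names(self) -> list[str]:
        return [a.name for a in self.attributes if a.kind == "categorical"]

    def continuous_names(self) -> list[str]:
        return [a.name for a in self.attributes if a.kind == "continuous"]


def stroke_schema() -> TabularSchema:
    """The default 12-attribute stroke-risk schema."""
    return TabularSchema(
        attributes=(
            Attribute("id", "integer-id"),
            Attribute("gender", "categorical", ("Male", "Female", "Other")),
            Attribute("age", "continuous", (0.0, 120.0)),
            Attribute("hypertension", "binary", (0, 1)),
            Attribute("heart_disease", "binary", (0, 1)),
            Attribute("ever_married", "categorical", ("No", "Yes")),
            Attribute(
                "work_type",
                "categorical",
                ("children", "Govt_job", "Never_worked", "Private", "Self-employed"),
            ),
            Attribute("residence_type", "categorical", ("Rural", "Urban")),
            Attribute("avg_glucose_level", "continuous", (40.0, 300.0)),
            Attribute("bmi", "continuous", (10.0, 70.0)),
            Attribute(
                "smoking_status",
                "categorical",
                ("formerly smoked", "never smoked", "smokes", "Unknown"),
            ),
            Attribute("stroke", "binary", (0, 1)),
        )
    )


@dataclass
class TabularRecord:
    """One patient's static attributes plus the binary stroke label.

    Continuous fields may be ``None`` to signal a missing value.
    """

    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    def __setitem__(self, key: str, val) -> None:
        self.values[key] = val

    @property
    def patient_id(self) -> int:
        return int(self.values["id"])

    @property
    def stroke(self) -> int:
        return int(self.values["stroke"])

    def validate(self, schema: TabularSchema) -> None:
        for attr in schema.attributes:
            if attr.name not in self.values:
                raise ValueError(f"record missing attribute {attr.name!r}")
            v = self.values[attr.name]
            if v is None:
                if attr.kind != "continuous":
                    raise ValueError(f"only continuous fields may be missing ({attr.name})")
                continue
            if attr.kind == "categorical" and v not in attr.values:
                raise ValueError(f"value {v!r} not allowed for {attr.name}")
            if attr.kind == "binary" and int(v) not in (0, 1):
                raise ValueError(f"binary field {attr.name} must be 0/1, got {v!r}")
            if attr.kind == "continuous" and attr.name in ("age", "avg_glucose_level", "bmi"):
                if float(v) <= 0:
                    raise ValueError(f"{attr.name} must be positive, got {v!r}")


def validate_records(records: Sequence[TabularRecord], schema: TabularSchema) -> None:
    """Validate each record and the dataset-level uniqueness of ``id``."""
    ids = set()
    for rec in records:
        rec.validate(schema)
        pid = rec.patient_id
        if pid in ids:
            raise ValueError(f"duplicate patient id {pid}")
        ids.add(pid)
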
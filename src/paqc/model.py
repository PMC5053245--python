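"""Domain data model: documentation statuses, prescriptions and case records.

A :class:`CaseRecord` is one admission episode abstracted from a case
record: what the admitting clinician documented (signs and symptoms),
which of the three in-scope diseases were diagnosed and with what
severity wording, and what was prescribed. Scoring never interprets
clinical truth — it measures *documentation* against guideline
recommendations, so a sign documented as absent counts exactly like one
documented as present.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

#: canonical disease identifiers (diarrhoea and dehydration are one illness
#: with four severity grades, not separate diseases)
DISEASES = ("malaria", "pneumonia", "diarrhoea_dehydration")


class DocStatus(str, Enum):
    documented_present = "documented_present"
    documented_absent = "documented_absent"
    documented_value = "documented_value"
    not_documented = "not_documented"


class Documentation(BaseModel):
    """Documentation state of one sign, optionally with a measured quantity."""

    model_config = ConfigDict(frozen=True)

    status: DocStatus = DocStatus.not_documented
    quantity: Optional[float] = None

    @model_validator(mode="after")
    def _value_needs_quantity(self) -> "Documentation":
        if self.status == DocStatus.documented_value and self.quantity is None:
            raise ValueError("documented_value requires a quantity")
        return self

    @property
    def documented(self) -> bool:
        return self.status != DocStatus.not_documented


class Role(str, Enum):
    loading = "loading"
    maintenance = "maintenance"
    single = "single"
    step1 = "step1"
    step2 = "step2"


class Route(str, Enum):
    iv = "iv"
    im = "im"
    oral = "oral"
    inhaled = "inhaled"
    ng = "ng"
    missing = "missing"


#: canonical drug vocabulary
DRUGS = (
    "quinine",
    "artemether_lumefantrine",
    "penicillin",
    "gentamicin",
    "oxygen",
    "amoxicillin",
    "cotrimoxazole",
    "normal_saline",
    "ringers_lactate",
    "ors",
)


class Prescription(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug: str
    role: Role = Role.single
    dose_amount: Optional[float] = Field(default=None, ge=0)
    dose_units: Optional[str] = None  # mg, iu, tablets, ml
    route: Route = Route.missing
    frequency_per_day: Optional[float] = Field(default=None, gt=0)
    duration: Optional[str] = None
    infusion_time_hours: Optional[float] = Field(default=None, gt=0)

    @field_validator("drug")
    @classmethod
    def _known_drug(cls, v: str) -> str:
        if v not in DRUGS:
            raise ValueError(f"unknown drug {v!r}")
        return v


class Arm(str, Enum):
    intervention = "intervention"
    control = "control"
    unknown = "unknown"


class CaseRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    record_id: str
    hospital_id: str
    clinician_id: Optional[str] = None
    arm: Arm = Arm.unknown
    survey: str = "baseline"
    age_months: float = Field(ge=0)
    weight_kg: Optional[float] = Field(default=None, gt=0)
    signs: dict[str, Documentation] = Field(default_factory=dict)
    #: disease -> classification wording as recorded (may be unrecognised)
    diagnoses: dict[str, str] = Field(default_factory=dict)
    prescriptions: tuple[Prescription, ...] = ()

    @field_validator("diagnoses")
    @classmethod
    def _known_diseases(cls, v: dict[str, str]) -> dict[str, str]:
        bad = set(v) - set(DISEASES)
        if bad:
            raise ValueError(f"diagnoses keys must be in {DISEASES}, got {sorted(bad)}")
        return v

    def documented(self, sign: str) -> bool:
        doc = self.signs.get(sign)
        return doc is not None and doc.documented

    @property
    def diseases(self) -> tuple[str, ...]:
        """Diagnosed in-scope diseases, in canonical order."""
        return tuple(d for d in DISEASES if d in self.diagnoses)
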
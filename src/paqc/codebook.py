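"""Machine-readable guideline codebook.

The codebook carries everything the scorers need to know about the three
in-scope illnesses: the 8 assessment items each, the primary/secondary
(danger) sign rules as boolean documentation expressions, the severity
classifications recognised by the guidelines, and the classification-
specific treatment rules (drug sets with route/dose/frequency/duration
constraints). A reference transcription ships with the package; loading
validates the structural invariants the scores rely on:

* each disease lists exactly 8 assessment items,
* the union of assessment items has exactly 19 signs,
* exactly 2 signs (ability to drink/breastfeed, AVPU) are shared by all
  three diseases.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import CodebookError
from .expressions import Expr, expr_signs, validate_expr
from .model import DISEASES, DRUGS, Route

#: default relative tolerance on per-kg doses ("deviations of up to 20%")
DEFAULT_DOSE_TOLERANCE = 0.20


class DoseRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["per_kg", "weight_band", "fluid_bolus", "fluid_total"]
    target: Optional[float] = Field(default=None, gt=0)  # per-kg target
    units: Optional[str] = None  # mg, iu, tablets, ml
    #: weight-band table rows (low_kg, high_kg or None for open, tablets)
    bands: Optional[tuple[tuple[float, Optional[float], int], ...]] = None
    window_hours: Optional[float] = Field(default=None, gt=0)
    window_hours_under_1y: Optional[float] = Field(default=None, gt=0)
    max_administrations: Optional[int] = Field(default=None, ge=1)
    tolerance: float = Field(default=DEFAULT_DOSE_TOLERANCE, ge=0, lt=1)

    @model_validator(mode="after")
    def _coherent(self) -> "DoseRule":
        if self.kind == "weight_band":
            if not self.bands:
                raise ValueError("weight_band rule needs a band table")
            lows = [b[0] for b in self.bands]
            highs = [b[1] for b in self.bands]
            if lows != sorted(lows):
                raise ValueError("bands must be ordered by weight")
            for (_, hi, _), (lo, _, _) in zip(self.bands, self.bands[1:]):
                if hi is None or lo <= hi:
                    raise ValueError("bands must be disjoint and ordered")
            if any(h is None for h in highs[:-1]):
                raise ValueError("only the last band may be open-ended")
        elif self.target is None:
            raise ValueError(f"{self.kind} rule needs a per-kg target")
        return self


class FrequencyRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["exact", "any_specified", "min_within_window", "steps_used", "none"] = "none"
    per_day: Optional[float] = Field(default=None, gt=0)
    window_hours: Optional[float] = Field(default=None, gt=0)
    min_count: int = Field(default=1, ge=1)

    @model_validator(mode="after")
    def _coherent(self) -> "FrequencyRule":
        if self.kind == "exact" and self.per_day is None:
            raise ValueError("exact frequency needs per_day")
        if self.kind == "min_within_window" and self.window_hours is None:
            raise ValueError("min_within_window needs window_hours")
        return self


class DurationRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal["any_specified", "stat", "none"] = "none"


class DrugSpec(BaseModel):
    """Constraints on one drug within an allowed combination."""

    model_config = ConfigDict(frozen=True)

    drug: str
    role: Optional[str] = None  # loading/maintenance/...; None = any role
    routes: Optional[tuple[Route, ...]] = None  # None = route not constrained
    dose: Optional[DoseRule] = None
    frequency: FrequencyRule = FrequencyRule()
    duration: DurationRule = DurationRule()

    @model_validator(mode="after")
    def _known_drug(self) -> "DrugSpec":
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        return self


class DrugSet(BaseModel):
    """One allowed drug combination; any one satisfied set earns drug choice."""

    model_config = ConfigDict(frozen=True)

    drugs: tuple[DrugSpec, ...]
    forbidden: tuple[str, ...] = ()  # co-prescriptions that void the set


class TreatmentRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug_sets: tuple[DrugSet, ...]

    @property
    def has_route(self) -> bool:
        return any(s.routes is not None for ds in self.drug_sets for s in ds.drugs)

    @property
    def has_dose(self) -> bool:
        return any(s.dose is not None for ds in self.drug_sets for s in ds.drugs)

    @property
    def has_frequency(self) -> bool:
        return any(s.frequency.kind != "none" for ds in self.drug_sets for s in ds.drugs)

    @property
    def has_duration(self) -> bool:
        return any(s.duration.kind != "none" for ds in self.drug_sets for s in ds.drugs)

    def applicable_aspects(self) -> tuple[str, ...]:
        """Itemised treatment aspects this rule constrains (basic score)."""
        out = ["drug"]
        for aspect, present in (
            ("route", self.has_route),
            ("dose", self.has_dose),
            ("frequency", self.has_frequency),
            ("duration", self.has_duration),
        ):
            if present:
                out.append(aspect)
        return tuple(out)


class DiseaseRules(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    assessment_items: tuple[str, ...]
    primary_signs: Expr
    secondary_signs: dict[str, Expr]  # classification -> documentation rule
    danger_branch: str    # classification whose rule is ">=1 danger sign"
    complete_branch: str  # classification whose rule is "all danger signs"
    classifications: dict[str, tuple[str, ...]]  # canonical -> recorded aliases
    treatments: dict[str, TreatmentRule]

    @property
    def danger_signs(self) -> tuple[str, ...]:
        """Flat list of signs involved in the danger-sign rule."""
        return tuple(sorted(expr_signs(self.secondary_signs[self.danger_branch])))

    @property
    def complete_items(self) -> tuple[str, ...]:
        """Signs whose documentation constitutes a complete assessment.

        The 8 assessment items plus any sign the secondary rules reference
        from another disease's list, so that complete documentation always
        implies the primary and secondary items score 1.
        """
        extra: set[str] = set()
        for expr in self.secondary_signs.values():
            extra |= expr_signs(expr)
        extra |= expr_signs(self.primary_signs)
        return tuple(dict.fromkeys(list(self.assessment_items) + sorted(extra - set(self.assessment_items))))

    def resolve_classification(self, recorded: Optional[str]) -> Optional[str]:
        """Canonical classification for a recorded wording, or None.

        Matching is case-insensitive with hyphens/underscores collapsed;
        unmatched wordings are treated as no valid classification.
        """
        if not recorded:
            return None
        key = _canon(recorded)
        for name, aliases in self.classifications.items():
            if key == _canon(name) or any(key == _canon(a) for a in aliases):
                return name
        return None


def _canon(s: str) -> str:
    return " ".join(s.lower().replace("-", " ").replace("_", " ").split())


class GuidelineCodebook(BaseModel):
    model_config = ConfigDict(frozen=True)

    version: str = "unversioned"
    signs: tuple[str, ...]
    synonyms: dict[str, str] = Field(default_factory=dict)
    diseases: dict[str, DiseaseRules]

    @model_validator(mode="after")
    def _invariants(self) -> "GuidelineCodebook":
        if set(self.diseases) != set(DISEASES):
            raise ValueError(f"diseases must be exactly {DISEASES}")
        for syn, target in self.synonyms.items():
            if target not in self.signs:
                raise ValueError(f"synonym {syn!r} maps to unknown sign {target!r}")
        union: set[str] = set()
        shared: Optional[set[str]] = None
        for name, rules in self.diseases.items():
            if len(rules.assessment_items) != 8:
                raise ValueError(
                    f"assessment item count for {name} is "
                    f"{len(rules.assessment_items)}, expected 8"
                )
            items = set(rules.assessment_items)
            unknown = items - set(self.signs)
            if unknown:
                raise ValueError(f"{name} lists unknown signs {sorted(unknown)}")
            union |= items
            shared = items if shared is None else shared & items
            validate_expr(rules.primary_signs, self.signs)
            for cls, expr in rules.secondary_signs.items():
                validate_expr(expr, self.signs)
                if cls not in rules.classifications:
                    raise ValueError(f"{name}: secondary rule for unknown classification {cls!r}")
            for branch in (rules.danger_branch, rules.complete_branch):
                if branch not in rules.secondary_signs:
                    raise ValueError(f"{name}: branch {branch!r} has no secondary rule")
            missing = set(rules.classifications) - set(rules.treatments)
            if missing:
                raise ValueError(f"{name}: classifications without treatment rules {sorted(missing)}")
        if len(union) != 19:
            raise ValueError(f"assessment item union has {len(union)} signs, expected 19")
        if shared is None or len(shared) != 2:
            raise ValueError(
                f"signs shared by all diseases: {sorted(shared or ())}, expected exactly 2"
            )
        expected = {
            "malaria": {"severe", "non_severe"},
            "pneumonia": {"very_severe", "severe", "non_severe"},
            "diarrhoea_dehydration": {"shock", "severe", "some", "none"},
        }
        for name, want in expected.items():
            got = set(self.diseases[name].classifications)
            if got != want:
                raise ValueError(f"{name} classifications {sorted(got)}, expected {sorted(want)}")
        return self

    @property
    def sign_union(self) -> tuple[str, ...]:
        """The guideline-recommended signs across all three diseases."""
        out: set[str] = set()
        for rules in self.diseases.values():
            out |= set(rules.assessment_items)
        return tuple(sorted(out))

    @property
    def shared_signs(self) -> tuple[str, ...]:
        items = [set(r.assessment_items) for r in self.diseases.values()]
        return tuple(sorted(set.intersection(*items)))

    def canonical_sign(self, name: str) -> Optional[str]:
        key = name.strip().lower()
        if key in self.signs:
            return key
        return self.synonyms.get(key) or self.synonyms.get(name.strip())


def load_codebook(path: str | Path | None = None) -> GuidelineCodebook:
    """Load and validate a codebook file (default: the shipped reference).

    Raises :class:`CodebookError` naming the failing invariant on any
    parse or validation failure.
    """
    try:
        if path is None:
            source = importlib.resources.files("paqc").joinpath("data/codebook.yaml")
            raw = yaml.safe_load(source.read_text())
        else:
            raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise CodebookError(f"cannot read codebook: {exc}") from exc
    if not isinstance(raw, dict):
        raise CodebookError("codebook file must be a mapping")
    try:
        diseases = {
            name: DiseaseRules(name=name, **spec)
            for name, spec in raw.get("diseases", {}).items()
        }
        return GuidelineCodebook(
            version=str(raw.get("version", "unversioned")),
            signs=tuple(raw.get("signs", ())),
            synonyms={str(k).lower(): v for k, v in (raw.get("synonyms") or {}).items()},
            diseases=diseases,
        )
    except (ValidationError, ValueError) as exc:
        raise CodebookError(f"invalid codebook: {exc}") from exc
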
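"""The PAQC score: six binary items, three domains, range 0-6.

Each disease-specific score sums six binary items grouped by domain:

* assessment — primary signs documented; secondary (danger) signs
  documented per the severity-dependent rule; complete documentation of
  all assessment signs (D1, 0-3);
* diagnosis — a guideline-recognised severity classification recorded
  (D2, 0-1);
* treatment — correct drug choice for the recorded severity; correct use
  of the chosen drugs (D3, 0-2).

With multimorbidity the patient-level items are the all-or-none (logical
AND) combination across diagnosed diseases, so the patient score remains
an integer count of fully completed care tasks on the same 0-6 scale.

The secondary-signs rule branches on severity: a severe-type
classification needs at least one danger sign documented, while a
non-severe claim requires *complete* documentation of the danger signs
(the clinician must positively exclude them). When no valid
classification is recorded the demanding complete-documentation branch
applies by default (``secondary_branch="complete"``); ``"any"`` and
``"zero"`` are available for sensitivity analyses.
"""

from __future__ import annotations

from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict

from .codebook import GuidelineCodebook
from .errors import NotScoreableError
from .expressions import evaluate
from .model import CaseRecord
from .treatment_eval import check_correct_use

ITEM_NAMES = (
    "primary_signs",
    "secondary_signs",
    "complete_assessment",
    "classification",
    "drug_choice",
    "correct_use",
)

SecondaryBranch = Literal["complete", "any", "zero"]


class ItemScores(BaseModel):
    model_config = ConfigDict(frozen=True)

    primary_signs: int
    secondary_signs: int
    complete_assessment: int
    classification: int
    drug_choice: int
    correct_use: int

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, n) for n in ITEM_NAMES)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    @property
    def domains(self) -> tuple[int, int, int]:
        """(D1 assessment 0-3, D2 diagnosis 0-1, D3 treatment 0-2)."""
        t = self.as_tuple()
        return sum(t[:3]), t[3], sum(t[4:])


class PAQCScore(BaseModel):
    """Patient-level result: per-disease items, combined items, domains, Q."""

    model_config = ConfigDict(frozen=True)

    record_id: str
    diseases: tuple[str, ...]
    per_disease: dict[str, ItemScores]
    combined: ItemScores

    @property
    def d1(self) -> int:
        return self.combined.domains[0]

    @property
    def d2(self) -> int:
        return self.combined.domains[1]

    @property
    def d3(self) -> int:
        return self.combined.domains[2]

    @property
    def q(self) -> int:
        return self.combined.total


def score_paqc_disease(
    record: CaseRecord,
    disease: str,
    codebook: GuidelineCodebook,
    secondary_branch: SecondaryBranch = "complete",
) -> ItemScores:
    """The six binary PAQC items of one record for one diagnosed disease."""
    if disease not in record.diagnoses:
        raise NotScoreableError(f"record {record.record_id} has no {disease} diagnosis")
    rules = codebook.diseases[disease]
    documented = {s for s in codebook.signs if record.documented(s)}

    primary = int(evaluate(rules.primary_signs, documented))
    classification = rules.resolve_classification(record.diagnoses.get(disease))

    if classification is not None:
        secondary = int(evaluate(rules.secondary_signs[classification], documented))
    elif secondary_branch == "zero":
        secondary = 0
    else:
        branch = rules.complete_branch if secondary_branch == "complete" else rules.danger_branch
        secondary = int(evaluate(rules.secondary_signs[branch], documented))

    complete = int(all(s in documented for s in rules.complete_items))

    if classification is None:
        drug_choice = correct_use = 0
    else:
        drug_choice, correct_use = check_correct_use(
            record.prescriptions,
            classification,
            record.weight_kg,
            record.age_months,
            rules.treatments[classification],
        )
    return ItemScores(
        primary_signs=primary,
        secondary_signs=secondary,
        complete_assessment=complete,
        classification=int(classification is not None),
        drug_choice=drug_choice,
        correct_use=correct_use,
    )


def combine_multimorbidity(per_disease: Mapping[str, ItemScores]) -> ItemScores:
    """All-or-none combination: each item is the AND across diagnosed diseases."""
    if not per_disease:
        raise NotScoreableError("no disease-specific scores to combine")
    values = [s.as_tuple() for s in per_disease.values()]
    combined = tuple(min(col) for col in zip(*values))
    return ItemScores(**dict(zip(ITEM_NAMES, combined)))


def score_patient(
    record: CaseRecord,
    codebook: GuidelineCodebook,
    secondary_branch: SecondaryBranch = "complete",
) -> PAQCScore:
    """Patient-level PAQC score across every in-scope diagnosis.

    Raises :class:`NotScoreableError` when the record carries none of the
    three diseases; batch callers count such records rather than fail.
    """
    diseases = record.diseases
    if not diseases:
        raise NotScoreableError(f"record {record.record_id} has no in-scope diagnosis")
    per_disease = {
        d: score_paqc_disease(record, d, codebook, secondary_branch) for d in diseases
    }
    return PAQCScore(
        record_id=record.record_id,
        diseases=diseases,
        per_disease=per_disease,
        combined=combine_multimorbidity(per_disease),
    )


def score_cohort(
    records: list[CaseRecord],
    codebook: GuidelineCodebook,
    secondary_branch: SecondaryBranch = "complete",
) -> tuple[list[PAQCScore], list[str]]:
    """Score a batch; returns (scores, record_ids that were not scoreable)."""
    scores: list[PAQCScore] = []
    not_scoreable: list[str] = []
    for rec in records:
        try:
            scores.append(score_patient(rec, codebook, secondary_branch))
        except NotScoreableError:
            not_scoreable.append(rec.record_id)
    return scores, not_scoreable
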
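"""The basic additive score.

The first-pass scoring scheme sums every itemised indicator: 8 assessment
documentation items, 1 classification item, and 5 itemised treatment
indicators (drug, route, dose, frequency, duration) for malaria and
pneumonia or 3 (drug, dose, frequency) for diarrhoea/dehydration —
15-point (0-14) and 13-point (0-12) scales respectively. The scheme is
retained because its documented deficiencies (assessment-domain
domination, non-equivalent ranges across diseases, item redundancy)
motivate the PAQC score, and the redundancy diagnostics need its items.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict

from .codebook import GuidelineCodebook
from .errors import NotScoreableError
from .model import CaseRecord
from .treatment_eval import evaluate_aspects


class BasicScore(BaseModel):
    model_config = ConfigDict(frozen=True)

    disease: str
    assessment: int  # 0-8: documented assessment items
    diagnosis: int   # 0/1: valid severity classification recorded
    treatment: int   # sum of itemised indicators (0-5, or 0-3 for diarrhoea)
    #: per-aspect treatment indicators actually scored (absent = structurally
    #: not applicable, e.g. route/duration for diarrhoea)
    treatment_items: dict[str, int]

    @property
    def total(self) -> int:
        return self.assessment + self.diagnosis + self.treatment


def score_basic(record: CaseRecord, disease: str, codebook: GuidelineCodebook) -> BasicScore:
    """Basic additive score of one record for one diagnosed disease.

    Treatment indicators are conditioned on a valid classification (all 0
    without one): the guidelines define treatment correctness relative to
    the indicated severity, so without a valid severity claim no
    prescription can be judged correct.
    """
    if disease not in record.diagnoses:
        raise NotScoreableError(f"record {record.record_id} has no {disease} diagnosis")
    rules = codebook.diseases[disease]
    assessment = sum(1 for item in rules.assessment_items if record.documented(item))
    classification = rules.resolve_classification(record.diagnoses.get(disease))
    if classification is None:
        items = {a: 0 for a in rules.treatments[next(iter(rules.treatments))].applicable_aspects()}
        return BasicScore(disease=disease, assessment=assessment, diagnosis=0,
                          treatment=0, treatment_items=items)
    rule = rules.treatments[classification]
    items = evaluate_aspects(record.prescriptions, rule, record.weight_kg, record.age_months)
    return BasicScore(
        disease=disease,
        assessment=assessment,
        diagnosis=1,
        treatment=sum(items.values()),
        treatment_items=items,
    )
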
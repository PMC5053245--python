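import pytest

from paqc.codebook import load_codebook
from paqc.model import CaseRecord, DocStatus, Documentation, Prescription, Role, Route


@pytest.fixture(scope="session")
def codebook():
    return load_codebook()


def documented(*signs, value_signs=()):
    out = {s: Documentation(status=DocStatus.documented_present) for s in signs}
    for s in value_signs:
        out[s] = Documentation(status=DocStatus.documented_value, quantity=48.0)
    return out


def full_marks_record(disease: str, cb) -> CaseRecord:
    """A hand-constructed perfectly adherent admission for one disease."""
    rules = cb.diseases[disease]
    signs = documented(*rules.complete_items)
    if disease == "malaria":
        diagnoses = {"malaria": "severe malaria"}
        rx = (
            Prescription(drug="quinine", role=Role.loading, route=Route.iv,
                         dose_amount=200.0, dose_units="mg", duration="stat"),
            Prescription(drug="quinine", role=Role.maintenance, route=Route.iv,
                         dose_amount=100.0, dose_units="mg",
                         frequency_per_day=2, duration="7 days"),
        )
    elif disease == "pneumonia":
        diagnoses = {"pneumonia": "very severe pneumonia"}
        rx = (
            Prescription(drug="penicillin", route=Route.im, dose_amount=500000.0,
                         dose_units="iu", frequency_per_day=4, duration="5 days"),
            Prescription(drug="gentamicin", route=Route.iv, dose_amount=75.0,
                         dose_units="mg", frequency_per_day=1, duration="5 days"),
            Prescription(drug="oxygen", frequency_per_day=1, duration="continuous"),
        )
    else:
        diagnoses = {"diarrhoea_dehydration": "shock"}
        rx = (
            Prescription(drug="normal_saline", dose_amount=200.0, dose_units="ml",
                         infusion_time_hours=1.0),
        )
    return CaseRecord(
        record_id=f"FULL-{disease}",
        hospital_id="H01",
        age_months=24.0,
        weight_kg=10.0,
        signs=signs,
        diagnoses=diagnoses,
        prescriptions=rx,
    )


@pytest.fixture(scope="session")
def full_marks(codebook):
    return {d: full_marks_record(d, codebook) for d in codebook.diseases}


@pytest.fixture()
def empty_malaria_record():
    """Diagnosed malaria, nothing documented, no classification wording."""
    return CaseRecord(record_id="E1", hospital_id="H01", age_months=12.0,
                      weight_kg=8.0, diagnoses={"malaria": ""})
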
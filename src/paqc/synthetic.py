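"""Synthetic multi-hospital case-record cohorts with controllable adherence.

The generator emulates the structure of a two-arm, multi-survey hospital
trial: records nest in hospitals (random intercepts), hospitals belong to
an arm, and each record carries one of seven single/multimorbidity
disease categories. Every PAQC item has a per-record adherence
probability resolved on the logit scale from a baseline level plus arm,
survey and arm-by-survey effects and the hospital intercept; item draws
are then *realised* as concrete documentation, classification wording and
prescriptions, so that scoring the generated record reproduces the drawn
item vector.

Draws are coupled down the item hierarchy so configured marginal
probabilities are reproduced exactly for single-disease records:
``complete_assessment = 1`` forces the primary and secondary items, and
``correct_use <= drug_choice <= classification`` by construction, with
conditional probabilities chosen so each item's marginal equals its
target (this requires the natural orderings ``p_complete <=
min(p_primary, p_secondary)`` and ``p_use <= p_drug <= p_classification``,
validated on the baseline levels; shared covariate shifts preserve them).

Non-adherent items are realised as a violation drawn from an enumerated
catalogue (missing documentation, unrecognised classification wording,
wrong/absent/incomplete drug, out-of-window dose, wrong route or
frequency, missing duration). With multimorbidity, items are generated
independently per disease; violations prefer disease-unique signs and
drugs so cross-disease leakage through the two shared signs is rare (it
is reported, not hidden, by :func:`adherence_recovery_report`).
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .codebook import DrugSpec, GuidelineCodebook, load_codebook
from .expressions import satisfying_set, violating_set
from .model import Arm, CaseRecord, DocStatus, Documentation, Prescription, Role, Route
from .paqc_score import ITEM_NAMES, score_cohort

# ---------------------------------------------------------------------------
# violation catalogue (data, not code)

#: classification-item violations: how a missing/invalid severity is recorded
CLASSIFICATION_VIOLATIONS = ("missing", "unrecognised")

#: drug-choice violations, filtered per rule (incomplete needs a multi-drug
#: set, forbidden_extra needs an exclusion rule, wrong_drug needs a safe drug)
DRUG_VIOLATIONS = ("none", "wrong_drug", "incomplete_set", "forbidden_extra")

#: correct-use violations, filtered to the aspects the rule constrains
USE_VIOLATIONS = ("bad_dose", "wrong_route", "wrong_frequency", "missing_duration")

#: preferred wrong-drug realisation per (disease, classification); drawn from
#: the same disease's other classifications where possible so a wrong drug
#: cannot complete a co-diagnosed disease's allowed set (checked at run time)
WRONG_DRUG_PREFERENCE: dict[tuple[str, str], tuple[str, ...]] = {
    ("malaria", "severe"): ("artemether_lumefantrine",),
    ("malaria", "non_severe"): ("penicillin", "oxygen"),
    ("pneumonia", "very_severe"): ("amoxicillin",),
    ("pneumonia", "severe"): ("amoxicillin",),
    ("pneumonia", "non_severe"): ("penicillin",),
    ("diarrhoea_dehydration", "shock"): ("ors",),
    ("diarrhoea_dehydration", "severe"): ("normal_saline",),
    ("diarrhoea_dehydration", "some"): ("normal_saline",),
    ("diarrhoea_dehydration", "none"): ("normal_saline",),
}

_UNRECOGNISED_WORDING = {
    "malaria": "?malaria",
    "pneumonia": "chest infection",
    "diarrhoea_dehydration": "gastro",
}


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int
    n_hospitals: int = Field(default=8, ge=1)
    n_per_hospital_per_survey: int = Field(default=400, ge=1)
    surveys: tuple[str, ...] = ("baseline", "endline")
    arms: tuple[str, str] = ("control", "intervention")
    #: disease category -> probability; multimorbidity keys join diseases
    #: with "+" in canonical order
    disease_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "malaria": 0.30,
            "pneumonia": 0.18,
            "diarrhoea_dehydration": 0.08,
            "malaria+pneumonia": 0.25,
            "malaria+diarrhoea_dehydration": 0.10,
            "pneumonia+diarrhoea_dehydration": 0.03,
            "malaria+pneumonia+diarrhoea_dehydration": 0.06,
        }
    )
    #: true severity distribution per disease (grades are classifications,
    #: not diseases)
    severity_probs: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "malaria": {"severe": 0.4, "non_severe": 0.6},
            "pneumonia": {"very_severe": 0.2, "severe": 0.4, "non_severe": 0.4},
            "diarrhoea_dehydration": {"shock": 0.1, "severe": 0.3, "some": 0.4, "none": 0.2},
        }
    )
    #: baseline (control arm, first survey, average hospital) adherence
    #: probability per PAQC item
    item_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "primary_signs": 0.85,
            "secondary_signs": 0.40,
            "complete_assessment": 0.20,
            "classification": 0.50,
            "drug_choice": 0.30,
            "correct_use": 0.20,
        }
    )
    arm_effect: float = 0.0       # logit shift, intervention arm at baseline
    survey_effect: float = 0.4    # logit shift per survey step (both arms)
    interaction: float = 0.7      # extra per-step shift in the intervention arm
    hospital_sd: float = Field(default=0.3, ge=0)
    #: exchangeable Gaussian-copula correlation of the per-item latent draws
    #: (within a disease); 0 = independent items given covariates
    latent_rho: float = Field(default=0.0, ge=0, lt=1)
    #: probability of prescribing the severity-appropriate drugs even when
    #: the classification item is non-adherent (treated-but-not-classified)
    p_treat_without_classification: float = Field(default=0.25, ge=0, le=1)
    #: probability of documenting each additional, rule-irrelevant sign
    extra_documentation_p: float = Field(default=0.15, ge=0, le=1)
    age_months_range: tuple[float, float] = (2.0, 59.0)

    @model_validator(mode="after")
    def _valid(self) -> "SimulationConfig":
        if not math.isclose(sum(self.disease_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("disease_mix probabilities must sum to 1")
        for cat in self.disease_mix:
            for d in cat.split("+"):
                if d not in self.severity_probs:
                    raise ValueError(f"unknown disease {d!r} in disease_mix")
        for d, probs in self.severity_probs.items():
            if not math.isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"severity_probs[{d!r}] must sum to 1")
        if set(self.item_probs) != set(ITEM_NAMES):
            raise ValueError(f"item_probs must cover exactly {ITEM_NAMES}")
        p = self.item_probs
        if not all(0.0 <= v <= 1.0 for v in p.values()):
            raise ValueError("item probabilities must lie in [0, 1]")
        if p["complete_assessment"] > min(p["primary_signs"], p["secondary_signs"]) + 1e-12:
            raise ValueError("complete_assessment target must not exceed primary/secondary targets")
        if not (p["correct_use"] <= p["drug_choice"] + 1e-12
                and p["drug_choice"] <= p["classification"] + 1e-12):
            raise ValueError("targets must satisfy correct_use <= drug_choice <= classification")
        return self


# ---------------------------------------------------------------------------
# probability resolution


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def resolved_item_probs(
    config: SimulationConfig, arm: str, survey_index: int, hospital_effect: float
) -> dict[str, float]:
    """Per-item adherence probabilities for one design cell.

    Degenerate baselines (0 or 1) stay degenerate regardless of effects.
    """
    is_int = 1.0 if arm == "intervention" else 0.0
    shift = (
        config.arm_effect * is_int
        + config.survey_effect * survey_index
        + config.interaction * is_int * survey_index
        + hospital_effect
    )
    out = {}
    for item, p in config.item_probs.items():
        if p <= 0.0 or p >= 1.0:
            out[item] = float(p)
        else:
            out[item] = _invlogit(_logit(p) + shift)
    return out


def hospital_effects(config: SimulationConfig) -> np.ndarray:
    """Hospital random intercepts; the first draws of the seeded stream,
    so reports can re-derive them from the config alone."""
    rng = np.random.default_rng([config.seed, 0])
    return rng.normal(0.0, config.hospital_sd, config.n_hospitals)


def _chain_draws(u: np.ndarray, p: dict[str, float]) -> dict[str, int]:
    """Draw the six items from uniforms, respecting the score hierarchy
    while reproducing each item's marginal probability."""

    def cond(child: float, parent: float) -> float:
        if parent <= 0.0:
            return 0.0
        return min(1.0, max(0.0, child / parent))

    com = u[2] < p["complete_assessment"]
    if com:
        pri = sec = True
    else:
        rest = 1.0 - p["complete_assessment"]
        pri = u[0] < min(1.0, max(0.0, (p["primary_signs"] - p["complete_assessment"]) / rest))
        sec = u[1] < min(1.0, max(0.0, (p["secondary_signs"] - p["complete_assessment"]) / rest))
    cls = u[3] < p["classification"]
    drug = cls and u[4] < cond(p["drug_choice"], p["classification"])
    use = drug and u[5] < cond(p["correct_use"], p["drug_choice"])
    return {
        "primary_signs": int(pri),
        "secondary_signs": int(sec),
        "complete_assessment": int(com),
        "classification": int(cls),
        "drug_choice": int(drug),
        "correct_use": int(use),
    }


# ---------------------------------------------------------------------------
# realisation of drawn items as record content


def _adherent_prescriptions(
    specs: Sequence[DrugSpec], weight: float, age_months: float, rng: np.random.Generator
) -> list[Prescription]:
    out: list[Prescription] = []
    for i, spec in enumerate(specs):
        route = Route(spec.routes[0].value) if spec.routes else Route.missing
        freq = dur = None
        infusion = None
        role = Role(spec.role) if spec.role else Role.single
        fr = spec.frequency
        if fr.kind == "exact":
            freq = fr.per_day
        elif fr.kind == "any_specified":
            freq = float(rng.integers(1, 5))
        if spec.duration.kind == "any_specified":
            dur = f"{int(rng.integers(2, 8))} days"
        elif spec.duration.kind == "stat":
            dur = "stat"
        dose = spec.dose
        if dose is None:
            out.append(Prescription(drug=spec.drug, role=role, route=route,
                                    frequency_per_day=freq, duration=dur))
            continue
        if dose.kind == "per_kg":
            amount = dose.target * weight * rng.uniform(0.85, 1.15)
            out.append(Prescription(drug=spec.drug, role=role, route=route,
                                    dose_amount=round(amount, 2), dose_units=dose.units,
                                    frequency_per_day=freq, duration=dur))
        elif dose.kind == "weight_band":
            tabs = None
            for lo, hi, n_tabs in dose.bands:
                if weight >= lo and (hi is None or weight <= hi):
                    tabs = n_tabs
            # weights in a band-table gap keep the nearest lower band's count
            if tabs is None:
                below = [n for lo, hi, n in dose.bands if lo <= weight]
                tabs = below[-1] if below else dose.bands[0][2]
            out.append(Prescription(drug=spec.drug, role=role, route=route,
                                    dose_amount=float(tabs), dose_units="tablets",
                                    frequency_per_day=freq, duration=dur))
        elif dose.kind == "fluid_bolus":
            amount = dose.target * weight * rng.uniform(0.85, 1.15)
            window = fr.window_hours or 1.0
            out.append(Prescription(drug=spec.drug, role=role, route=route,
                                    dose_amount=round(amount, 1), dose_units="ml",
                                    infusion_time_hours=round(0.75 * window, 2),
                                    frequency_per_day=freq, duration=dur))
        else:  # fluid_total
            total = dose.target * weight * rng.uniform(0.9, 1.1)
            window = dose.window_hours
            if window is not None and dose.window_hours_under_1y is not None and age_months < 12:
                window = dose.window_hours_under_1y
            if fr.kind == "steps_used":
                parts = (0.3, 0.7)
                roles = (Role.step1, Role.step2)
                times = (0.25 * window, 0.6 * window) if window else (None, None)
                for part, r, t in zip(parts, roles, times):
                    out.append(Prescription(drug=spec.drug, role=r, route=route,
                                            dose_amount=round(total * part, 1), dose_units="ml",
                                            infusion_time_hours=round(t, 2) if t else None,
                                            frequency_per_day=freq, duration=dur))
            else:
                t = None
                if fr.kind == "min_within_window":
                    t = 0.5 * fr.window_hours
                elif window is not None:
                    t = 0.8 * window
                out.append(Prescription(drug=spec.drug, role=role, route=route,
                                        dose_amount=round(total, 1), dose_units="ml",
                                        infusion_time_hours=t,
                                        frequency_per_day=freq, duration=dur))
    return out


def _spoil_use(
    rx: list[Prescription], specs: Sequence[DrugSpec], rng: np.random.Generator
) -> list[Prescription]:
    """Apply one correct-use violation from the catalogue to an otherwise
    adherent prescription list."""
    applicable = []
    for v in USE_VIOLATIONS:
        if v == "bad_dose" and any(s.dose is not None for s in specs):
            applicable.append(v)
        elif v == "wrong_route" and any(s.routes for s in specs):
            applicable.append(v)
        elif v == "wrong_frequency" and any(s.frequency.kind != "none" for s in specs):
            applicable.append(v)
        elif v == "missing_duration" and any(s.duration.kind != "none" for s in specs):
            applicable.append(v)
    choice = applicable[int(rng.integers(len(applicable)))]

    def pick(pred) -> Optional[str]:
        for s in specs:
            if pred(s):
                return s.drug
        return None

    if choice == "bad_dose":
        # scale every administration of the dosed drug so split fluid plans
        # go out of tolerance as a whole, not just one part
        drug = pick(lambda s: s.dose is not None)
        return [p.model_copy(update={"dose_amount": round(p.dose_amount * 1.6, 2)})
                if p.drug == drug and p.dose_amount is not None else p for p in rx]
    if choice == "wrong_route":
        spec = next(s for s in specs if s.routes)
        wrong = Route.oral if Route.oral not in spec.routes else Route.iv
        return [p.model_copy(update={"route": wrong}) if p.drug == spec.drug else p
                for p in rx]
    if choice == "wrong_frequency":
        spec = next(s for s in specs if s.frequency.kind != "none")
        kind = spec.frequency.kind
        out = []
        for p in rx:
            if p.drug != spec.drug:
                out.append(p)
            elif kind == "exact":
                out.append(p.model_copy(update={"frequency_per_day": spec.frequency.per_day + 2}))
            elif kind == "any_specified":
                out.append(p.model_copy(update={"frequency_per_day": None}))
            elif kind == "min_within_window":
                out.append(p.model_copy(update={"infusion_time_hours": spec.frequency.window_hours * 3}))
            else:  # steps_used: the step plan structure must be absent entirely
                out.append(p.model_copy(update={"role": Role.single}))
        return out
    # missing_duration
    spec = next(s for s in specs if s.duration.kind != "none")
    return [p.model_copy(update={"duration": None}) if p.drug == spec.drug else p
            for p in rx]


def _wrong_drug(
    disease: str, classification: str, other_disease_drugs: set[str]
) -> Optional[str]:
    for cand in WRONG_DRUG_PREFERENCE[(disease, classification)]:
        if cand not in other_disease_drugs:
            return cand
    return None


class _Realiser:
    """Builds one record's documentation/diagnoses/prescriptions from the
    drawn per-disease item vectors."""

    def __init__(self, codebook: GuidelineCodebook, rng: np.random.Generator):
        self.cb = codebook
        self.rng = rng
        self.doc: set[str] = set()
        self.ban: set[str] = set()
        self.diagnoses: dict[str, str] = {}
        self.prescriptions: list[Prescription] = []
        self.conflicts = 0

    def realise(
        self,
        drawn: dict[str, dict[str, int]],  # disease -> item -> 0/1
        severity: dict[str, str],
        weight: float,
        age_months: float,
    ) -> None:
        # adherent documentation first, then violations against what is pledged
        for d, items in drawn.items():
            rules = self.cb.diseases[d]
            branch = severity[d] if items["classification"] else rules.complete_branch
            if items["complete_assessment"]:
                self.doc |= set(rules.complete_items)
            else:
                if items["primary_signs"]:
                    s = satisfying_set(rules.primary_signs, frozenset(self.ban))
                    self.doc |= s if s is not None else satisfying_set(rules.primary_signs) or set()
                if items["secondary_signs"]:
                    expr = rules.secondary_signs[branch]
                    s = satisfying_set(expr, frozenset(self.ban))
                    self.doc |= s if s is not None else satisfying_set(expr) or set()
        for d, items in drawn.items():
            rules = self.cb.diseases[d]
            branch = severity[d] if items["classification"] else rules.complete_branch
            if not items["primary_signs"]:
                self._violate(rules.primary_signs)
            if not items["secondary_signs"]:
                self._violate(rules.secondary_signs[branch])
            if not items["complete_assessment"]:
                candidates = [s for s in rules.complete_items if s not in self.doc]
                if candidates:
                    self.ban.add(candidates[int(self.rng.integers(len(candidates)))])
                else:
                    self.conflicts += 1
            self._realise_treatment(d, items, severity[d], weight, age_months)

    def _violate(self, expr) -> None:
        v = violating_set(expr, frozenset(self.doc))
        if v is None:
            self.conflicts += 1
        else:
            self.ban |= v

    def _realise_treatment(self, disease, items, true_cls, weight, age_months) -> None:
        rules = self.cb.diseases[disease]
        if items["classification"]:
            aliases = rules.classifications[true_cls]
            self.diagnoses[disease] = aliases[0]
        else:
            how = CLASSIFICATION_VIOLATIONS[int(self.rng.integers(len(CLASSIFICATION_VIOLATIONS)))]
            self.diagnoses[disease] = "" if how == "missing" else _UNRECOGNISED_WORDING[disease]

        rule = rules.treatments[true_cls]
        dset = rule.drug_sets[int(self.rng.integers(len(rule.drug_sets)))]
        prescribe_anyway = (
            not items["classification"]
            and self.rng.random() < self._p_treat_without_classification
        )
        if items["drug_choice"] or prescribe_anyway:
            rx = _adherent_prescriptions(dset.drugs, weight, age_months, self.rng)
            if (items["drug_choice"] and not items["correct_use"]) or prescribe_anyway:
                if not items["correct_use"]:
                    rx = _spoil_use(rx, dset.drugs, self.rng)
            self.prescriptions.extend(rx)
        elif items["classification"]:
            # classification made but wrong/no drug: draw a drug-choice violation
            other_drugs = {
                s.drug
                for d2, c2 in self._co_classifications.items()
                if d2 != disease
                for ds in self.cb.diseases[d2].treatments[c2].drug_sets
                for s in ds.drugs
            }
            options = ["none"]
            if _wrong_drug(disease, true_cls, other_drugs):
                options.append("wrong_drug")
            if len(dset.drugs) > 1:
                options.append("incomplete_set")
            if dset.forbidden:
                options.append("forbidden_extra")
            choice = options[int(self.rng.integers(len(options)))]
            if choice == "wrong_drug":
                drug = _wrong_drug(disease, true_cls, other_drugs)
                self.prescriptions.append(Prescription(
                    drug=drug, route=Route.oral, dose_amount=1.0, dose_units=None,
                    frequency_per_day=2, duration="3 days"))
            elif choice == "incomplete_set":
                rx = _adherent_prescriptions(dset.drugs[:-1], weight, age_months, self.rng)
                self.prescriptions.extend(rx)
            elif choice == "forbidden_extra":
                rx = _adherent_prescriptions(dset.drugs, weight, age_months, self.rng)
                rx.append(Prescription(drug=dset.forbidden[0], route=Route.im,
                                       dose_amount=7.5 * weight, dose_units="mg",
                                       frequency_per_day=1, duration="5 days"))
                self.prescriptions.extend(rx)

    # populated by generate_cohort before realise()
    _co_classifications: dict[str, str] = {}
    _p_treat_without_classification: float = 0.0


# ---------------------------------------------------------------------------


def generate_cohort(
    config: SimulationConfig, codebook: Optional[GuidelineCodebook] = None
) -> list[CaseRecord]:
    """Generate the configured cohort; reproducible given ``config.seed``."""
    cb = codebook or load_codebook()
    effects = hospital_effects(config)
    categories = list(config.disease_mix)
    cat_p = np.array([config.disease_mix[c] for c in categories])

    records: list[CaseRecord] = []
    idx = 0
    for h in range(config.n_hospitals):
        hospital_id = f"H{h + 1:02d}"
        arm = config.arms[h % 2]
        for s_idx, survey in enumerate(config.surveys):
            probs = resolved_item_probs(config, arm, s_idx, effects[h])
            for _ in range(config.n_per_hospital_per_survey):
                rec_rng = np.random.default_rng([config.seed, 1, idx])
                real_rng = np.random.default_rng([config.seed, 2, idx])
                cat = categories[rec_rng.choice(len(categories), p=cat_p)]
                diseases = cat.split("+")
                age = float(rec_rng.uniform(*config.age_months_range))
                # median-for-age growth curve with log-normal spread, floored
                # at 5 kg (severely malnourished children are out of scope of
                # the weight-band dose tables)
                median_w = 2.9 + 6.8 * math.sqrt(age / 12.0)
                weight = round(max(5.0, median_w * math.exp(rec_rng.normal(0.0, 0.11))), 1)
                severity = {}
                for d in diseases:
                    grades = list(config.severity_probs[d])
                    gp = np.array([config.severity_probs[d][g] for g in grades])
                    severity[d] = grades[rec_rng.choice(len(grades), p=gp)]
                drawn = {}
                for d in diseases:
                    if config.latent_rho > 0:
                        shared = rec_rng.normal()
                        z = (math.sqrt(config.latent_rho) * shared
                             + math.sqrt(1 - config.latent_rho) * rec_rng.normal(size=6))
                        u = _norm_cdf(z)
                    else:
                        u = rec_rng.random(6)
                    drawn[d] = _chain_draws(u, probs)

                realiser = _Realiser(cb, real_rng)
                realiser._co_classifications = severity
                realiser._p_treat_without_classification = config.p_treat_without_classification
                realiser.realise(drawn, severity, weight, age)

                free = [s for s in cb.signs
                        if s not in realiser.doc and s not in realiser.ban]
                extra = {s for s in free
                         if real_rng.random() < config.extra_documentation_p}
                signs = {}
                for s in sorted(realiser.doc | extra):
                    if s == "respiratory_rate":
                        signs[s] = Documentation(status=DocStatus.documented_value,
                                                 quantity=float(real_rng.integers(20, 70)))
                    else:
                        status = (DocStatus.documented_present
                                  if real_rng.random() < 0.5 else DocStatus.documented_absent)
                        signs[s] = Documentation(status=status)

                records.append(CaseRecord(
                    record_id=f"R{idx + 1:06d}",
                    hospital_id=hospital_id,
                    clinician_id=f"{hospital_id}-C{int(rec_rng.integers(1, 6))}",
                    arm=Arm(arm) if arm in Arm.__members__ else Arm.unknown,
                    survey=survey,
                    age_months=round(age, 1),
                    weight_kg=weight,
                    signs=signs,
                    diagnoses=realiser.diagnoses,
                    prescriptions=tuple(realiser.prescriptions),
                ))
                idx += 1
    return records


def _norm_cdf(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.vectorize(math.erf)(z / math.sqrt(2.0)))


def adherence_recovery_report(
    cohort: list[CaseRecord],
    config: SimulationConfig,
    codebook: Optional[GuidelineCodebook] = None,
) -> pd.DataFrame:
    """Observed vs target patient-level item proportions.

    The target for a record is the product over its diagnosed diseases of
    the resolved per-item probability (independent per-disease draws and
    all-or-none combination), averaged over the cohort.
    """
    cb = codebook or load_codebook()
    effects = hospital_effects(config)
    hospital_index = {f"H{h + 1:02d}": h for h in range(config.n_hospitals)}
    survey_index = {s: i for i, s in enumerate(config.surveys)}

    scores, _ = score_cohort(cohort, cb)
    by_id = {s.record_id: s for s in scores}

    rows = {item: {"observed": 0.0, "target": 0.0, "n": 0} for item in ITEM_NAMES}
    for rec in cohort:
        score = by_id.get(rec.record_id)
        if score is None:
            continue
        probs = resolved_item_probs(
            config, rec.arm.value, survey_index[rec.survey],
            effects[hospital_index[rec.hospital_id]],
        )
        k = len(rec.diseases)
        for item in ITEM_NAMES:
            rows[item]["observed"] += getattr(score.combined, item)
            rows[item]["target"] += probs[item] ** k
            rows[item]["n"] += 1
    out = pd.DataFrame(rows).T
    out["observed"] /= out["n"]
    out["target"] /= out["n"]
    out["n"] = out["n"].astype(int)
    return out[["observed", "target", "n"]]


def latent_binary_pairs(
    n: int, rho: float, p_x: float, p_y: float, seed: int
) -> np.ndarray:
    """(n, 2) binary draws dichotomised from a bivariate normal with
    correlation ``rho`` at thresholds matching the marginal probabilities —
    ground truth for tetrachoric recovery checks."""
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.normal(size=n)
    from scipy.stats import norm

    x = (z1 > norm.ppf(1.0 - p_x)).astype(int)
    y = (z2 > norm.ppf(1.0 - p_y)).astype(int)
    return np.column_stack([x, y])
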
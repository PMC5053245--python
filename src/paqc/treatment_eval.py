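"""Evaluation of prescriptions against classification-specific treatment rules.

Three families of dose rule appear in the guidelines:

* per-kg targets with a relative tolerance ("20 mg/kg loading, 10 mg/kg
  maintenance, deviations of up to 20% are correct") — bounds inclusive;
* weight-band tablet tables (artemether-lumefantrine style);
* fluid plans, either per-bolus (shock: each bolus 20 ml/kg) or total
  volume over an age-dependent time window (rehydration plans).

``check_correct_use`` combines these with route, frequency and duration
constraints into the two PAQC treatment items (drug choice, correct use);
``evaluate_aspects`` exposes the itemised per-aspect verdicts the basic
additive score needs.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

from .codebook import DoseRule, DrugSet, DrugSpec, FrequencyRule, TreatmentRule
from .errors import (
    UnitMismatchError,
    W_DUPLICATE_RX,
    W_MISSING_WEIGHT,
    W_OUT_OF_BAND,
    warn,
)
from .model import Prescription

#: duration wordings accepted as a stat (single, immediate) dose
_STAT_WORDS = {"stat", "single", "once", "single dose"}

_UNIT_ALIASES = {
    "mg": "mg",
    "milligram": "mg",
    "milligrams": "mg",
    "iu": "iu",
    "units": "iu",
    "u": "iu",
    "tab": "tablets",
    "tabs": "tablets",
    "tablet": "tablets",
    "tablets": "tablets",
    "ml": "ml",
    "millilitre": "ml",
    "millilitres": "ml",
}


def _norm_units(units: Optional[str]) -> Optional[str]:
    if units is None:
        return None
    key = units.strip().lower()
    return _UNIT_ALIASES.get(key, key)


def _require_units(prescribed_units: Optional[str], rule_units: Optional[str]) -> None:
    pu, ru = _norm_units(prescribed_units), _norm_units(rule_units)
    if pu is not None and ru is not None and pu != ru:
        raise UnitMismatchError(f"dose units {prescribed_units!r} incompatible with rule units {rule_units!r}")


def check_dose_per_kg(
    prescribed: Optional[float],
    weight_kg: Optional[float],
    rule: DoseRule,
    units: Optional[str] = None,
) -> int:
    """1 iff the prescribed amount lies within the tolerance band around
    ``target * weight``, bounds inclusive."""
    if rule.kind != "per_kg":
        raise ValueError(f"rule kind {rule.kind!r}, expected per_kg")
    _require_units(units, rule.units)
    if weight_kg is None:
        warn(W_MISSING_WEIGHT, "per-kg dose rule applies but weight is missing; scored 0")
        return 0
    if prescribed is None:
        return 0
    lo = rule.target * weight_kg * (1.0 - rule.tolerance)
    hi = rule.target * weight_kg * (1.0 + rule.tolerance)
    return int(lo <= prescribed <= hi)


def check_weight_band(
    prescribed_tablets: Optional[float],
    weight_kg: Optional[float],
    rule: DoseRule,
) -> int:
    """1 iff the tablet count equals the count demanded by the weight band."""
    if rule.kind != "weight_band":
        raise ValueError(f"rule kind {rule.kind!r}, expected weight_band")
    if weight_kg is None:
        warn(W_MISSING_WEIGHT, "weight-band dose rule applies but weight is missing; scored 0")
        return 0
    if prescribed_tablets is None:
        return 0
    for lo, hi, tabs in rule.bands:
        if weight_kg >= lo and (hi is None or weight_kg <= hi):
            return int(prescribed_tablets == tabs)
    warn(W_OUT_OF_BAND, f"weight {weight_kg} kg outside the band table; scored 0")
    return 0


def check_fluid_plan(
    prescriptions: Sequence[Prescription],
    weight_kg: Optional[float],
    age_months: Optional[float],
    rule: DoseRule,
) -> int:
    """Fluid dose verdict for a bolus or total-volume plan.

    Per-bolus plans check every administration against the per-kg target;
    total plans check the summed volume, and — when the rule states a time
    window — that the summed administration time fits the age-appropriate
    window (3 h over 1 year, 6 h under, for the rehydration plan).
    """
    if rule.kind not in ("fluid_bolus", "fluid_total"):
        raise ValueError(f"rule kind {rule.kind!r}, expected a fluid rule")
    if weight_kg is None:
        warn(W_MISSING_WEIGHT, "fluid dose rule applies but weight is missing; scored 0")
        return 0
    rx = [p for p in prescriptions if p.dose_amount is not None]
    for p in rx:
        _require_units(p.dose_units, rule.units)
    if not rx:
        return 0
    if rule.max_administrations is not None and len(rx) > rule.max_administrations:
        return 0
    tol = rule.tolerance
    lo, hi = 1.0 - tol, 1.0 + tol
    per_kg_target = rule.target * weight_kg
    if rule.kind == "fluid_bolus":
        return int(all(lo * per_kg_target <= p.dose_amount <= hi * per_kg_target for p in rx))
    total = sum(p.dose_amount for p in rx)
    if not (lo * per_kg_target <= total <= hi * per_kg_target):
        return 0
    window = rule.window_hours
    if window is not None:
        if rule.window_hours_under_1y is not None and age_months is not None and age_months < 12:
            window = rule.window_hours_under_1y
        times = [p.infusion_time_hours for p in rx]
        if any(t is None for t in times):
            return 0
        if sum(times) > window:
            return 0
    return 1


def _check_dose(spec: DrugSpec, rx: Sequence[Prescription], weight_kg, age_months) -> int:
    rule = spec.dose
    if rule is None:
        return 1
    if rule.kind == "per_kg":
        p = rx[0]
        return check_dose_per_kg(p.dose_amount, weight_kg, rule, units=p.dose_units)
    if rule.kind == "weight_band":
        p = rx[0]
        _require_units(p.dose_units, rule.units)
        return check_weight_band(p.dose_amount, weight_kg, rule)
    return check_fluid_plan(rx, weight_kg, age_months, rule)


def _check_frequency(rule: FrequencyRule, rx: Sequence[Prescription]) -> int:
    if rule.kind == "none":
        return 1
    if rule.kind == "exact":
        return int(bool(rx) and all(p.frequency_per_day == rule.per_day for p in rx))
    if rule.kind == "any_specified":
        return int(any(p.frequency_per_day is not None for p in rx))
    if rule.kind == "min_within_window":
        n = sum(1 for p in rx if p.infusion_time_hours is not None and p.infusion_time_hours <= rule.window_hours)
        return int(n >= rule.min_count)
    # steps_used: the step-1/step-2 plan structure must be used
    return int(any(p.role.value in ("step1", "step2") for p in rx))


def _check_duration(spec: DrugSpec, rx: Sequence[Prescription]) -> int:
    kind = spec.duration.kind
    if kind == "none":
        return 1
    if kind == "any_specified":
        return int(all(p.duration is not None and str(p.duration).strip() != "" for p in rx))
    return int(all(p.duration is not None and str(p.duration).strip().lower() in _STAT_WORDS for p in rx))


def _check_route(spec: DrugSpec, rx: Sequence[Prescription]) -> int:
    if spec.routes is None:
        return 1
    return int(all(p.route in spec.routes for p in rx))


def select_prescriptions(
    prescriptions: Iterable[Prescription], spec: DrugSpec
) -> list[Prescription]:
    """Prescriptions matching a drug spec.

    For non-fluid rules the first prescription per (drug, role) in input
    order is evaluated; duplicates are kept only for fluid plans (where
    repeated administrations are the plan) and otherwise warned about.
    """
    matched = [
        p for p in prescriptions
        if p.drug == spec.drug and (spec.role is None or p.role.value == spec.role)
    ]
    if spec.dose is not None and spec.dose.kind in ("fluid_bolus", "fluid_total"):
        return matched
    seen: dict[tuple[str, str], Prescription] = {}
    for p in matched:
        key = (p.drug, p.role.value)
        if key in seen:
            warn(W_DUPLICATE_RX, f"duplicate prescription for {key}; first kept")
        else:
            seen[key] = p
    return list(seen.values())


def _set_satisfied(prescriptions: Sequence[Prescription], dset: DrugSet) -> bool:
    drugs_present = {p.drug for p in prescriptions}
    if any(f in drugs_present for f in dset.forbidden):
        return False
    return all(select_prescriptions(prescriptions, spec) for spec in dset.drugs)


def choose_drug_set(
    prescriptions: Sequence[Prescription], rule: TreatmentRule
) -> tuple[Optional[DrugSet], bool]:
    """(best-matching allowed set, fully satisfied?).

    A fully prescribed, non-voided set wins; otherwise the set with the
    most matching drugs is returned so itemised aspects can still be
    evaluated on whatever was prescribed.
    """
    best, best_n = None, -1
    for dset in rule.drug_sets:
        if _set_satisfied(prescriptions, dset):
            return dset, True
        n = sum(1 for spec in dset.drugs if select_prescriptions(prescriptions, spec))
        if n > best_n:
            best, best_n = dset, n
    return best, False


def evaluate_aspects(
    prescriptions: Sequence[Prescription],
    rule: TreatmentRule,
    weight_kg: Optional[float],
    age_months: Optional[float],
) -> dict[str, int]:
    """Itemised treatment indicators for the basic additive score.

    ``drug`` is 1 iff an allowed combination is fully prescribed (and no
    forbidden co-prescription voids it). Each other aspect is 1 iff it is
    constrained by the rule, at least one relevant prescription exists,
    and every relevant prescription satisfies it. Aspects the rule does
    not constrain are absent from the result (structurally not scored).
    """
    dset, satisfied = choose_drug_set(prescriptions, rule)
    out: dict[str, int] = {"drug": int(satisfied)}
    aspects = rule.applicable_aspects()
    checks = {
        "route": _check_route,
        "duration": _check_duration,
    }
    for aspect in aspects:
        if aspect == "drug":
            continue
        verdicts: list[int] = []
        for spec in dset.drugs if dset else ():
            rx = select_prescriptions(prescriptions, spec)
            if not rx:
                verdicts.append(0)
                continue
            if aspect == "dose":
                verdicts.append(_check_dose(spec, rx, weight_kg, age_months))
            elif aspect == "frequency":
                verdicts.append(_check_frequency(spec.frequency, rx))
            else:
                verdicts.append(checks[aspect](spec, rx))
        out[aspect] = int(bool(verdicts) and all(verdicts))
    return out


def check_correct_use(
    prescriptions: Sequence[Prescription],
    classification: str,
    weight_kg: Optional[float],
    age_months: Optional[float],
    rule: TreatmentRule,
) -> tuple[int, int]:
    """PAQC treatment items: (drug_choice, correct_use).

    drug_choice is 1 iff some allowed drug combination is fully prescribed
    (exclusions respected); correct_use additionally requires every
    applicable constraint to pass for every drug in the satisfied set.
    """
    del classification  # resolved by the caller; kept for interface clarity
    drug_choice = 0
    for dset in rule.drug_sets:
        if not _set_satisfied(prescriptions, dset):
            continue
        drug_choice = 1
        ok = True
        for spec in dset.drugs:
            rx = select_prescriptions(prescriptions, spec)
            if not rx or not (
                _check_route(spec, rx)
                and _check_dose(spec, rx, weight_kg, age_months)
                and _check_frequency(spec.frequency, rx)
                and _check_duration(spec, rx)
            ):
                ok = False
                break
        if ok:
            return 1, 1
    return drug_choice, 0
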
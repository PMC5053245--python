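"""Independent brute-force oracles used by the test suite.

These re-derive results literally from first principles (the codebook
*data*, not the scoring code): a rule-by-rule PAQC item scorer written as
straight-line checks, and a grid-search maximiser of the tetrachoric
likelihood. They intentionally share no control flow with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np

from paqc.codebook import GuidelineCodebook
from paqc.model import CaseRecord, Prescription
from paqc.psychometrics import FourfoldTable, table_loglik


# ---------------------------------------------------------------------------
# literal PAQC item derivation


def _truth(expr, documented: set[str]) -> bool:
    if isinstance(expr, str):
        return expr in documented
    ((op, args),) = expr.items()
    results = [_truth(a, documented) for a in args]
    return any(results) if op == "any" else all(results)


def _all_expr_signs(expr) -> set[str]:
    if isinstance(expr, str):
        return {expr}
    ((_, args),) = expr.items()
    out = set()
    for a in args:
        out |= _all_expr_signs(a)
    return out


def _match_classification(rules, recorded: str | None) -> str | None:
    if not recorded:
        return None
    norm = " ".join(recorded.lower().replace("-", " ").replace("_", " ").split())
    for name, aliases in rules.classifications.items():
        candidates = [name] + list(aliases)
        for cand in candidates:
            if norm == " ".join(cand.lower().replace("-", " ").replace("_", " ").split()):
                return name
    return None


def _first_per_role(prescriptions, drug: str, role: str | None) -> list[Prescription]:
    seen = {}
    for p in prescriptions:
        if p.drug != drug:
            continue
        if role is not None and p.role.value != role:
            continue
        key = p.role.value
        if key not in seen:
            seen[key] = p
    return list(seen.values())


def _dose_ok(spec, matched, weight, age_months) -> bool:
    rule = spec.dose
    if rule is None:
        return True
    if weight is None:
        return False
    if rule.kind == "per_kg":
        p = matched[0]
        if p.dose_amount is None:
            return False
        lo = rule.target * weight * (1 - rule.tolerance)
        hi = rule.target * weight * (1 + rule.tolerance)
        return lo <= p.dose_amount <= hi
    if rule.kind == "weight_band":
        p = matched[0]
        if p.dose_amount is None:
            return False
        for b_lo, b_hi, tabs in rule.bands:
            if weight >= b_lo and (b_hi is None or weight <= b_hi):
                return p.dose_amount == tabs
        return False
    # fluid rules: every administration of the drug counts
    admins = [p for p in matched if p.dose_amount is not None]
    if not admins:
        return False
    if rule.max_administrations is not None and len(admins) > rule.max_administrations:
        return False
    ref = rule.target * weight
    if rule.kind == "fluid_bolus":
        return all(ref * (1 - rule.tolerance) <= p.dose_amount <= ref * (1 + rule.tolerance)
                   for p in admins)
    total = sum(p.dose_amount for p in admins)
    if not (ref * (1 - rule.tolerance) <= total <= ref * (1 + rule.tolerance)):
        return False
    window = rule.window_hours
    if window is not None:
        if rule.window_hours_under_1y is not None and age_months is not None and age_months < 12:
            window = rule.window_hours_under_1y
        if any(p.infusion_time_hours is None for p in admins):
            return False
        if sum(p.infusion_time_hours for p in admins) > window:
            return False
    return True


def _freq_ok(spec, matched) -> bool:
    fr = spec.frequency
    if fr.kind == "none":
        return True
    if fr.kind == "exact":
        return len(matched) > 0 and all(p.frequency_per_day == fr.per_day for p in matched)
    if fr.kind == "any_specified":
        return any(p.frequency_per_day is not None for p in matched)
    if fr.kind == "min_within_window":
        good = [p for p in matched
                if p.infusion_time_hours is not None and p.infusion_time_hours <= fr.window_hours]
        return len(good) >= fr.min_count
    return any(p.role.value in ("step1", "step2") for p in matched)


def _duration_ok(spec, matched) -> bool:
    if spec.duration.kind == "none":
        return True
    for p in matched:
        if p.duration is None or not str(p.duration).strip():
            return False
        if spec.duration.kind == "stat":
            if str(p.duration).strip().lower() not in ("stat", "single", "once", "single dose"):
                return False
    return True


def _matched_for(spec, prescriptions):
    if spec.dose is not None and spec.dose.kind in ("fluid_bolus", "fluid_total"):
        return [p for p in prescriptions
                if p.drug == spec.drug and (spec.role is None or p.role.value == spec.role)]
    return _first_per_role(prescriptions, spec.drug, spec.role)


def paqc_items_literal(
    record: CaseRecord, disease: str, cb: GuidelineCodebook
) -> tuple[int, int, int, int, int, int]:
    """The six PAQC items re-derived literally from the codebook data."""
    rules = cb.diseases[disease]
    documented = {s for s in cb.signs
                  if s in record.signs and record.signs[s].status.value != "not_documented"}

    primary = int(_truth(rules.primary_signs, documented))

    cls = _match_classification(rules, record.diagnoses.get(disease))
    branch = cls if cls is not None else rules.complete_branch
    secondary = int(_truth(rules.secondary_signs[branch], documented))

    needed = set(rules.assessment_items) | _all_expr_signs(rules.primary_signs)
    for expr in rules.secondary_signs.values():
        needed |= _all_expr_signs(expr)
    complete = int(needed <= documented)

    classification = int(cls is not None)
    drug_choice = correct_use = 0
    if cls is not None:
        rule = rules.treatments[cls]
        drugs_present = {p.drug for p in record.prescriptions}
        for dset in rule.drug_sets:
            if any(f in drugs_present for f in dset.forbidden):
                continue
            matches = [_matched_for(spec, record.prescriptions) for spec in dset.drugs]
            if not all(matches):
                continue
            drug_choice = 1
            ok = True
            for spec, matched in zip(dset.drugs, matches):
                if spec.routes is not None and any(p.route not in spec.routes for p in matched):
                    ok = False
                if not _dose_ok(spec, matched, record.weight_kg, record.age_months):
                    ok = False
                if not _freq_ok(spec, matched):
                    ok = False
                if not _duration_ok(spec, matched):
                    ok = False
            if ok:
                correct_use = 1
                break
    return (primary, secondary, complete, classification, drug_choice, correct_use)


def patient_items_literal(record: CaseRecord, cb: GuidelineCodebook) -> tuple[int, ...]:
    per = [paqc_items_literal(record, d, cb) for d in record.diseases]
    return tuple(min(vals) for vals in zip(*per))


# ---------------------------------------------------------------------------
# tetrachoric grid-search oracle


def grid_tetrachoric(table: FourfoldTable, step: float = 1e-4) -> float:
    """Brute-force maximiser of the tetrachoric likelihood over
    rho in [-0.999, 0.999]."""
    grid = np.arange(-0.999, 0.999 + step / 2, step)
    ll = table_loglik(table, grid)
    return float(grid[int(np.argmax(ll))])
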
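# Methods

## The measure

Admission care for children aged 1–59 months with malaria, pneumonia or
diarrhoea/dehydration is assessed against national clinical-practice
guidelines along three process domains: **assessment** (documentation of
recommended signs and symptoms), **diagnosis** (recording a
guideline-recognised severity classification) and **treatment**
(prescribing the recommended drugs correctly for that severity).

Two scoring systems are implemented.

**Basic additive score.** Every itemised indicator is summed: 8
assessment-documentation items per disease, 1 classification item, and
itemised treatment indicators — drug, route, dose, frequency, duration
for malaria and pneumonia (5), and drug, dose, frequency for
diarrhoea/dehydration, whose guideline rules carry no route or duration
constraint (3). The resulting scales are 0–14 (malaria, pneumonia) and
0–12 (diarrhoea/dehydration). The scheme is retained deliberately: it is
dominated by the assessment domain (8 of 14 points), its ranges are not
comparable across diseases, and its items are mutually redundant — the
deficiencies that motivate the PAQC score and that the psychometric
module is designed to expose.

**PAQC score.** Six binary items per disease, grouped

| domain | items | range |
|---|---|---|
| D1 assessment | primary signs; secondary (danger) signs; complete assessment | 0–3 |
| D2 diagnosis | valid severity classification | 0–1 |
| D3 treatment | correct drug choice; correct use | 0–2 |

giving a 7-point scale, Q = D1 + D2 + D3 ∈ [0, 6], identical across
diseases. With multimorbidity each patient-level item is the logical AND
of that item over the diagnosed diseases (all-or-none combination), so Q
remains an integer count of fully completed care tasks and is bounded by
the smallest disease-specific sum.

### Item semantics and the open design choices

*Documentation, not clinical truth.* A sign documented as present,
absent, or with a value counts identically; only absence of
documentation scores 0.

*Secondary signs branch on severity.* A severe-type classification
(severe malaria, very severe pneumonia, shock) is justified by at least
one documented danger sign; a non-severe claim requires documentation of
**all** danger signs, because the clinician must positively exclude them.
When the record carries no valid classification the scorer defaults to
the demanding complete-documentation branch
(`secondary_branch="complete"`): without a severity claim, only full
danger-sign work-up demonstrates adequate assessment. `"any"` and
`"zero"` are available for sensitivity analyses.

*Complete assessment.* Scored 1 when the disease's 8 assessment items
**and** every sign referenced by its primary/secondary rules are
documented. The guideline wording for malaria's danger signs cites
grunting (a pneumonia-list sign) and pneumonia's cites acidotic
breathing (a malaria-list sign); widening the complete-assessment set to
include these cross-list signs (9 for malaria and pneumonia, 8 for
diarrhoea) preserves the hierarchy invariant that complete documentation
implies the primary and secondary items score 1. The 8-item lists, their
19-sign union and the basic score's assessment count are unaffected.

*Treatment conditioning.* Drug choice and correct use are evaluated
against the treatment rule of the **recorded** classification and score
0 when no valid classification exists — drug correctness is only defined
relative to an indicated severity. This encodes the perfect coupling
between the classification and drug-choice indicators as a structural
invariant (`drug_choice ≤ classification`), not an empirical finding.

*Ambiguous guideline phrasings* are resolved in the shipped codebook
file, not in code, so alternative readings need no code change:
"pallor in the presence of grunting or indrawing" is one composite
danger element `pallor AND (grunting OR indrawing)`; the
severe-dehydration plan's "70 mg/kg" is transcribed as 70 ml/kg (units
typo; the 30 + 70 ml/kg rehydration plan); "at least 1 in an 24 h" is
encoded as ≥1 administration within 24 hours; "vol/time ×4" permits up
to 4 administrations of the fluid plan.

## Treatment evaluation

Dose rules come in three families, all data-driven from the codebook:

* **per-kg targets** with a relative tolerance (default 0.20 — deviations
  of up to 20% of the per-kg recommendation are correct); bounds are
  inclusive, since "up to 20%" naturally includes the endpoint and
  inclusive bounds make boundary tests exact;
* **weight-band tablet tables** (artemether-lumefantrine style); the band
  edges are transcribed exactly as printed, including the 24.5–25 kg gap
  in the source table (weights in a gap score 0 with an `W_OUT_OF_BAND`
  warning);
* **fluid plans**: per-bolus checks (shock: every bolus within ±20% of
  20 ml/kg, at most 4 boluses, at least one within an hour) and
  total-volume checks over an age-dependent window (severe dehydration:
  100 ml/kg in 3 h over 1 year of age, 6 h under — the age boundary at
  exactly 12 months is assigned to the faster window).

"Any specified" frequency/duration constraints pass iff the field is
non-missing; oxygen has no dose rule and is checked on frequency and
duration only. Missing weight where a per-kg rule applies scores the dose
indicator 0 and emits `W_MISSING_WEIGHT`; duplicate prescriptions of the
same (drug, role) keep the first in input order and emit
`W_DUPLICATE_RX`. For drug choice, an allowed combination must be fully
prescribed and no excluded co-prescription present ("penicillin only, no
gentamicin"); partial combinations earn nothing — the stricter reading of
"singly or in recommended combinations".

## Tetrachoric diagnostics

Redundancy screening uses the tetrachoric correlation: the correlation
of the latent bivariate normal assumed to underlie two dichotomised
items. The estimator is the standard two-step maximum-likelihood
procedure — thresholds fixed at the inverse-normal transforms of the
marginal proportions, multinomial likelihood of the 2×2 table maximised
over ρ alone (bounded scalar optimisation, absolute tolerance 1e-6,
estimates clamped to ±0.9999). Quadrant probabilities are evaluated via
Owen's T function, which makes the likelihood vectorisable over ρ; a
unit test checks the orthant probability against scipy's bivariate
normal integration to ~1e-10, and the test suite confirms the maximiser
against a brute-force grid search of the same likelihood (step 1e-4).
Tables with a zero cell receive a 0.5 continuity correction on every
cell (conventional; prevents divergence to ±1 — with the correction the
likelihood maximum for a perfect table is interior, near 0.9995).
Tables with an empty margin have no information about ρ and are
signalled as undefined rather than guessed. Pairs with |ρ| > 0.80
("very strong" on Evans' verbal scale) are flagged as redundant, and
item correlation matrices are checked for positive semidefiniteness
(minimum eigenvalue ≥ −1e-8), the signature of linear dependency among
items.

## Synthetic cohorts

The generator emulates the structure of the kind of two-arm, pre/post
hospital-improvement trial the score was developed on: 8 hospitals split
between control and intervention arms, baseline and endline surveys, and
a default of 400 abstracted records per hospital per survey. Disease
categories (3 single + 4 multimorbidity) are drawn from a configurable
mix; severity grades per disease from configurable distributions; ages
uniform over 2–59 months; weights from a median-for-age growth curve
with log-normal spread, floored at 5 kg (severely malnourished children
are outside the weight-band dose tables' scope).

Each item's adherence probability is resolved on the logit scale:
baseline level + arm effect + survey effect + arm×survey interaction +
a hospital random intercept (SD 0.3 by default). Default baseline levels
are round, plausible values (primary 0.85, secondary 0.40, complete
0.20, classification 0.50, drug 0.30, use 0.20) with a null arm effect,
a modest secular trend (0.4 logits/survey) and a positive interaction
(0.7) — chosen once to mirror the qualitative pattern of a successful
intervention, deliberately not any published table of adherence levels.

Item draws are coupled down the score hierarchy so configured marginals
are reproduced exactly on single-diagnosis records: complete ⇒
secondary, primary (conditional probabilities (p−p_c)/(1−p_c) on the
non-complete branch) and use ⇒ drug ⇒ classification (conditionals
p_child/p_parent). This requires p_complete ≤ min(p_primary,
p_secondary) and p_use ≤ p_drug ≤ p_classification, validated at
configuration time; shared scalar covariate shifts preserve the
ordering. Adherent items are realised as concrete content (documentation
satisfying the boolean sign rules, a valid classification alias, doses
sampled inside the tolerance window); non-adherent items as a violation
drawn from an enumerated catalogue (missing/unrecognised classification
wording; absent, wrong, incomplete or forbidden-extra drug; out-of-window
dose, wrong route, wrong frequency, missing duration). An optional
exchangeable Gaussian copula (`latent_rho`) correlates the within-disease
item draws to exercise the tetrachoric estimator at a known ρ, and
`latent_binary_pairs` dichotomises an explicit bivariate normal for
recovery tests.

**What the generator does not emulate.** Items are independent across
diseases given covariates, but the two signs shared by all three
diseases (AVPU, ability to drink/breastfeed) create unavoidable
cross-disease leakage: documentation satisfying one illness's secondary
rule can satisfy a co-diagnosed illness's rule too, so multimorbidity
combined-item proportions run slightly (≲0.03) above the independence
product p^k. This is a property of the instrument, not a simulation
artefact; marginal-calibration checks therefore run on single-diagnosis
cohorts, and the multimorbidity regime is checked against the product
law with a sampling margin. Real abstraction data also carry
clinician-level clustering, missingness correlated with severity, and
transcription noise, none of which are modelled — passing tests show the
scoring pipeline is correct and the generator calibrated, not that any
particular adherence level is realistic.

## Aggregation and numerical conventions

Summaries (n, mean, median, IQR, per-item scored-1 proportions) are
computed per group with numpy's inclusive linear-interpolation quantile
convention, fixed so "median (IQR)" reports are bit-reproducible.
CSV output from the CLI rounds floats to 4 decimals; scoring is fully
deterministic, so simulate → score → report is byte-stable for a given
seed. Structured warnings carry stable codes (`W_MISSING_WEIGHT`,
`W_OUT_OF_BAND`, `W_DUPLICATE_RX`) and are echoed into the run manifest.

## Problem sizes

The test suite and the reproduction script use cohorts of 1 000 records
for the brute-force scoring equivalence, 10 000 for adherence-parameter
recovery (±0.02), 50 000 dichotomised pairs for tetrachoric consistency
(±0.03), 100 random 2×2 tables for the grid-search agreement (1e-3), and
2 000 records per arm×survey cell for the distribution-shift rank-sum
check — sizes at which the binomial sampling bounds comfortably cover the
stated tolerances.

## Known limitations

* The codebook transcribes one guideline edition; real audits must
  re-transcribe their own guidelines (the file format is the interface).
* The blood-test-for-malaria item scores documentation that the test was
  done; whether a result should be required is configurable in the
  codebook rather than decided here, as guidelines differ.
* No inferential statistics: proportional-odds modelling of score
  differences is intentionally out of scope (any ordinal regression
  package can consume the score CSVs).
* No weighting of items and no diagnostic-testing domain.
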
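# paqc — Paediatric Admission Quality of Care scoring

Hospital teams, programme managers and researchers auditing admission
care for sick children need a single, clinically meaningful number per
admission — not dozens of per-indicator percentages that cannot be
compared across illnesses or combined when a child has more than one.
`paqc` implements such a measure for the three diagnoses behind most
under-five admissions in low-income settings: malaria, pneumonia and
diarrhoea/dehydration.

## The score

Care is decomposed into three guideline domains. Per diagnosed disease,
six binary items are scored from the case record:

* **D1 assessment (0–3):** primary signs documented; secondary (danger)
  signs documented — at least one if a severe classification was made,
  *all* of them if a non-severe classification was claimed (danger signs
  must be positively excluded); complete documentation of all
  recommended signs;
* **D2 diagnosis (0–1):** a guideline-recognised severity classification
  recorded;
* **D3 treatment (0–2):** correct drug choice for that severity; correct
  use (route, dose within ±20% per kg, frequency, duration — whichever
  the guideline constrains).

The patient-level score is

```
Q = D1 + D2 + D3 ∈ {0, …, 6}
```

identical in range for every disease. Under multimorbidity each item is
combined **all-or-none** across the diagnosed diseases (an item scores 1
only if it scored 1 for *every* diagnosis), so Q stays an integer count
of fully completed care tasks. The rejected "basic additive" score
(0–14 / 0–12, summing all itemised indicators) is also implemented,
together with the tetrachoric-correlation diagnostics that expose its
redundancy — the reason it was rejected.

All guideline content — the 19-sign vocabulary, danger-sign rules,
severity classifications and treatment rules — lives in a YAML codebook
(`src/paqc/data/codebook.yaml`); auditing against a different guideline
edition means editing data, not code. A synthetic cohort generator
produces multi-hospital, two-arm, multi-survey case-record CSVs with
controllable per-item adherence, so the whole pipeline is testable
without any real patient data.

## Worked example

```sh
paqc simulate --seed 42 --n-per-cell 50 --out records.csv --rx rx.csv
paqc score    --records records.csv --rx rx.csv --out scores.csv
paqc report   --scores scores.csv --by arm,survey --out summary.csv
```

prints

```
wrote 800 records -> records.csv
scored 800 records (0 not scoreable) -> scores.csv
4 summary row(s) -> summary.csv
```

and `summary.csv` contains

```
         arm   survey   n  mean  median  q25  q75
     control baseline 200 1.915     1.0  1.0  3.0
     control  endline 200 2.445     2.0  1.0  4.0
intervention baseline 200 1.870     1.0  1.0  3.0
intervention  endline 200 3.170     3.0  2.0  4.0
```

The two arms start level (median 1, IQR 1–3); both improve by endline,
the intervention arm more (median 3 vs 2) — the generator's default
positive arm×survey adherence interaction showing through the score, the
qualitative signature the measure is designed to detect. Each row of
`scores.csv` carries the six items, D1–D3, Q and the per-disease sums;
`paqc score --method basic` writes the basic additive scores, and
`paqc psych --scores scores.csv --out matrix.csv` estimates the
tetrachoric correlation matrix of the items, flags pairs above 0.80 and
reports positive semidefiniteness. (On synthetic cohorts the
classification → drug-choice → correct-use chain is structural, so those
pairs correlate strongly by construction.)

The same operations are available as a library:

```python
from paqc import load_codebook, score_patient, generate_cohort, SimulationConfig

cb = load_codebook()
cohort = generate_cohort(SimulationConfig(seed=1, n_per_hospital_per_survey=50), cb)
s = score_patient(cohort[0], cb)
print(s.diseases, s.combined.as_tuple(), s.q)
```

## Layout

| path | contents |
|---|---|
| `src/paqc/codebook.py`, `data/codebook.yaml` | guideline codebook model + reference transcription |
| `src/paqc/model.py`, `io.py` | case-record model, CSV schemas |
| `src/paqc/paqc_score.py`, `basic_score.py` | the two scoring systems |
| `src/paqc/treatment_eval.py` | dose/route/frequency/duration checking |
| `src/paqc/psychometrics.py` | tetrachoric estimation, redundancy flags, PSD check |
| `src/paqc/synthetic.py` | cohort generator and adherence-recovery report |
| `src/paqc/aggregate.py`, `cli.py` | grouping summaries; `paqc` CLI |
| `docs/methods.md` | model, assumptions, numerical conventions, limitations |
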
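# incns

Python toolkit for the INCNS neurocritical-illness prognostic score and
the validation battery used to benchmark it against four established
severity scores (APACHE II, SAPS II, GCS, FOUR).

The INCNS score sums 19 routine bedside and laboratory items, each worth
0–3 points, into five category subtotals — inflammation, nutrition,
consciousness, neurologic function, systemic condition — for a 0–44
total. Higher totals indicate a worse predicted 3-month functional
outcome (modified Rankin Scale ≥ 3 is "unfavorable").

## What's in the package

| module | contents |
| --- | --- |
| `incns.scoresheet` | the 19-item bin tables, `PatientSnapshot`, `score_incns` / `score_item` / `score_motor` / `score_respiration` |
| `incns.comparators` | GCS, FOUR, APACHE II and SAPS II from their original point tables, plus `ComparatorInputs` |
| `incns.windowing` | worst-value abstraction of timestamped readings into 24 h / 72 h snapshots, per score |
| `incns.valstats` | ROC/AUC with DeLong CIs and paired tests, Youden cutoffs, McNemar tests, paired predictive-value Wald tests, logistic score→probability curve |
| `incns.simulate` | seeded synthetic longitudinal cohorts with a controllable severity–outcome association, plus an AUC calibration routine |
| `incns.report` | cohort accounting, proportion formatting, JSON reports and plots |
| `incns.io` / `incns.cli` | long-format observation CSV schema and the `incns` command line |

The scoresheet and the APACHE II / SAPS II point tables are also bundled
as declarative JSON under `incns/resources/`; tests diff the code tables
against these transcriptions cell by cell.

Notes on interpretation (see docstrings for details):

- Numeric items are binned after rounding to the precision the printed
  scoresheet uses (one decimal for WBC, temperature, albumin, glucose,
  potassium, bilirubin; integers elsewhere), which makes binning total
  and deterministic.
- "Most deranged" windowing maximizes item points per variable
  independently (ties go to the earliest reading; window boundaries are
  closed), so an assembled snapshot may mix timestamps.
- Missing data is a hard error by default; `assume_normal=True` (CLI
  `--assume-normal`) scores missing items 0 and flags them as imputed.
- Intubated patients always score "incomprehensible speech/none" on the
  verbal item.

## Command line

```bash
# generate a seeded synthetic cohort (observations.csv, outcomes.csv, truth.json)
incns simulate --n 500 --prevalence 0.592 --effect 1.0 --seed 7 --out cohort/

# worst-value windowing + scoring
incns score --input cohort/observations.csv --window 72 \
    --score incns --score apache2 --score saps2 --out scores.csv

# ROC/AUC, Youden cutoffs, paired comparisons, probability curve
incns validate --scores scores.csv --outcomes cohort/outcomes.csv \
    --compare incns:apache2,incns:saps2 --out report.json --plots figures/
```

The observation CSV is long-format: `patient_id, timestamp, variable,
value`, one row per measured variable, with an optional
`variable=admission` row marking N-ICU admission. GCS and FOUR totals
decrease with severity, so negate them (or swap the comparison
direction) when contrasting their ROC curves against the other scores.

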
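# riskcal

Validation toolkit for binned actuarial violence-risk instruments: scoring and
bin assignment, rank-based discrimination (AUC), calibration (logistic
score-to-rate models, Hosmer–Lemeshow, expected/observed index with
multiplicative CIs), interrater reliability (ICC, kappa, Gwet AC1/AC2, percent
agreement, Cronbach's alpha), cohort descriptives, and a seeded synthetic
cohort generator so the whole pipeline is testable without restricted clinical
data.

## Package layout

| module | contents |
|---|---|
| `riskcal.instrument` | item weights, total scores, proration of omitted items, nine-bin assignment, spec/sheet I/O |
| `riskcal.synthetic_data` | seeded cohorts (sex-specific truncated-normal scores, logistic fixed-horizon outcomes, diagnoses with comorbidity targets), item sheets with missingness, second-rater simulation |
| `riskcal.discrimination` | Mann–Whitney AUC with Hanley–McNeil or bootstrap CIs, effect-size labels, subgroup tables |
| `riskcal.calibration` | IRLS logistic fits, score→rate curves, Hosmer–Lemeshow, norms tables, expected counts, E/O index with 95% CI |
| `riskcal.reliability` | one-way/two-way single-measure ICC, weighted/unweighted kappa, Gwet AC1/AC2, percent agreement, Cronbach's alpha |
| `riskcal.cohort_stats` | bin frequency tables, Welch t with Cohen's d variants, chi-square with Cramér's V, fixed-window outcomes, conviction coding |
| `riskcal.cli` | `riskcal` command-line entry point |

## CLI

```bash
# seeded synthetic fixtures (cohort + item sheets + second rater)
riskcal simulate --out-dir sim/ --seed 7 [--config params.yaml]

# score sheets (proration + bin assignment)
riskcal score --sheets sim/sheets.csv --out scored.csv

# analyses
riskcal discriminate --cohort sim/cohort.csv --by diagnosis --out auc.csv
riskcal calibrate   --cohort sim/cohort.csv --out-dir calib/
riskcal reliability --ratings ratings.csv --out reliability.json
riskcal validate    --cohort sim/cohort.csv --out-dir report/   # everything
```

All randomness flows from the single seed; reruns with the same configuration
are byte-identical, and every output directory carries a `manifest.json` with
the seed and a configuration hash.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` re-derives the published desk-scale quantities
(E/O indices, the gender Welch t, the bin-by-gender chi-square, the instrument
score minimum) and runs the property-based criteria (AUC vs exhaustive pair
counting, logistic parameter recovery, Hosmer–Lemeshow type-I calibration,
agreement-coefficient extremes).

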
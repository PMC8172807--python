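# psybattery

Reusable pipeline for analysing repeated cross-sectional youth mental-health
surveys: declarative instrument scoring with skip logic, consistency-based
exclusion screening, cut-off "probable diagnosis" flags, and a 75-test
battery of permutation tests on linear-model slopes with nuisance
covariates and joint Benjamini–Hochberg FDR correction. A calibrated
synthetic cohort generator makes every stage testable without access to any
real survey data.

## Components

| module | what it does |
| --- | --- |
| `psybattery.scales` | Survey data model; scoring of CPSS, PHQ-A, HADS (anxiety), CRAFFT, Tobacco Use, Rosenberg, Kidscreen-10 and CYRM-12, including reverse-coded items and skip rules; tri-state suicidal-thinking and tobacco-use assessments. A machine-readable schema of every item and answer choice ships as `schema.json`. |
| `psybattery.screening` | Five exclusion criteria (two categorical age extremes, three configurable consistency screens) with a conservation-checked ledger; threshold-based tri-state diagnosis flags incl. the any-of-4 composite. |
| `psybattery.inference` | Design-matrix construction (centred covariates, gender indicator nuisance columns, intercept rules), OLS slope via the normal equations, two-tailed permutation tests (effect-shuffle or Freedman–Lane residual scheme), step-up FDR. |
| `psybattery.battery` | Orchestration of the default 15-measure × 5-effect battery with per-measure complete-case filtering, a single joint FDR family, demographic summary tables, and an age-restricted (12–17) sensitivity re-run. |
| `psybattery.cohort` | Synthetic item-level cohort generator: demographic sampling, Gaussian latent severities with planted time/age/gender effects, exact total-to-item allocation, injectable missingness / inconsistent responders / out-of-range ages, plus an analytic population-slope oracle. |

## CLI

```bash
# synthesize an item-level survey CSV (1,200 rows, with planted noise)
psybattery simulate -o cohort.csv --seed 3 --n-per-year 400,400,400 \
    --missing-rate 0.02 --inconsistent-rate 0.03 --oor-age-rate 0.01

psybattery score  -i cohort.csv -o scored.csv           # scale totals + flags
psybattery screen -i cohort.csv -o kept.csv --ledger ledger.tsv
psybattery analyze -i cohort.csv -o out/ --permutations 100000 --seed 3
psybattery report -i cohort.csv -o tables/              # demographic tables
```

`analyze` writes `battery.tsv` (one row per test: N, group descriptives,
slope, p-value, FDR flag), the exclusion ledger, demographic tables, an
age-12–17 sensitivity battery and `run.json` with the run metadata. A YAML
or JSON config file passed via `--config` overrides flags key by key.

The input CSV has columns `year`, `age` (integer years or the categorical
extremes `10 years or less` / `20 years or more`), `gender`
(`female|male|other|prefer_not_say`) and one column per item
(`cpss_q3`, `phqa_q9`, ...) holding the 0-based printed answer index;
empty cells are unanswered items.

## Notes

- Permutation p-values use the (r+1)/(B+1) estimator and can never be 0;
  the default iteration count is 10^5 (scale down with `--permutations`
  for quick runs — the test count and FDR family are unaffected).
- The permutation scheme shuffles the effect column across rows, keeping
  response/nuisance rows intact; `--scheme freedman_lane` permutes
  nuisance-model residuals instead.
- Binary outcome measures are analysed by the same linear machinery coded
  0/100, so slopes read as percentage points per unit of the effect.
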
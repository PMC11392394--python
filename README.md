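# ventalloc

Monte Carlo simulation of crisis-standards-of-care ventilator allocation
protocols. The package estimates lives saved, life-years saved, and
allocation equity for six triage rules — lottery, 10-year age bands, pure
SOFA, SOFA tiers (New York '15), SOFA points plus severe-comorbidity penalty
(Maryland '21), and SOFA points plus an age-adjusted Charlson contribution
(Colorado '20) — under bed shortages of c = n/20 beds per patient.

## How the simulation works

Each replicate randomly permutes the cohort, cuts it into blocks of twenty,
and forms ten random pairs per block. With n beds per block, the first n−10
pairs both get beds (when n > 10), the last 10−n pairs get none (when
n < 10), and every remaining pair is contested: the member with the higher
protocol priority wins, ties broken by lottery. Unallocated patients are
assumed not to survive; allocated patients realise their scarcity-free
outcome. Post-discharge life expectancy comes from a life table (age, sex,
race) re-entered at a comorbidity-shifted effective age.

Headline metrics per protocol p and capacity c:

- lives saved per patient `LS = S_sim − S_B·c` (baseline survival S_B),
- life-years saved per patient `LYS = LY_sim − LY_B·c`,
- allocation and survival rates overall and by race, with age-standardised
  rates using modified-gamma confidence intervals.

Because the original encounter file is restricted-access, the package ships
a calibrated synthetic-cohort generator (`ventalloc.cohort.CohortSpec` /
`generate_cohort`): marginals match the published descriptive table, and
survival is drawn from a logistic model with odds ratios 0.896 per SOFA
point, 0.964 per year of age and 1.054 per Elixhauser point, with the
intercept solved so overall survival hits 72%.

## CLI

```sh
# calibrated synthetic cohort
ventalloc generate --n 3707 --seed 7 --out runs/cohort.csv

# one protocol / capacity
ventalloc simulate --cohort runs/cohort.csv --protocol age \
    --capacity 0.5 --replicates 1000 --seed 7 --out-dir runs/age_half

# all six protocols over the full 0.05..0.95 capacity grid
ventalloc sweep --cohort runs/cohort.csv --protocols all --seed 7 \
    --out-dir runs/sweep

# figures from a sweep's metric tables
ventalloc report --metrics-dir runs/sweep
```

Outputs are tidy CSVs (`table2_survival_allocation.csv`,
`table3_lives_saved.csv`, `table4_life_years_saved.csv`,
`capacity_sweep.csv`) plus a `manifest.json` recording the seed and
configuration; reruns with the same manifest are byte-identical.

A custom life table may be supplied as a CSV with columns
`age,sex,race,ex` (`--life-table`); the bundled default table is synthetic
and monotone, not official vital statistics. Comorbidity banding/offsets and
the Colorado age-points table are YAML-configurable (`--adjustments`,
`--colorado-table`).

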
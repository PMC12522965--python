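# icdcea

Lifetime Markov cohort cost-effectiveness analysis of implantable
cardiac defibrillator (ICD) therapy versus pharmaceutical therapy for
cardiac arrhythmia, from the perspective of the Iranian health system.

The model runs a cohort through annual cycles over two arm-specific
state structures — ICD: *well, hospitalization, complication, device
rejection, death*; pharmaceutical: *well, hospitalization, death* — and
accrues costs (discounted at 6%/year) and QALYs (discounted at 3%/year)
to a lifetime horizon (death absorption within 1e-4, at most 100
cycles). On top of the engine it provides:

- **Metrics** — ICER, per-arm ACER, net monetary benefit and dominance /
  CE-plane classification against a willingness-to-pay threshold of
  $13,002/QALY (three times 2021 GDP per capita).
- **Deterministic sensitivity analysis** — one-way swings over 95%
  ranges (mean ± 1.96·SD, ±25% where no SD is published), a sorted
  tornado, and a two-way preference map over the well-state costs of
  both arms.
- **Probabilistic sensitivity analysis** — seeded Monte-Carlo (default
  1000 iterations) drawing beta-distributed probabilities/utilities and
  gamma-distributed costs fitted by the method of moments, with
  cost-effectiveness acceptability curve and CE-plane scatter.
- **Calibration** — the source table does not publish the well-state
  exit probabilities; `icdcea calibrate` fits them (three for ICD, two
  for the pharmaceutical arm, bounded to [0, 0.5]) to per-arm lifetime
  cost/QALY targets by bounded Nelder-Mead from a deterministic
  multistart grid.

All monetary amounts are in USD (the source data were converted at the
official 2021 rate of 42,000 Rial/USD; no currency logic is included).

## Command line

```sh
icdcea run                      # base case: per-arm totals, ICER/ACER/NMB, verdict
icdcea psa --n-iter 1000 --seed 42   # PSA sample, CEAC, CE-plane scatter + plots
icdcea tornado                  # one-way DSA over 95% ranges
icdcea twoway --grid-n 20       # preference map over both well-state costs
icdcea calibrate                # fit free transitions to lifetime targets
icdcea fixtures --out params.csv     # write the bundled parameter table
```

Every verb accepts `--params` (parameter CSV; defaults to the bundled
table), `--settings` (YAML/JSON block), `--out-dir`, `--wtp`,
`--discount-cost`, `--discount-outcome`, `--max-cycles`,
`--half-cycle/--no-half-cycle` and `--seed`; precedence is CLI flag >
settings file > bundled default. Each run writes a `run_log.json`
echoing the effective configuration.

The parameter file is a flat CSV with columns
`parameter_id, arm, category, source_state, target_state, mean, sd,
distribution`; rows omitted from a user file are filled from the bundled
defaults (`src/icdcea/data/default_parameters.csv`). The bundled free
well-state transitions carry the best-fit calibrated values.

## Known inconsistencies in the source figures

- The published NMB column ($169,155 / $179,387) back-solves to a WTP of
  roughly $16,650, not the stated $13,002; this package reports NMB at
  the configured WTP and makes no attempt to match that column.
- The published incremental QALY is printed as 1.35 while
  12.63 − 11.29 = 1.34; the printed ICER ($24,286) is consistent with
  1.34, which is what the arithmetic here yields.

## Layout

```
src/icdcea/
  states.py        # arms, health states, state orderings
  parameters.py    # distribution fitting, parameter table IO, sampling
  engine.py        # transition matrices, cohort trace, discounted accrual
  metrics.py       # ICER / ACER / NMB / dominance
  sensitivity.py   # one-way, tornado, two-way, PSA, CEAC, scatter
  calibration.py   # free-parameter fitting to lifetime targets
  fixtures.py      # bundled table writer, toy oracle chains, random sets
  plots.py         # CE plane, CEAC, tornado, two-way figures
  cli.py           # the `icdcea` command group
scripts/acceptance.py
tests/             # unit, property (hypothesis) and acceptance suites
```
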
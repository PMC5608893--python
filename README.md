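# bleedrisk

Bleeding-risk score computation and validation pipeline for atrial-fibrillation
patients on vitamin-K antagonists.

The package computes four additive clinical bleeding-risk scores — HAS-BLED,
ATRIA, ORBIT and HEMORR2HAGES (plus CHA2DS2-VASc for descriptive output) —
and their TTR-modified variants that add one point for poor anticoagulation
control (time in therapeutic range, TTR < 65%). It quantifies anticoagulation
quality with the Rosendaal linear-interpolation TTR, and evaluates how well
the scores predict ISTH-defined major bleeding using:

- 2×2 association statistics (Woolf odds ratios, chi-squared) and
  crude / annualized event rates,
- Kaplan–Meier curves, log-rank tests and univariate Cox regression
  (Newton–Raphson partial-likelihood fit, Breslow or Efron ties),
- c-index (Mann–Whitney concordance), DeLong paired ROC comparison,
  Pencina NRI / IDI, Hosmer–Lemeshow calibration,
- decision-curve analysis (net benefit across threshold probabilities).

A synthetic-cohort generator produces registry-like cohorts (covariate
prevalences, per-patient INR trajectories auto-tuned to a target labile-INR
fraction, exponential bleeding hazard log-linear in risk factors) so the
entire pipeline is testable without any external data.

## Command-line use

```bash
bleedrisk simulate --n 1361 --seed 1 --out cohort/   # two-CSV cohort + config
bleedrisk ttr cohort/baseline.csv cohort/inr.csv     # per-patient TTR table
bleedrisk score cohort/baseline.csv cohort/inr.csv   # points + breakdowns
bleedrisk rates cohort/baseline.csv cohort/inr.csv   # bleed rates (JSON)
bleedrisk run --n 1361 --seed 1 --out results/       # full pipeline
```

`bleedrisk run` (also `survival`, `evaluate`, `dca`) writes TSV/JSON
analogues of the analysis tables: per-score odds ratios, event-distribution
tables, KM curves, Cox fits, DeLong/NRI/IDI comparisons, Hosmer–Lemeshow
calibration, and decision curves. Runs are deterministic for a fixed
`--seed`; each stage draws from a stage-name-derived substream.

Cohorts are plain CSV: a baseline table (one row per patient; demographics,
comorbidity flags as 0/1, hemoglobin, follow-up, outcome) and a long-format
INR table (`patient_id, day, inr`) with integer day offsets from entry
(day 0); 1 year = 365.25 days everywhere.

## Notes and caveats

- Anemia cut-offs: hemoglobin < 13 g/dL (men) / < 12 g/dL (women), strict
  inequalities. An explicit adjudicated anemia flag, when present, overrides
  the hemoglobin-derived value (with a logged warning on disagreement).
- Rosendaal TTR uses a 183-day window, a 56-day maximum inter-visit gap
  (both configurable; gap cap can be disabled), and counts boundary INRs
  (exactly 2.0 / 3.0) as in range. TTR of exactly 65% is *not* labile.
- Integer scores are mapped to event probabilities by univariate logistic
  regression before IDI, Hosmer–Lemeshow and decision-curve analyses;
  rank-based statistics (c-index, DeLong) use raw points.
- The published HAS-BLED category odds ratio (2.00) is not reproducible
  from the published cell counts (87/163 events, 752/609 category sizes
  give 2.33 by direct computation) and is therefore not an acceptance
  target; the three reproducible ORs are.
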
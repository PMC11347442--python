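# loadlab

Session-RPE workload monitoring and lagged injury-risk classification for
athlete cohorts.

Team-sport practitioners quantify internal training load with the
session-RPE method: after each session the athlete reports a rating of
perceived exertion on Borg's CR-10 scale, and the daily workload is

    workload = RPE × duration (min)   [A.U.]

A family of derived metrics summarises how that load accumulates, and the
open question this package operationalises is which of them — and at what
time lag — best classifies day-level injury risk. `loadlab` implements the
full analysis as a reusable pipeline:

1. **Seven workload metrics**, computed daily on trailing windows per
   athlete: coupled ACWR (acute 7-day sum ÷ mean of the 4 trailing weekly
   block sums), uncoupled ACWR (÷ the 3 weeks preceding the acute week),
   weekly ratio of workload change (Diff), training monotony (mean daily
   load ÷ SD), the SD-of-weekly-change z-score (SDΔ), the EWMA-based ACWR
   (λ = 2/(N+1), decay time N = 5), and the REDI-based ACWR (robust
   exponential decreasing index, weights e⁻ⁱ zeroed on missing days).
   Burn-in and degenerate-denominator cells carry explicit invalid markers.
2. **Lag alignment**: the metric at day *t* predicts the injury flag at day
   *t + lag* (lags 0, 5, 10 by default), predictors standardized, 70/30
   uniform random split.
3. **Two model families per (metric, lag) cell**: maximum-likelihood
   logistic regression reported as the classic Wald table (B, SE, Wald, p,
   Exp(B), 95% CI, accuracy) and a single-hidden-layer perceptron (tanh
   hidden units, softmax/cross-entropy output, 1–50 units).
4. **Evaluation**: summed cross-entropy on train/test, ROC/AUC, per-class
   accuracy, cumulative gain and lift (benefit) curves, and box-plot-style
   score summaries per class.
5. **A synthetic cohort generator** — 8 athletes × 211 days, 5-day
   microcycles with the fifth day rest, injuries drawn from a logistic
   hazard on a chosen driving metric at a chosen lag, prevalence calibrated
   to a 38:212 injury:sample ratio — so the entire grid is exercisable and
   testable without any private data.

## Worked example

Generate a synthetic squad and run the full 7 × 3 × 2 experiment grid:

```console
$ loadlab synth --seed 42 --out log.csv
wrote 1688 athlete-day rows (8 athletes x 211 days) to log.csv

$ loadlab run --in log.csv --seed 42 --out reports
grid: 42 cells, 42 fitted, 0 failed, 4.6s; reports in reports
  logistic lag  0d: mean accuracy 77.8%, mean AUC 0.697
  logistic lag  5d: mean accuracy 77.4%, mean AUC 0.588
  logistic lag 10d: mean accuracy 78.2%, mean AUC 0.536
       mlp lag  0d: mean accuracy 77.9%, mean AUC 0.697
       mlp lag  5d: mean accuracy 76.9%, mean AUC 0.574
       mlp lag 10d: mean accuracy 78.2%, mean AUC 0.553
```

This squad's injury process is driven by the no-lag EWMA-ACWR, and the
summary shows exactly the signature such a process leaves: mean AUC is
highest with no lag and decays toward chance at 10 days, while raw accuracy
stays near the non-injury prevalence for every cell (a constant "never
injured" prediction would already score ≈ 82%, which is why AUC and the
per-class accuracies in the tables are the informative columns).
`reports/` then contains one Wald table per lag (`logistic_lag*.csv`), one
perceptron table per lag with cross-entropies and AUC (`mlp_lag*.csv`),
long-format ROC/gain/lift points (`curves.csv`), the per-lag summary
(`summary.csv`), and a `manifest.json` recording config, per-cell seeds and
row accounting. Reruns with the same seed are byte-identical.

The same flow is available as a library:

```python
import loadlab as ll

log = ll.generate_cohort(ll.SyntheticConfig(seed=42))
panel = ll.compute_all_metrics(log)
ds = ll.split(ll.standardize(ll.align_labels(panel, log, "ewma_acwr", 0)),
              0.7, seed=1)
report, scorer = ll.fit_logistic(ds.part("train")["x"], ds.part("train")["y"])
print(report.B, report.expB, report.p)
```

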
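# Methods

## The analysis in one paragraph

Each athlete-day carries a session-RPE workload (CR-10 rating × minutes,
A.U.). Seven rolling metrics summarise load accumulation per athlete; each
metric, paired with the binary injury flag at a 0/5/10-day lag, feeds a
single-predictor classifier (logistic regression and a small MLP) on a
standardized 70/30 split; models are compared by test AUC, cross-entropy,
per-class accuracy and gain/lift curves over the full metric × lag × model
grid.

## Metric definitions and conventions

All metrics are evaluated every day on trailing windows of one athlete's
daily series; athletes never share windows. A cell is invalid — NaN plus a
recorded reason — iff its full look-back is unavailable (burn-in) or a
denominator is degenerate; invalid cells are excluded downstream rather
than propagated as ±∞.

| metric | definition | burn-in |
|---|---|---|
| coupled ACWR | trailing 7-day sum ÷ mean of 4 trailing non-overlapping 7-day block sums (acute week included) | 28 d |
| uncoupled ACWR | same acute sum ÷ mean of the 3 blocks preceding the acute week | 28 d |
| Diff | trailing 7-day sum ÷ preceding 7-day sum | 14 d |
| monotony | mean of 7 trailing daily loads ÷ their SD | 7 d |
| SDΔ | (acute weekly sum − mean of 4 trailing block sums) ÷ their SD | 28 d |
| EWMA-ACWR | 7-day mean of daily EWMA ÷ 28-day mean | 28 d |
| REDI-ACWR | 7-day mean of daily REDI ÷ 28-day mean | 28 d |

Decisions where the construct admits more than one reading:

* **Monotony** uses Foster's construct (mean daily load ÷ SD of daily
  loads); a weekly-sum numerator over a daily SD has mismatched units and
  is not offered.
* **SDΔ** defaults to the SD denominator (a z-score, matching the
  1-SD/2-SD risk-threshold usage); the variance denominator is kept as
  `sddelta_denominator="variance"` for fidelity to the printed form. A
  zero numerator returns exactly 0 even when the block SD is also zero
  (constant load), so the constant-load fixed point is well defined.
* **EWMA** defaults to Williams' standard recursion
  E_t = λW_t + (1−λ)E_{t−1}, E_0 = W_0, λ = 2/(N+1), N = 5 → λ = 1/3. The
  variant recursion that omits λ on today's load is available as
  `ewma_form="literal"` with P_0 = W_0/λ; then P_t = E_t/λ for all t, so
  both forms give identical EWMA-ACWR — a tested invariant.
* **REDI** is the self-consistent weighted mean Σαᵢw_{t−i} / Σαᵢ over the
  trailing `redi_window_days` (= 5, one microcycle) days with αᵢ = e⁻ⁱ and
  αᵢ = 0 on missing days. Missing means 0 A.U. by default (scheduled rest
  or injury stoppage); a true zero-load training day is indistinguishable
  in the log and is treated the same — a documented limitation. An
  explicit `rest_mask` overrides the zero heuristic.
* **"1-week" / "4-week" values of smoothed series** (EWMA, REDI) are read
  as trailing 7-day and 28-day means of the daily smoothed values,
  paralleling the coupled-ACWR structure; both windows are configurable.
* **SD convention** is sample (n−1) throughout, matching common
  statistics-package defaults; population SD is a config switch.

## Lag alignment, standardization, splitting

"5-day latency" means the metric at day *t* predicts injury at day
*t + 5*: load precedes injury. The final `lag` days per athlete have no
future label and are dropped; invalid metric cells are dropped; both
counts are kept and the manifest identity raw = used + lag-dropped +
invalid-dropped is tested. Standardization (zero mean, unit sample SD) is
computed on the full dataset before splitting — mirroring the workflow the
pipeline reproduces — with stored moments re-appliable for leakage-free
variants. The split is uniform at the row level, round(0.7 n) rows to
train, ignoring athlete identity and time; single-class training draws are
retried with a warning, then fail.

## Models

*Logistic*: statsmodels maximum likelihood with intercept; reported as B,
SE, Wald = (B/SE)², a 1-df chi-square p, Exp(B) with the Wald interval
exp(B ± 1.96·SE), and accuracy at the 0.5 threshold. Complete separation
raises rather than emitting a junk table.

*MLP*: scikit-learn `MLPClassifier`, one tanh hidden layer, lbfgs, seeded
initialization. For a binary target its logistic output with binomial
cross-entropy is exactly a 2-class softmax with cross-entropy. Hidden
width is clamped to [1, 50]; when unspecified it is chosen from the grid
(1, 2, 4, 8) by cross-entropy on an internal 20% validation slice, then
refit on all training rows — a deliberately small grid, since a 1-D
predictor rarely supports more capacity and the 42-cell grid stays cheap.
The original analysis's proprietary scaled-conjugate-gradient optimizer
and automated architecture search are intentionally not emulated.

*Evaluation*: cross-entropy is the summed negative log-likelihood in nats
(scores clipped to [1e-12, 1−1e-12] only inside the loss); ROC/AUC and
gain/lift use the raw scores, so AUC is invariant under monotone transforms
(tested). Gain(q) is the fraction of positives captured in the top-q score
quantile with ties broken by stable ordering, anchored at (0,0); lift =
gain/q. Accuracy uses a fixed 0.5 threshold — none was canonical, and the
threshold-free surfaces carry the comparisons — and is always reported
alongside per-class accuracy, because at ~18% prevalence overall accuracy
mostly restates the class balance.

## The synthetic cohort

The generator emulates the structure the analysis assumes, not any real
squad: 8 athletes × 211 consecutive days; 5-day microcycles whose last day
is rest (0 A.U.); integer CR-10 ratings from a clipped normal (mean 5,
SD 1.5); durations from a truncated normal (90 ± 20 min) whose mean ramps
sinusoidally ±30% over a 42-day period with a per-athlete phase, so
chronic windows have genuine dynamic range. Load magnitudes are arbitrary
by construction — only their relative dynamics matter to ratio metrics.

Injuries follow a logistic hazard on one chosen driving metric:
P(injury at t + lag) = expit(β0 + β1 z_t). Generation is **sequential**:
z_t is the driving metric evaluated on the athlete's *realized* load
history — including the 0 A.U. days an earlier injury stoppage already
forced — standardized with moments from an injury-free pilot cohort drawn
from the same seed. Recomputing the metric from the emitted log therefore
reproduces the values the hazard saw; there is no hidden counterfactual
series. (A two-pass design that zeroes stoppage days after drawing
injuries decorrelates the emitted log from its own hazard badly enough to
halve the recoverable signal at this prevalence.) Days with no defined
source value (burn-in, or t < lag) use the baseline rate expit(β0). After
each injury, 0–3 following days (uniform) are zeroed; labels are left as
drawn. β0 defaults to logit(38/212) ≈ −1.52, the injury:sample ratio the
pipeline targets, and `calibrate_beta0` solves
mean(expit(β0 + β1 z)) = target on a pilot cohort's z by root bracketing —
deterministic and strictly monotone in β0.

What the generator does **not** emulate: real injury aetiology (no
severity, recurrence structure, or illness), multi-session days,
positional differences, or any canonical A.U. scale. Passing tests
therefore demonstrate that the pipeline recovers structure *it planted
itself*, not that any metric predicts real injuries.

## Test-study designs and problem sizes

Two suite studies deliberately switch off stoppage zeroing
(`stoppage_days_max=0`): parameter recovery (200 cohorts, 8 × 652 days ≈
5000 valid athlete-days each, β = (−1.5, 1.0)) and structural recovery
(20 replicate default-size squads, prevalence calibrated to 38:212, full
21-cell MLP grid with shared splits). Both are planted-structure studies:
with feedback on, an injury zeroes the next days' load and craters the
metric exactly where lagged pairings look — the driving metric's lag-5
autocorrelation drops from 0.66 to ≈ 0 — so the feedback, not the
estimator or the grid, would dominate the outcome. The shared-split mode
exists precisely for such controlled cross-cell comparisons. The
fixed-point, oracle-equivalence and form-equivalence suites run on 50–200
day random series; the end-to-end determinism check runs the full 42-cell
default grid twice and compares output bytes.

## Known limitations

* One row per athlete-day: multiple sessions must be pre-summed upstream.
* REDI cannot distinguish a true zero-load training day from a missing
  day without an explicit rest mask.
* Row-level random splitting ignores the serial dependence of athlete-day
  data; grouped/blocked splits are out of scope by design, so test metrics
  are optimistic relative to a leave-athlete-out regime.
* The monotony literal variant (weekly sum ÷ SD) is not offered.
* Gain/lift are reported for the positive (injury) class only.
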
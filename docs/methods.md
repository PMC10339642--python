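# Methods

## The estimands

For a competing-risks process with cause 1 (adverse event of interest)
and cause 2 (death), and a binary treatment covariate `x` (0 control,
1 verum):

- the **cause-specific hazard** `h_k(t)` is the event rate of cause `k`
  among subjects still free of *any* event. The cause-specific Cox model
  `h_1(t | x) = h_01(t) e^{βx}` is fitted by treating competing events as
  right-censored at their event time. `HR_cs = e^β`.
- the **subdistribution hazard** `λ_k(t)` is the event rate of cause `k`
  in a risk set that retains subjects who already failed from the
  competing cause; it is the hazard attached to the cumulative incidence
  function `F_k(t) = P(T ≤ t, cause = k)` via
  `F_k(t | x) = 1 − exp(−Λ_0k(t) e^{γx})`. `HR_sd = e^γ`.

The two hazard ratios answer different questions. `HR_cs` isolates the
effect on the adverse-event rate; `HR_sd` compares cumulative incidences
and therefore also absorbs the treatment's effect on survival. The
package's purpose is to quantify, by simulation, how trial-level
conclusions switch between the two.

## Trial simulator

Each subject draws two independent latent exponential times, one per
cause, with arm- and cause-specific rates `h = log(2) / t₀.₅` set from
target medians; the observed record is `(min(T₁, T₂, c), cause of the
minimum)` with administrative censoring at `c = 30` months. For
exponential marginals, independent latent times and constant
cause-specific hazards are the same mechanism, so the generator is the
unique constant-hazard model matching the stated medians. A latent time
exactly equal to the horizon (measure zero, but possible in floating
point) counts as censored.

Design defaults (one grid "condition" = one pair of adverse-event
medians):

| parameter | default | meaning |
|---|---|---|
| grid | 1–20 × 1–20 months | median time to first AE, verum × control |
| `n_per_arm` | 300 | 600 patients per trial, 1:1 allocation |
| death medians | 20 / 10 months | verum / control; death HR = 0.5 fixed |
| `censor_time` | 30 months | administrative horizon |
| `replications` | 1000 (100 in reduced mode) | Monte-Carlo replicates per condition |
| `alpha` | 0.05 | two-sided significance level |

The analytic truths are closed-form: the true cause-specific HR of a
condition is the inverse ratio of its AE medians, and the cumulative
incidence is `CIF_k(t) = h_k/(h₁+h₂) · (1 − e^{−(h₁+h₂)t})`, used as the
oracle for all estimators.

Randomness: one master seed; the trial for (condition i, replicate r) is
drawn from `SeedSequence([seed, i, r])`, so any cell is reproducible in
isolation and adding replications never perturbs existing ones.

What the generator does *not* emulate: non-constant hazards (adverse
events in practice cluster early after treatment start), staggered entry,
loss to follow-up or any non-administrative censoring, covariates beyond
the arm indicator, and within-subject recurrence. Passing tests therefore
demonstrate the estimators' behaviour under the idealised constant-hazard
design, not robustness to real-data violations of it.

## Estimation

Both regressions maximise a partial likelihood in the single binary
covariate by Newton–Raphson with step halving (start β = 0, stop when
|score| < 1e−9 or |step| < 1e−10, max 50 iterations). With a binary
covariate the risk-set sums reduce to per-arm at-risk counts, making a
fit O(n log n); ties are handled by Efron's correction (absent almost
surely in simulated data, present possibly in user tables). Standard
errors are model-based (inverse observed information); confidence
intervals and two-sided p-values are Wald on the log-HR scale.

Monotone likelihoods (all events of interest in one arm) have no finite
maximiser; the estimate is capped at |log HR| = 15, flagged
non-converged, and excluded from pooling with a logged count. Datasets
with zero events of interest raise an estimation error and the replicate
is likewise excluded.

The Fine-Gray fit uses the **censoring-complete** construction: because
every subject's potential censoring time is the common administrative
horizon, a subject failing from the competing cause is simply held in the
risk set until the horizon with weight 1, and the estimating equation is
an ordinary Cox partial likelihood on the recoded data. This is exact for
the simulated design (and verified against `cmprsk::crr`, whose IPCW
weights are identically 1 in this regime); general random censoring would
require the IPCW extension and is rejected with an explicit error. The
baseline cumulative subdistribution hazard is a Breslow-type sum over the
extended risk set.

A caveat surfaced by testing: when the arms' death rates differ, the
proportional-subdistribution-hazards assumption does not hold exactly
under this generator, so at very large n the model-predicted cumulative
incidence carries a small misspecification bias (~0.01 at the horizon
for the equal-AE-medians condition). This is a property of the model, not
the estimator — the fitted coefficients and predictions agree with
`cmprsk` to all printed digits — and it is part of what the grid study
measures.

## Pooling and classification

Per condition and setting, the m converged replicate estimates are
combined by Rubin's rules on the log-HR scale: `Q̄ = mean(β̂)`,
`W = mean(se²)`, `B = var(β̂)` (unbiased), `T = W + (1 + 1/m)B`, with the
classical degrees of freedom `ν = (m−1)(1 + W/((1+1/m)B))²` and a
Student-t reference (normal when B = 0; the Barnard–Rubin small-sample
adjustment is negligible at m ≥ 100 and not used). The pooled decision
rule is: superiority if pooled HR < 1 and p ≤ α, inferiority if HR > 1
and p ≤ α, equivalence otherwise (p = α exactly counts as significant; a
significant HR of exactly 1 is unreachable under Wald inference).
Crossing the cause-specific with the subdistribution outcome gives the
nine switching categories (1 = remains superior, 2 = superiority →
equivalence, …, 9 = remains inferior).

Because `T ≥ W + B` regardless of m, the pooled test's scale is nearly
invariant in the number of replications; only the Monte-Carlo error of Q̄
(≈ √(B/m)) shrinks. Condition classifications are therefore stable
between 100 and 1000 replications, which is why the reduced preset (100
replications, the default for the acceptance script and the end-to-end
tests; roughly a minute of CPU for the full grid) reproduces the
full-scale marginal percentages within Monte-Carlo noise.

## Non-parametric estimators

Cause-specific Kaplan–Meier (competing events censored; Greenwood
variance), Nelson–Aalen (`Σ d/n`; Poisson-type variance `Σ d/n²`) and the
Aalen–Johansen cumulative incidence
(`CIF_k(t) = Σ_{t_i ≤ t} S(t_i−) d_{k,i}/n_i`, with S the all-cause
Kaplan–Meier). Conventions: subjects censored at an event time are
counted at risk there; deaths and adverse events tied at the same time
share one increment with `S(t−)` taken before it. The complement `1 − KM`
always dominates the Aalen–Johansen incidence, strictly once any death
precedes the last adverse event — the classic sense in which the naive
curve "overstates" incidence. No pointwise variance is attached to the
Aalen–Johansen curve (nothing in the pipeline consumes one; the KM and NA
variances are included for completeness).

## Numerical and design choices

- Pooling excludes non-converged (capped) replicates rather than keeping
  the cap value: a handful of |log HR| = 15 entries would otherwise
  dominate B and the pooled variance. At n = 600 with the default grid
  such replicates are essentially absent.
- The between variance B is snapped to zero when it is at rounding-noise
  scale relative to the estimates, so identical replicates cleanly fall
  back to the normal reference.
- Grid-level assertions on per-cell Monte-Carlo quantities (e.g. the
  HR_cs/HR_true ratio map staying at ≤ 1) use a simultaneous Bonferroni
  bound across the 400 cells rather than a per-cell 3-SE rule, which
  would by construction fail somewhere on a 400-cell grid about half the
  time.
- In the strong-inferiority corner of the grid (verum AE median a few
  months, control much longer) the subdistribution HR is attenuated
  toward 1 relative to the cause-specific HR — the familiar saturation of
  cumulative incidence near 1 — so "the subdistribution view is more
  pessimistic" is a statement about outcome categories (no condition ever
  switches in verum's favour), not a numeric ordering of the two HRs;
  the numeric ordering HR_sd ≥ HR_cs does hold wherever the pooled
  cause-specific HR favours verum.

## Limitations

Exponential event times only (no Weibull or piecewise hazards), a single
binary covariate, purely administrative censoring, and no formal
equivalence testing — "equivalence" is non-significance at α. The
Fine-Gray implementation is deliberately restricted to the
censoring-complete regime; fitting user data with random censoring
requires other software.
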
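# Methods

## Model and assumptions

Scores follow the classical test theory decomposition `x = τ + ε` on each of
two occasions, with `(τ₁, τ₂, ε₁, ε₂)` jointly normal. The population
structure is fully described by five parameters:

| parameter | meaning | units | default |
|---|---|---|---|
| `true_var` (σ²_τ) | true-score variance, shared across occasions | score units² | — |
| `error_var` (σ²_ε) | error-score variance, shared across occasions | score units² | — |
| `tau_stability` (r_τ) | cross-occasion correlation of true scores, in [0, 1] | — | — |
| `error_dependence` (r_ε) | cross-occasion correlation of error scores, in [0, 1) | — | 0 |
| `true_mean` | location of the true-score distribution | score units | 10 |

Error scores have mean zero by definition, and all true–error covariances
are zero. The mean of 10 is arbitrary — it only keeps true scores visibly
apart from the errors — and every closed form and every simulated
correlation is invariant to it and to a common rescaling of the two
variances; only the variance *ratio* (reliability) matters.

Under this structure the expected test–retest correlation is the
variance-weighted mixture `r_τ·ρ + r_ε·(1 − ρ)` with `ρ = σ²_τ/(σ²_τ+σ²_ε)`.
Negative correlations are rejected rather than modelled: stability and error
dependence below zero have no substantive interpretation in this setting,
and the study grids never use them. `r_ε = 1` is excluded because it would
make the "error" a second stable trait.

## What the generator emulates — and what it does not

`generate_scores` draws standard-normal deviates, correlates each
(true-score, error-score) pair with the analytic 2×2 Cholesky factor
`[[1, 0], [r, √(1−r²)]]`, scales by the standard deviations, and shifts by
the means; observed scores are the exact floating-point sums `τ + ε`. The
fixed-true-score path (`generate_fixed_tau`) copies occasion-1 true scores
to occasion 2; it consumes the same deviate layout, so at `r_τ = 1` the two
paths return bit-identical panels under a shared seed, and for other
stability values they are equivalent in distribution.

The generator reproduces the *idealized* conditions of the simulation
design: exactly normal, homoscedastic, continuous scores with a common
variance on both occasions. Passing tests therefore demonstrate the
behaviour of the coefficient under the model, not robustness of real
test–retest data to skewness, floor/ceiling effects, ordinal item scales,
occasion-specific variance changes, or true-score/error covariance — all of
which are out of scope here.

## Numerical choices

* **Bit-exact scale invariance.** Scaled deviates are quantized to 24-bit
  significands (float32 round-trip, a perturbation below one part in 10⁷ —
  orders of magnitude under Monte Carlo noise) so that adding the mean is an
  exact floating-point sum, and the replication pipeline centers observed
  scores at their known population mean before correlating (a translation
  Pearson r ignores). Together these make every downstream statistic
  *bit-identical* when both variances are rescaled by `4^k` under the same
  seed — the scale-invariance property holds exactly, not just
  approximately. For non-power-of-two factors invariance holds to ~1e-7.
* **Seed layout.** All randomness flows through `numpy.random.SeedSequence`.
  Each (condition, replicate) pair gets an independent child stream keyed by
  (root seed, stability-level index, error-dependence-level index, n,
  replicate index). The variance cell is deliberately *not* part of the key:
  conditions differing only in variance scale share common random numbers,
  which upgrades scale invariance to identical result rows and reduces noise
  in comparisons across variance ratios. Results are reproducible and
  independent of evaluation order.
* **Correlation estimator.** A two-pass product-moment implementation
  (checked against `scipy.stats.pearsonr`), clipped into [−1, 1] to absorb
  last-ulp rounding. Zero-variance inputs return NaN rather than raising;
  the replication layer drops such replicates, counts them in `dropped`, and
  warns. With both variances positive this path is unreachable — it exists
  for the permitted degenerate specs (`true_var = 0` or `error_var = 0`).
* **Summaries.** Replicate SDs use the n−1 denominator. No Fisher-z
  transformation anywhere: raw correlations are averaged, matching how the
  replicate summaries are defined. `n = 2` is accepted but triggers a
  warning, since r is ±1 almost surely there.
* **Minimum-n rule.** The search evaluates the replicate SD at every grid
  point and returns the smallest n from which the criterion holds *at that
  point and all larger evaluated points* (sustained crossing). This is
  robust to single lucky dips of a noisy SD estimate near the threshold. The
  default grid — 2, 3, 5, 8, 10, 15, 20, 25, 30, 40, 50, 75, 100, 150, 200,
  then hundreds to 1000 — brackets every landmark the analyses report;
  conditions that never sustain the criterion inside the 1000-participant
  ceiling are reported as `>1000`. Reported minima are grid values, so they
  are resolved only to grid spacing (e.g. a condition whose analytic
  threshold is ~583 reports 600, ~804 reports 800 or 900 depending on
  Monte Carlo noise at the marginal point).
* **Stability criteria and reliability bands.** SD ≤ .05 is "good",
  ≤ .025 "excellent". TRC interpretation bands use inclusive lower bounds
  (.70 acceptable, .80 good, .90 excellent); inclusivity is a convention
  chosen to make classification total.

## Study grids and problem sizes

Study 1 sweeps stability {1.0, .9, .8, .7, .6, .5} (1.0 via the fixed-copy
path) against variance cells and sample sizes with independent errors;
Study 2 fixes total variance at 10, realizes reliabilities .60–.95 (step
.05) as `true_var = 10·ρ`, and crosses stability {1.0–.6} with error
dependence {0, .1, .3, .5}. The zero level is kept as the independent-error
baseline so within-table contrasts (upward bias, homogenization of
reliability levels) need no second run. Full scale uses the 9×9 variance
grid, the default n grid, and 1000 replicates per condition. Desk scale —
the default, and what the test suite exercises — uses four representative
variance ratios (.6–.9), a coarse n grid, and 200 replicates, finishing in
seconds to minutes on one CPU while leaving every qualitative conclusion
and every closed-form column identical.

The analytic large-sample law `SD(r) ≈ (1 − ρ²)/√(n − 1)` serves as the
independent oracle for coefficient-stability results; simulated SDs track
it within 15% for n ≥ 100.

## Known limitations

* Minimum-n values are grid-resolved and Monte Carlo estimates; at grid
  points whose true SD sits within one standard error of the threshold the
  reported minimum can move by one grid step between seeds.
* The asymptotic SD law degrades for very small n and |ρ| near 1; the search
  never relies on it, but oracle comparisons are restricted to n ≥ 100.
* For a perfectly stable, highly reliable instrument (ρ = .9) the
  large-sample law puts the excellent-stability threshold near n ≈ 60, and
  the search agrees; published sample-size folklore for this regime is
  sometimes far more pessimistic, so minimum-n output should be read
  against the analytic law rather than rules of thumb.
* Only jointly normal, continuous scores are generated; ordinal, bounded,
  or non-normal instruments and three-wave longitudinal designs are out of
  scope, as is estimating `r_τ`, `r_ε`, or reliability from real two-wave
  data — the equivalence-set explorer exists precisely because that inverse
  problem is underidentified.
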
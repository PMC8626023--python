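# Methods

## Statistical model and procedure

The pipeline analyses a multi-arm DSS-colitis experiment: a healthy
control arm, a DSS arm, one or more DSS+monotherapy arms and a
DSS+combination arm. Endpoints are treated as independent samples per
group; continuous endpoints (body-weight change, colon length, colon
weight, MPO activity) are modelled as normal within group, ordinal
endpoints (stool, ulcers, blood, histology subscores) as categorical.

Three layers of inference are reported per endpoint:

1. **Summaries** — mean, SD, SEM (= SD/√n) and n per group, missing
   values excluded with a logged count.
2. **Classical tests** — Shapiro–Wilk per group (a rejection logs a
   warning but does not abort: the parametric analysis proceeds, with the
   bootstrap as the small-sample safeguard), one-way ANOVA, and
   independent-samples t contrasts restricted to a configured set (each
   non-control arm vs control, each treated arm vs DSS), Bonferroni
   adjusted within that family (`p_adj = min(1, m·p)`). No correction is
   applied across endpoints; endpoints are reported side by side the way
   study figures are.
3. **Synergy** — for each (monotherapy, combination) contrast, the
   bootstrap test below on the endpoint values of the two groups. The
   report pairs the observed absolute difference in means with its
   bootstrap p-value, and flags significance at α = 0.05 with the usual
   star thresholds (0.05, 0.01, 0.001, 0.0001).

### The bootstrap test

Observed statistic `T_obs = |mean(a) − mean(b)|`. Under the default
`pooled` strategy both resamples (sizes n_a and n_b, with replacement) are
drawn from the pooled sample, so resampling happens under the
no-difference null; `P_bootstrap` is the fraction of B = 10,000 resampled
statistics ≥ T_obs, inclusive, with no (B+1) smoothing (minimum attainable
p is 0). The layout of the resample matrix is an implementation detail;
results depend only on the draws.

Design choices worth stating:

- **Pooling.** Descriptions of this test in the applied literature often
  say only "resample the datasets". Resampling each group from itself
  estimates the sampling variability of the statistic, not its null
  distribution, and cannot give a calibrated p-value; pooling is the
  choice that makes the procedure a hypothesis test. Both strategies are
  implemented (`strategy="pooled" | "per_group"`), pooled is the default,
  and the calibration tests cover the pooled path.
- **Ties.** The ≥ comparison is implemented as
  `stat ≥ T_obs − 1e-9·(1 + T_obs)`: mathematically tied resample
  statistics (common with integer data) must count, and the guard keeps
  last-ulp float noise from dropping them. The same guard is used in the
  exact oracle so the two routes agree tie-for-tie.
- **Exact oracle.** For n_a + n_b = N small enough that N^N ≤ 10⁷, the
  oracle enumerates the distribution of resample sums by convolving the
  pool's value multiset (exact for integer inputs) and returns the exact
  probability. It is an independent route kept solely for verification.

Calibration, verified by the test suite: with both groups N(0,1) at
n = 8 the rejection rate at α = 0.05 over 1,000 simulated experiments
falls in [0.03, 0.08] and the p-value distribution is near-uniform
(KS distance < 0.05); a 3-pooled-SD combination effect at n = 8 is
detected in over 80% of 500 replicates.

## Scoring rules

Macroscopic total (0–15) = stool (0–3) + ulcers (0–3) + length points +
weight points + blood (0/1). Percent-change points use the absolute
deviation from the control-group mean — the colon shortens but its weight
may rise, so direction is ignored — binned as [0,5] → 0, (5,15) → 1,
[15,25) → 2, [25,35) → 3, [35,∞) → 4. The printed rule tables for this
score overlap at the bin edges ("≤5" vs "5–14", "25–35" vs "≥35"); this
package resolves an exact 35% to 4 points (the severe bin wins) and an
exact 5% to 0, with the bins centralised in one constant so the
convention is changeable. Ulcer counts above 3 clamp to 3. Colon weight
is scored as recorded (with fecal content). Microscopic total (3–11) is
the plain sum of the five histology subscores.

## MPO quantification

Per replicate, the absorbance-vs-time slope is the closed-form OLS
estimate over the 0/30/60 s reads, converted to abs/min; replicates are
aggregated by mean (median available). The standard curve
`rate = slope·activity + intercept` is OLS on calibration pairs with
residual diagnostics. Well activity `(rate − intercept)/slope` is
normalised by the grams of tissue in the assayed aliquot,
`homogenate_concentration × supernatant_volume_in_well`
(defaults 0.030 g/mL × 0.007 mL), giving mU per g wet tissue. The
well-to-per-gram normalisation is the standard dilution-accounting
choice, isolated in one function with configurable constants. Negative
rates and negative well activities clamp to 0 (enzyme activity cannot be
negative) and are logged. Units are computed in mU/g throughout; any
µU/g axis labelling is treated as a display choice.

## Synthetic-cohort generator

The generator emulates the study conditions the analysis assumes: 5 arms,
n = 8 per group by default (configurable; real designs use 5–10),
continuous endpoints drawn from per-group normals, ordinal scores from
per-group categorical distributions, and an additive `synergy_shift`
applied to the combination arm's means beyond the single-drug effects.
Default endpoint parameters depict a severe DSS episode with nearly
ineffective monotherapies: control colon length 8.0 ± 0.5 cm vs 6.4 ± 0.5
under DSS (a 20% deficit), colon weight 0.25 ± 0.03 g vs 0.32 ± 0.04,
MPO 2 ± 1 vs 15 ± 4 mU/g, body-weight change +3 ± 2% vs −15 ± 4%. These
are generator conventions chosen once as a realistic severe-colitis
picture, not estimates of any particular dataset.

Body-weight trajectories are a normal baseline (24 ± 1 g, clipped to a
physiologic 18–30 g) times a constant daily multiplier reaching the
drawn final percent change on day 7 — the endpoint is parameterised, not
the disease mechanism. MPO plate kinetics are synthesised by inverting
the forward computation (target → well activity → rate → linear
triplicate trace from a 0.05 baseline absorbance) plus Gaussian read
noise (SD 0.002 absorbance by default); at zero noise the round trip
through the forward computation is exact. The synthesis curve slope
(50 abs/min per mU) is chosen so simulated tissue activities give rates
well above read noise, as a usable assay must.

What the generator does **not** emulate: correlations between endpoints
within an animal (ordinal and continuous endpoints are sampled
independently), day-to-day weight noise, cage or batch effects, dropout,
and any pharmacokinetics. Passing calibration and power tests therefore
show the statistical machinery is correct under the stated sampling
model, not that real cohorts satisfy that model.

## Numerical conventions and degenerate inputs

- Determinism: every stochastic routine takes a seed; the report spawns
  per-contrast seeds from one root seed, so reruns are byte-identical.
- Identical constant groups: observed statistic 0, bootstrap p = 1.
- Zero within-group variance in every group: ANOVA rejected as undefined;
  a single constant group merely gets a NaN Shapiro entry.
- Validation is fail-fast with the offending field named (negative SDs,
  probabilities not summing to 1, out-of-range ordinal scores,
  non-finite samples, degenerate calibration points).

## Problem sizes used in the checks

The simulation-based checks run at the study's own scale (n = 8 per
group) with 10,000 bootstrap iterations; calibration uses 1,000 simulated
experiments, power and null-rate checks 500 replicates each, distribution
recovery 10,000 animals per group, and the MPO round trip 1,000 seeds.

## Known limitations

- The bootstrap p-value has resolution 1/B; with B = 10,000 the smallest
  nonzero p is 10⁻⁴.
- The percent-change bins assume a trustworthy control mean; very small
  control groups make the length/weight points noisy, and no shrinkage is
  attempted.
- With plate noise and near-zero true activity, clamping negative rates
  at 0 biases recovered MPO upward; at the default signal-to-noise this
  bias is negligible, but the assay model is not meant for activities
  near the detection limit.
- `per_group` resampling is provided for comparison only; its p-values
  are not calibrated and the suite does not pretend otherwise.
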
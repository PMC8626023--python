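# colitistats

Quantitative workflow for preclinical DSS-colitis drug-combination studies:
synthetic multi-arm cohorts, composite colon-damage scoring,
myeloperoxidase (MPO) quantification from kinetic plate-reader data, and a
bootstrap hypothesis test of drug synergy.

In the dextran-sulfate-sodium (DSS) mouse model of ulcerative colitis,
candidate drug combinations are judged on a handful of endpoints: body
weight loss, a composite macroscopic damage score, colon length and weight,
tissue MPO activity and a histology score. Group sizes are small (5–10
animals), so on top of ANOVA with Bonferroni post-hoc contrasts the synergy
question — does the combination separate from each monotherapy? — is
assessed by resampling. This package implements that whole pipeline as a
tested library, driven by a synthetic-cohort generator so every stage can
be exercised and calibrated without animal data.

## The core statistic

For a monotherapy group *a* and a combination group *b* the observed test
statistic is the absolute difference in sample means,

```
T_obs = | x̄_a − x̄_b |
```

Both groups are then redrawn with replacement from the pooled sample
(imposing the null hypothesis of no difference) B = 10,000 times, yielding
resampled statistics T*₁ … T*_B, and

```
P_bootstrap = #{ i : T*_i ≥ T_obs } / B
```

The comparison is inclusive and unsmoothed, so a run in which 2,500 of
10,000 resampled statistics reach the observed value gives exactly
P = 0.25. An exact enumeration oracle (all N^N equally likely resample
pairs, N = n_a + n_b) verifies the Monte-Carlo estimate on small samples.
A per-group (non-pooled) resampling strategy is also available for
comparison; pooled is the default because only it samples under the null.

Scoring follows the standard rule tables: the macroscopic total (0–15) is
stool consistency (0–3) + ulcers (0–3) + percent-change points for colon
length and weight vs the control mean (≤5% → 0, 5–14% → 1, 15–24% → 2,
25–34% → 3, ≥35% → 4) + fecal blood (0/1); the microscopic total (3–11)
sums five histology subscores. MPO activity is the least-squares slope of
triplicate 0/30/60 s absorbance reads (abs/min), mapped through a purified
peroxidase standard curve and normalised to mU per gram of wet tissue.

## Worked example

```python
from colitistats import bootstrap_p, exact_p_oracle

mono  = [8.2, 7.9, 9.1, 8.6, 7.5, 8.8, 9.4, 8.0]
combo = [7.1, 6.8, 7.9, 7.4, 6.2, 7.6, 8.1, 6.9]
res = bootstrap_p(mono, combo, n_iterations=10_000, seed=1)
print(res.observed_test_stat, res.p_bootstrap)
# 1.1875 0.0048
exact_p_oracle([1.0, 1.0], [2.0, 2.0])
# 0.125
```

The combination mean sits 1.1875 units below the monotherapy mean; only
0.48% of pooled resamples reach that separation, so the contrast is
flagged as synergy at α = 0.05. The enumeration oracle on the tiny
instance returns the exact probability the resampler is estimating.

The `examples/` directory holds one short script per capability
(cohort generation, scoring, MPO assay, bootstrap test, full report); each
prints the numbers it computes and a line on what they mean. The same
functionality is scriptable from the shell:

```sh
colitistats simulate --n-per-group 8 --seed 1 --out cohort.csv
colitistats score --cohort cohort.csv --out scores.csv
colitistats analyze --cohort scores.csv --seed 1 --out report.json
colitistats synergy --a 1,2,3 --b 4,5,6 --seed 1
```

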
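# Methods

## The question and the statistics

When every trial in a meta-analysis reports the same continuous outcome in
the same unit, the analyst can pool either the **mean difference**
(MD = m_t − m_c, in outcome units) or the **standardized mean difference**.
`metamd` implements the SMD as **Hedges' adjusted g**:

    s_p = sqrt(((n_t−1) s_t² + (n_c−1) s_c²) / (n_t+n_c−2))
    d   = (m_t − m_c) / s_p
    g   = J(df) · d,   J(df) = 1 − 3/(4·df − 1),   df = n_t + n_c − 2

J is the standard closed-form approximation to the exact gamma-ratio bias
correction; at df ≥ 2 the two differ by well under 10⁻³, and the closed form
is what meta-analytic software universally uses. Sampling variances are

    Var(MD) = s_t²/n_t + s_c²/n_c
    Var(g)  = (n_t+n_c)/(n_t·n_c) + g²/(2(n_t+n_c))        (Hedges–Olkin, default)
    Var(g)  = (n_t+n_c)/(n_t·n_c) + g²/(2(n_t+n_c−3.94))   (RevMan variant)

Both g-variance conventions are provided (`smd_variance=`) because published
pipelines differ and the choice measurably shifts leave-one-out agreement in
small trials; the large-sample Hedges–Olkin form is the default.

## Pooling and heterogeneity

Inverse-variance pooling with fixed-effect weights w_i = 1/v_i, or
DerSimonian–Laird random-effects weights w*_i = 1/(v_i + τ²) where

    Q  = Σ w_i (y_i − ŷ_FE)²,   τ²_DL = max(0, (Q − df) / C),
    C  = Σ w_i − Σ w_i² / Σ w_i,   df = k − 1.

Cochran's Q and I² = max(0, (Q−df)/Q)·100 are always computed from the
fixed-effect weights: heterogeneity is a property of the trial estimates,
not of the pooling model, so each review carries one I² per metric. CIs use
the exact normal 0.975 quantile (1.959963984540054), two-sided p-values the
normal distribution. τ² and I² are truncated at zero. No Knapp–Hartung
adjustment, REML/Paule–Mandel estimators, or prediction intervals.

A caution the test suite documents: under exact homogeneity Q ~ χ²(k−1)
whatever the trial sizes, so I² does not converge to zero as trials grow —
its null *median* is 0 but its null mean at k ≈ 5 is around 13%. Degenerate
checks therefore assert the median.

## Leave-one-out percentage agreement

For each trial i of a review with k ≥ 3 trials: compute the trial's point
estimate under the chosen metric, pool the remaining k−1 trials as a
self-contained meta-analysis (τ² re-estimated on the subset, never frozen
from the full review), and flag agreement when the point estimate lies
inside the pooled 95% CI, boundary inclusive (a measure-zero convention).
The review's percentage agreement is the flagged fraction; it estimates how
well the meta-analysis of the other studies predicts the next study —
a direct, interpretable generalizability statistic.

Two corpus summaries are reported, because they genuinely differ with
unequal review sizes: the **median of per-review percentages** (each review
one unit — also the pairing unit of the sign test) and the **pooled
proportion** Σ n_agree / Σ k. Neither is privileged.

## Corpus-level comparisons

All paired tests are exact. The **sign test** on within-review differences
(I², agreement, |Z|) excludes ties and doubles the smaller binomial tail,
capped at 1; all-tied input returns p = 1 with a warning. The **McNemar
test** on the discordant cells of the significant/non-significant 2×2 table
defaults to the exact binomial form (discordant counts in this design are
typically below 20); a continuity-corrected χ² variant is available.
Significance of a pooled effect is the strict inequality p < α, α = 0.05 by
default and configurable (e.g. 0.0042 for a 12-comparison Bonferroni
sensitivity analysis).

Reviews are stratified by heterogeneity with a strict both-metric rule:
a review enters the "< t%" stratum only if I²(MD) < t **and** I²(SMD) < t,
default thresholds 60 and 30. The |Z| (power) comparison runs only in the
lowest stratum by default — comparing detection power between metrics of
unequal heterogeneity conflates power with generalizability — and can be
enabled everywhere with `z_all_strata`.

## Synthetic corpus generator

Real review collections of this kind are not redistributable, so the
generator emulates the reported shape of a large Cochrane-style corpus; all
pipeline tests run against it. Per review j and trial i:

| parameter | default | role |
| --- | --- | --- |
| `k_dist` | 3 + NegBin(r=0.7, p=0.175) | trials per review: median 5, IQR 3–8 |
| `n_dist` | exp(3.8 + 1.1·A_j + 0.4·B_ij), floor 2 | per-arm size; review-level factor A gives total participants median ≈ 500, IQR ≈ 220–1170 |
| `delta_dist` | N(0, 0.43) | review effect on the SMD scale; median |δ| ≈ 0.29 |
| `tau` | 0.2 | between-trial heterogeneity SD, standardized scale |
| `sigma_base` | 10 | population SD, outcome units (arbitrary scale) |
| `sd_dispersion` (η) | 0.3 | σ_ij = σ_base·exp(η ζ_ij): across-trial SD spread |

Observed summaries are drawn from the exact normal-theory sampling
distributions (means normal, sample variances scaled χ²), matching the
assumptions of every downstream formula. Arms are equal-sized within a
trial. Each review consumes its own spawned RNG substream, so enlarging a
corpus never changes earlier reviews, and a corpus is a pure function of
(config, seed).

`effect_scale` decides which metric is "true": `smd_fixed` holds the
standardized effect constant (the MD then disperses with σ_ij), `md_fixed`
holds the mean difference constant (the SMD then disperses). δ and τ are
always specified on the standardized scale relative to σ_base so the two
scenarios are exchangeable.

**Scenario-separation experiments** (generator purpose-check and the
qualitative-direction acceptance test) set τ = 0: only then is exactly one
metric homogeneous by construction, making the predicted direction flip
(I² and agreement favoring SMD under `smd_fixed`, MD under `md_fixed`) a
property of the metric scale rather than of shared heterogeneity. With the
calibrated default τ = 0.2 both metrics are heterogeneous and the agreement
contrast no longer reverses under `md_fixed` — an observation about the
statistic, recorded here deliberately.

What the generator does *not* emulate: publication bias and small-study
effects, non-normal or skewed outcomes, unequal arm ratios, correlated
outcomes within reviews, and the editorial selection process that produced
real review collections. Passing tests therefore demonstrate correctness of
the computations and the direction of the metric contrast under the stated
model, not the empirical magnitudes in any real corpus.

## Problem sizes and numerical choices

The default experiment sizes — 1068 reviews for the calibrated corpus,
300 per scenario corpus, 500 replicates of 50-trial reviews for τ²
recovery — mirror the corpus scale the generator is calibrated to while
keeping a full run in seconds on one CPU. Floats are serialized at full
double precision (`repr`) so corpus CSV and JSON reports round-trip
bit-exactly; human-readable TSV tables round to one decimal. Degenerate
inputs are rejected loudly: arms with n < 2 or sd ≤ 0, reviews with k < 3,
pooling with k < 2, a DL denominator C ≤ 0 (τ² = 0 with a warning).

## Known limitations

* DL is the only τ² estimator; it is moment-based and noisy at small k
  (the recovery check uses k = 50 for that reason).
* The leave-one-out CI uses the normal quantile, as does the pooled Z —
  no t-distribution small-k adjustment.
* The exact-J gamma-ratio correction is not implemented (negligible at
  df ≥ 2, but a documented extension point).
* Percentage agreement is reported without an uncertainty measure; the
  paired sign test across reviews is the only inferential statement.
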
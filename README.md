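# metamd

**Mean difference or standardized mean difference?** When every randomized
trial in a meta-analysis reports the same continuous outcome in the same
unit, the analyst can pool either the mean difference (MD, in outcome units)
or the standardized mean difference (SMD, in SD units). `metamd` is a
library and CLI for asking, over a whole corpus of meta-analyses, which of
the two metrics is more *generalizable* (lower heterogeneity, better
out-of-study prediction) and which is more *powerful* (larger Z-scores) —
the kind of empirical methods question systematic reviewers and
biostatisticians face when writing analysis plans.

It implements, from trial-level summary statistics (n, mean, SD per arm):

* **Effect sizes** — MD with its exact two-sample variance, and the SMD as
  Hedges' adjusted *g* = J(df)·(m_t−m_c)/s_p with J(df) = 1 − 3/(4df−1),
  under either the Hedges–Olkin or the RevMan variance convention.
* **Pooling** — inverse-variance fixed-effect and DerSimonian–Laird
  random-effects models, with Cochran's Q, τ², and I² = max(0,(Q−df)/Q)·100
  computed from fixed-effect weights.
* **Percentage agreement** — a leave-one-out generalizability statistic:
  the fraction of trials whose point estimate falls inside the 95% CI of
  the meta-analysis of the remaining trials.
* **Paired corpus-level comparisons** — exact sign tests on within-review
  I², agreement and |Z| differences; exact (or continuity-corrected)
  McNemar tests on significance concordance; heterogeneity strata
  (both-metric I² < 60% / < 30%).
* **A calibrated synthetic-corpus generator** — reviews with median 5
  trials (IQR 3–8), median ≈ 500 total participants, median |SMD| ≈ 0.29,
  tunable between-trial heterogeneity and across-trial SD dispersion, so
  the full pipeline is reproducible without any proprietary data.

See [docs/methods.md](docs/methods.md) for formulas, modelling assumptions
and design choices.

## Worked example

```python
from metamd import (SimulationConfig, simulate_corpus,
                    build_review_table, report_from_table)

corpus, cal = simulate_corpus(SimulationConfig(seed=42, n_reviews=200))
print(cal.median_k, cal.median_total_n, round(cal.median_abs_smd_random, 3))
# 5.0 465.0 0.307

table = build_review_table(corpus)          # one row per review
report = report_from_table(table)           # stratified MD-vs-SMD report
s = report.stratum("all")
i2 = s.paired[0]
print(f"median I2: MD {i2.median_md:.1f}% vs SMD {i2.median_smd:.1f}%, "
      f"sign-test p = {i2.p_value:.2g}")
# median I2: MD 56.2% vs SMD 37.1%, sign-test p = 1.5e-13
```

The default scenario holds the true effect constant on the SMD scale while
trial-level population SDs disperse, so the MD inherits the SD spread: the
SMD shows systematically lower I² (37.1% vs 56.2% above, a difference the
paired sign test calls at p ≈ 10⁻¹³), and its leave-one-out agreement is
higher — e.g. in this run's fixed-effect model, median agreement 40.0% for
SMD vs 36.4% for MD across all 200 reviews. The significance cross-tab is
dominated by the diagonal (both metrics significant or neither), so the
metrics rarely disagree about *whether* an effect exists, only about how
generalizable its summary is.

The same analysis runs from the shell:

```sh
metamd simulate --seed 42 --n-reviews 200 --out corpus.csv
metamd analyze --input corpus.csv --i2-thresholds 60,30 --alpha 0.05 \
               --out results/
```

which writes `report.json` (full precision), `per_review.tsv`, and rounded
`table_agreement.tsv` / `table_significance.tsv` analogs. Input CSVs use
the flat schema `review_id,study_id,n_t,mean_t,sd_t,n_c,mean_c,sd_c`, one
row per trial, at least three trials per review.

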
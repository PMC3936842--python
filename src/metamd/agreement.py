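"""Leave-one-out percentage agreement — a generalizability statistic.

For each trial in a meta-analysis, the trial's own point estimate (MD or
SMD) is compared with the 95% confidence interval of the pooled estimate of
the *remaining* trials, re-pooled from scratch (tau^2 re-estimated on each
leave-one-out subset).  The trial "agrees" when its point estimate falls
inside that interval, boundary inclusive.  The percentage agreement of the
meta-analysis is the fraction of its trials that agree: a measure of how
well the pooled result of the other studies predicts the next study.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

from .corpus import Corpus, MetaAnalysisGroup
from .effects import Metric, SMDVariance, compute_effect
from .pooling import Model, pool


@dataclass(frozen=True)
class AgreementResult:
    """Leave-one-out agreement tally for one review under one metric/model."""

    review_id: str
    metric: Metric
    model: Model
    k: int
    n_agree: int
    pct_agreement: float
    per_study_flags: tuple[bool, ...]


@dataclass(frozen=True)
class AgreementSummary:
    """Corpus-level agreement under one metric/model.

    ``median_pct`` is the median of per-review percentage agreements (each
    review counts once); ``pooled_pct`` is the trial-weighted proportion
    sum(n_agree)/sum(k).  They differ when reviews have unequal sizes.
    """

    metric: Metric
    model: Model
    n_reviews: int
    n_trials: int
    n_agree: int
    median_pct: float
    pooled_pct: float


def leave_one_out_agreement(
    group: MetaAnalysisGroup,
    metric: Metric | str,
    model: Model | str,
    variance_form: SMDVariance | str = SMDVariance.HEDGES_OLKIN,
) -> AgreementResult:
    """Tally which trials fall inside the 95% CI pooled from the others.

    Requires k >= 3 so every leave-one-out pool has at least two trials.
    Trials are visited in their stored order.
    """
    metric = Metric(metric)
    model = Model(model)
    group.validate()
    effects = [compute_effect(t, metric, variance_form=variance_form) for t in group.trials]
    flags: list[bool] = []
    for i, held_out in enumerate(effects):
        rest = effects[:i] + effects[i + 1:]
        pooled = pool(rest, model, review_id=group.review_id)
        flags.append(pooled.ci_low <= held_out.estimate <= pooled.ci_high)
    n_agree = sum(flags)
    k = len(group)
    return AgreementResult(
        review_id=group.review_id,
        metric=metric,
        model=model,
        k=k,
        n_agree=n_agree,
        pct_agreement=n_agree / k,
        per_study_flags=tuple(flags),
    )


def corpus_agreement(
    corpus: Corpus,
    metric: Metric | str,
    model: Model | str,
    variance_form: SMDVariance | str = SMDVariance.HEDGES_OLKIN,
) -> tuple[list[AgreementResult], AgreementSummary]:
    """Per-review agreement results plus both corpus summaries."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    results = [
        leave_one_out_agreement(g, metric, model, variance_form=variance_form)
        for g in corpus
    ]
    return results, summarize_agreement(results)


def summarize_agreement(results: Sequence[AgreementResult]) -> AgreementSummary:
    if not results:
        raise ValueError("no agreement results to summarize")
    n_trials = sum(r.k for r in results)
    n_agree = sum(r.n_agree for r in results)
    return AgreementSummary(
        metric=results[0].metric,
        model=results[0].model,
        n_reviews=len(results),
        n_trials=n_trials,
        n_agree=n_agree,
        median_pct=median(r.pct_agreement for r in results),
        pooled_pct=n_agree / n_trials,
    )
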
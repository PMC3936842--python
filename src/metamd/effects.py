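"""Per-trial effect sizes: mean difference and Hedges'-adjusted-g SMD.

For a two-arm trial with treatment summary (n_t, m_t, s_t) and control
summary (n_c, m_c, s_c):

* mean difference        MD = m_t - m_c,  Var = s_t^2/n_t + s_c^2/n_c
* standardized MD        d  = MD / s_p,   s_p the pooled within-group SD
* Hedges' adjusted g     g  = J(df) * d,  df = n_t + n_c - 2

J(df) = 1 - 3/(4*df - 1) removes the small-sample upward bias of d.  The
sampling variance of g defaults to the large-sample Hedges–Olkin form

    Var(g) = (n_t + n_c)/(n_t*n_c) + g^2 / (2*(n_t + n_c))

with the RevMan convention (denominator 2*(n_t + n_c - 3.94)) available as
an alternative.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .corpus import TrialSummary


class Metric(str, enum.Enum):
    MD = "MD"
    SMD = "SMD"


class SMDVariance(str, enum.Enum):
    """Convention for the sampling variance of Hedges' g."""

    HEDGES_OLKIN = "hedges_olkin"
    REVMAN = "revman"


class DegenerateTrialError(ValueError):
    """The pooled within-group SD is zero, so the SMD is undefined."""


@dataclass(frozen=True)
class EffectEstimate:
    """A per-trial point estimate and sampling variance under one metric."""

    study_id: str
    metric: Metric
    estimate: float
    variance: float

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"{self.study_id}: variance must be > 0, got {self.variance}")
        if not math.isfinite(self.estimate):
            raise ValueError(f"{self.study_id}: estimate is not finite")


def compute_md(trial: TrialSummary) -> EffectEstimate:
    """Mean difference with its exact two-sample variance."""
    trial.validate()
    return EffectEstimate(
        study_id=trial.study_id,
        metric=Metric.MD,
        estimate=trial.mean_t - trial.mean_c,
        variance=trial.sd_t**2 / trial.n_t + trial.sd_c**2 / trial.n_c,
    )


def small_sample_correction(df: int) -> float:
    """Hedges' bias-correction factor J(df) = 1 - 3/(4*df - 1).

    Strictly increasing in df and -> 1 as df -> infinity; requires df >= 2.
    This is the standard closed-form approximation to the exact
    gamma-function ratio, universal in meta-analytic software.
    """
    if df < 2:
        raise ValueError(f"df must be >= 2, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def compute_hedges_g(
    trial: TrialSummary,
    variance_form: SMDVariance | str = SMDVariance.HEDGES_OLKIN,
) -> EffectEstimate:
    """Hedges' adjusted g with its sampling variance."""
    trial.validate()
    variance_form = SMDVariance(variance_form)
    n_t, n_c = trial.n_t, trial.n_c
    df = n_t + n_c - 2
    sp2 = ((n_t - 1) * trial.sd_t**2 + (n_c - 1) * trial.sd_c**2) / df
    if sp2 <= 0:
        raise DegenerateTrialError(
            f"{trial.review_id}/{trial.study_id}: pooled SD is zero, SMD undefined"
        )
    d = (trial.mean_t - trial.mean_c) / math.sqrt(sp2)
    g = small_sample_correction(df) * d
    n_total = n_t + n_c
    if variance_form is SMDVariance.HEDGES_OLKIN:
        var = n_total / (n_t * n_c) + g**2 / (2.0 * n_total)
    else:
        var = n_total / (n_t * n_c) + g**2 / (2.0 * (n_total - 3.94))
    return EffectEstimate(study_id=trial.study_id, metric=Metric.SMD, estimate=g, variance=var)


def compute_effect(
    trial: TrialSummary,
    metric: Metric | str,
    variance_form: SMDVariance | str = SMDVariance.HEDGES_OLKIN,
) -> EffectEstimate:
    """Dispatch to :func:`compute_md` or :func:`compute_hedges_g`."""
    metric = Metric(metric)
    if metric is Metric.MD:
        return compute_md(trial)
    return compute_hedges_g(trial, variance_form=variance_form)
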
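"""Inverse-variance pooling: fixed-effect and DerSimonian–Laird random effects.

Given per-trial effects y_i with sampling variances v_i:

* fixed effect: weights w_i = 1/v_i, pooled estimate sum(w y)/sum(w),
  SE = sum(w)^(-1/2).
* heterogeneity: Cochran's Q = sum(w_i (y_i - est_FE)^2) on k-1 df;
  I^2 = max(0, (Q - df)/Q) * 100;
  DL between-trial variance tau^2 = max(0, (Q - df)/C),
  C = sum(w) - sum(w^2)/sum(w).
* random effects: refit with weights w*_i = 1/(v_i + tau^2).

Q and I^2 are computed from fixed-effect weights under both models —
heterogeneity is a property of the data, not of the pooling model — so each
meta-analysis carries a single I^2 per metric.  Confidence intervals use the
exact 0.975 normal quantile, not 1.96 rounded.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import norm

from .effects import EffectEstimate, Metric

logger = logging.getLogger(__name__)

#: Exact standard-normal 0.975 quantile used for all 95% CIs.
Z_975: float = float(norm.ppf(0.975))


class Model(str, enum.Enum):
    FIXED = "fixed"
    RANDOM = "random"


@dataclass(frozen=True)
class PooledResult:
    """One meta-analysis result under one metric and one pooling model."""

    review_id: str
    metric: Metric
    model: Model
    k: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    df: int
    tau2: float
    i2: float


def _check_effects(effects: Sequence[EffectEstimate]) -> Metric:
    if len(effects) < 2:
        raise ValueError(f"need at least 2 effects to pool, got {len(effects)}")
    metrics = {e.metric for e in effects}
    if len(metrics) != 1:
        raise ValueError(f"effects mix metrics {sorted(m.value for m in metrics)}")
    return next(iter(metrics))


def _fixed_weights(effects: Sequence[EffectEstimate]) -> list[float]:
    return [1.0 / e.variance for e in effects]


def _q_statistic(effects: Sequence[EffectEstimate]) -> float:
    """Cochran's Q about the fixed-effect pooled estimate."""
    w = _fixed_weights(effects)
    sw = sum(w)
    est = sum(wi * e.estimate for wi, e in zip(w, effects)) / sw
    return sum(wi * (e.estimate - est) ** 2 for wi, e in zip(w, effects))


def _i_squared(q: float, df: int) -> float:
    if q <= 0.0:
        return 0.0
    return max(0.0, (q - df) / q) * 100.0


def _assemble(
    review_id: str,
    metric: Metric,
    model: Model,
    effects: Sequence[EffectEstimate],
    weights: Sequence[float],
    tau2: float,
) -> PooledResult:
    k = len(effects)
    sw = sum(weights)
    estimate = sum(wi * e.estimate for wi, e in zip(weights, effects)) / sw
    se = sw ** -0.5
    z = estimate / se
    p = 2.0 * float(norm.sf(abs(z)))
    q = _q_statistic(effects)
    df = k - 1
    return PooledResult(
        review_id=review_id,
        metric=metric,
        model=model,
        k=k,
        estimate=estimate,
        se=se,
        ci_low=estimate - Z_975 * se,
        ci_high=estimate + Z_975 * se,
        z=z,
        p=p,
        q=q,
        df=df,
        tau2=tau2,
        i2=_i_squared(q, df),
    )


def pool_fixed(effects: Sequence[EffectEstimate], review_id: str = "") -> PooledResult:
    """Fixed-effect inverse-variance pooling (weights 1/v_i)."""
    metric = _check_effects(effects)
    return _assemble(review_id, metric, Model.FIXED, effects, _fixed_weights(effects), tau2=0.0)


def tau_squared_dl(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian–Laird moment estimator of the between-trial variance.

    tau^2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w); returns 0
    (with a warning) when C is not positive, which happens only when one
    trial carries essentially all the weight.
    """
    _check_effects(effects)
    w = _fixed_weights(effects)
    sw = sum(w)
    c = sw - sum(wi * wi for wi in w) / sw
    if c <= 0.0:
        logger.warning("DL estimator: C <= 0 (single effective study); returning tau2 = 0")
        return 0.0
    q = _q_statistic(effects)
    df = len(effects) - 1
    return max(0.0, (q - df) / c)


def pool_random(effects: Sequence[EffectEstimate], review_id: str = "") -> PooledResult:
    """DerSimonian–Laird random-effects pooling (weights 1/(v_i + tau^2))."""
    metric = _check_effects(effects)
    tau2 = tau_squared_dl(effects)
    weights = [1.0 / (e.variance + tau2) for e in effects]
    return _assemble(review_id, metric, Model.RANDOM, effects, weights, tau2=tau2)


def pool(
    effects: Sequence[EffectEstimate], model: Model | str, review_id: str = ""
) -> PooledResult:
    """Dispatch to :func:`pool_fixed` or :func:`pool_random`."""
    model = Model(model)
    if model is Model.FIXED:
        return pool_fixed(effects, review_id=review_id)
    return pool_random(effects, review_id=review_id)


def significance(result: PooledResult, alpha: float = 0.05) -> bool:
    """Two-sided normal test of the pooled effect: true iff p < alpha (strict)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return result.p < alpha
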
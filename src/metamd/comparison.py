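"""Corpus-level paired comparisons of MD vs. SMD.

Every review is analyzed under both metrics (MD, Hedges' g) and both pooling
models (fixed, random).  The two metrics are then compared *pairwise within
reviews*:

* heterogeneity — exact sign test on paired I^2 values (I^2 is computed
  from fixed-effect weights, so it is model-free);
* generalizability — exact sign test on paired leave-one-out percentage
  agreements, per model;
* statistical power — exact sign test on paired |Z| scores, per model,
  restricted by default to reviews where both metrics show I^2 < 30%
  (comparing power between metrics of unequal heterogeneity is not
  meaningful);
* significance concordance — McNemar test on the discordant cells of the
  2x2 significant/non-significant cross-classification, per model.

Reviews are additionally stratified by heterogeneity: a review enters the
"< t%" stratum only when I^2 of *both* metrics is strictly below t.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import binom, chi2

from .agreement import leave_one_out_agreement
from .corpus import Corpus
from .effects import Metric, SMDVariance, compute_effect
from .pooling import Model, pool, significance

logger = logging.getLogger(__name__)


class Quantity(str, enum.Enum):
    I2 = "i2"
    PCT_AGREEMENT = "pct_agreement"
    ABS_Z = "abs_z"


class McNemarMethod(str, enum.Enum):
    EXACT = "exact"
    CC_CHI2 = "cc_chi2"


MODEL_FREE = "model_free"


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the corpus analysis; defaults reproduce the full design."""

    models: tuple[Model, ...] = (Model.RANDOM, Model.FIXED)
    i2_thresholds: tuple[float, ...] = (60.0, 30.0)
    alpha: float = 0.05
    smd_variance: SMDVariance = SMDVariance.HEDGES_OLKIN
    mcnemar_method: McNemarMethod = McNemarMethod.EXACT
    #: By default the |Z| comparison runs only in the lowest-threshold
    #: stratum; set True to run it in every stratum.
    z_all_strata: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if list(self.i2_thresholds) != sorted(self.i2_thresholds, reverse=True) or len(
            set(self.i2_thresholds)
        ) != len(self.i2_thresholds):
            raise ValueError(f"i2_thresholds must be strictly decreasing: {self.i2_thresholds}")
        if not self.models:
            raise ValueError("at least one pooling model required")


@dataclass(frozen=True)
class SignTestResult:
    """Exact paired sign test: two-sided binomial on non-tied differences."""

    n_pairs: int
    n_pos: int
    n_neg: int
    n_ties: int
    p_value: float


@dataclass(frozen=True)
class PairedComparison:
    """A sign-test comparison of one quantity between MD and SMD."""

    quantity: Quantity
    model: str  # a Model value or "model_free"
    n_pairs: int
    n_pos: int  # reviews with MD > SMD
    n_neg: int  # reviews with MD < SMD
    n_ties: int
    median_md: float
    median_smd: float
    p_value: float


@dataclass(frozen=True)
class SignificanceCrossTab:
    """2x2 cross-classification of MD/SMD significance with McNemar p."""

    model: Model
    both_sig: int
    md_only: int
    smd_only: int
    neither: int
    p_value: float


@dataclass(frozen=True)
class StratumReport:
    name: str
    threshold: float | None  # None for the all-reviews stratum
    n_reviews: int
    paired: tuple[PairedComparison, ...]
    crosstabs: tuple[SignificanceCrossTab, ...]


@dataclass(frozen=True)
class ComparisonReport:
    strata: tuple[StratumReport, ...]
    options: AnalysisOptions

    def stratum(self, name: str) -> StratumReport:
        for s in self.strata:
            if s.name == name:
                return s
        raise KeyError(name)


def sign_test(diffs: Sequence[float]) -> SignTestResult:
    """Exact two-sided sign test, ties excluded.

    p = min(1, 2 * P(X <= min(n_pos, n_neg))) for X ~ Binomial(n_pos+n_neg, 1/2).
    All-tied input gives p = 1 with a warning.
    """
    if len(diffs) == 0:
        raise ValueError("sign test needs at least one pair")
    n_pos = sum(1 for d in diffs if d > 0)
    n_neg = sum(1 for d in diffs if d < 0)
    n_ties = len(diffs) - n_pos - n_neg
    n = n_pos + n_neg
    if n == 0:
        logger.warning("sign test: all %d pairs tied; p = 1", n_ties)
        p = 1.0
    else:
        p = min(1.0, 2.0 * float(binom.cdf(min(n_pos, n_neg), n, 0.5)))
    return SignTestResult(n_pairs=len(diffs), n_pos=n_pos, n_neg=n_neg, n_ties=n_ties, p_value=p)


def mcnemar_test(
    md_only: int, smd_only: int, method: McNemarMethod | str = McNemarMethod.EXACT
) -> float:
    """McNemar test on the discordant counts of a paired 2x2 table.

    ``exact``: two-sided binomial on the discordant pairs, capped at 1.
    ``cc_chi2``: continuity-corrected (|b-c|-1)^2/(b+c) against chi^2(1).
    Zero discordant pairs give p = 1 under either method.
    """
    if md_only < 0 or smd_only < 0:
        raise ValueError("discordant counts must be non-negative")
    method = McNemarMethod(method)
    b, c = md_only, smd_only
    n = b + c
    if n == 0:
        return 1.0
    if method is McNemarMethod.EXACT:
        return min(1.0, 2.0 * float(binom.cdf(min(b, c), n, 0.5)))
    stat = (abs(b - c) - 1.0) ** 2 / n
    return float(chi2.sf(stat, df=1))


def stratify_by_i2(
    i2_by_review: Mapping[str, tuple[float, float]],
    thresholds: Sequence[float],
) -> dict[float, set[str]]:
    """Map each threshold t to reviews with I^2(MD) < t AND I^2(SMD) < t.

    The inequality is strict, so a review sitting exactly at a threshold is
    excluded.  Strata are nested by construction when thresholds decrease.
    """
    return {
        t: {rid for rid, (i2_md, i2_smd) in i2_by_review.items() if i2_md < t and i2_smd < t}
        for t in thresholds
    }


# ---------------------------------------------------------------------------
# Per-review analysis table


def build_review_table(corpus: Corpus, options: AnalysisOptions = AnalysisOptions()) -> pd.DataFrame:
    """Analyze every review under both metrics and the configured models.

    Returns one row per review with columns ``i2_<metric>``,
    ``tau2_<metric>_<model>``, ``est/se/z/p/sig_<metric>_<model>`` and
    ``agree_<metric>_<model>`` (the leave-one-out percentage agreement).
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    rows = []
    for group in corpus:
        row: dict[str, object] = {"review_id": group.review_id, "k": len(group)}
        for metric in (Metric.MD, Metric.SMD):
            m = metric.value.lower()
            effects = [
                compute_effect(t, metric, variance_form=options.smd_variance)
                for t in group.trials
            ]
            for model in options.models:
                pooled = pool(effects, model, review_id=group.review_id)
                agr = leave_one_out_agreement(
                    group, metric, model, variance_form=options.smd_variance
                )
                suffix = f"{m}_{model.value}"
                row[f"est_{suffix}"] = pooled.estimate
                row[f"se_{suffix}"] = pooled.se
                row[f"z_{suffix}"] = pooled.z
                row[f"p_{suffix}"] = pooled.p
                row[f"sig_{suffix}"] = significance(pooled, options.alpha)
                row[f"tau2_{suffix}"] = pooled.tau2
                row[f"agree_{suffix}"] = agr.pct_agreement
                row[f"nagree_{suffix}"] = agr.n_agree
                # I^2 comes from fixed-effect weights: identical across models
                row[f"i2_{m}"] = pooled.i2
        rows.append(row)
    return pd.DataFrame(rows)


def _paired(
    table: pd.DataFrame, quantity: Quantity, model_label: str, col_md: str, col_smd: str
) -> PairedComparison:
    if len(table) == 0:
        return PairedComparison(
            quantity=quantity, model=model_label, n_pairs=0, n_pos=0, n_neg=0,
            n_ties=0, median_md=math.nan, median_smd=math.nan, p_value=math.nan,
        )
    md = table[col_md].tolist()
    smd = table[col_smd].tolist()
    st = sign_test([a - b for a, b in zip(md, smd)])
    return PairedComparison(
        quantity=quantity,
        model=model_label,
        n_pairs=st.n_pairs,
        n_pos=st.n_pos,
        n_neg=st.n_neg,
        n_ties=st.n_ties,
        median_md=median(md),
        median_smd=median(smd),
        p_value=st.p_value,
    )


def _crosstab(
    table: pd.DataFrame, model: Model, method: McNemarMethod
) -> SignificanceCrossTab:
    sig_md = table[f"sig_md_{model.value}"].astype(bool)
    sig_smd = table[f"sig_smd_{model.value}"].astype(bool)
    both = int((sig_md & sig_smd).sum())
    md_only = int((sig_md & ~sig_smd).sum())
    smd_only = int((~sig_md & sig_smd).sum())
    neither = int((~sig_md & ~sig_smd).sum())
    p = mcnemar_test(md_only, smd_only, method=method) if len(table) else math.nan
    return SignificanceCrossTab(
        model=model, both_sig=both, md_only=md_only, smd_only=smd_only,
        neither=neither, p_value=p,
    )


def _stratum_name(threshold: float | None) -> str:
    if threshold is None:
        return "all"
    t = int(threshold) if float(threshold).is_integer() else threshold
    return f"both_i2_lt_{t}"


def report_from_table(
    table: pd.DataFrame, options: AnalysisOptions = AnalysisOptions()
) -> ComparisonReport:
    """Assemble the stratified comparison report from a per-review table."""
    membership = stratify_by_i2(
        {r.review_id: (r.i2_md, r.i2_smd) for r in table.itertuples()},
        options.i2_thresholds,
    )
    lowest = min(options.i2_thresholds) if options.i2_thresholds else None
    strata: list[StratumReport] = []
    for threshold in (None, *options.i2_thresholds):
        sub = (
            table
            if threshold is None
            else table[table["review_id"].isin(membership[threshold])]
        )
        if len(sub) == 0:
            logger.warning("stratum %s is empty; tests skipped", _stratum_name(threshold))
        paired: list[PairedComparison] = [
            _paired(sub, Quantity.I2, MODEL_FREE, "i2_md", "i2_smd")
        ]
        for model in options.models:
            paired.append(
                _paired(
                    sub, Quantity.PCT_AGREEMENT, model.value,
                    f"agree_md_{model.value}", f"agree_smd_{model.value}",
                )
            )
        run_z = options.z_all_strata or (threshold is not None and threshold == lowest)
        if run_z:
            for model in options.models:
                zsub = sub.copy()
                zsub["absz_md"] = zsub[f"z_md_{model.value}"].abs()
                zsub["absz_smd"] = zsub[f"z_smd_{model.value}"].abs()
                paired.append(
                    _paired(zsub, Quantity.ABS_Z, model.value, "absz_md", "absz_smd")
                )
        crosstabs = tuple(
            _crosstab(sub, model, options.mcnemar_method) for model in options.models
        )
        strata.append(
            StratumReport(
                name=_stratum_name(threshold),
                threshold=threshold,
                n_reviews=len(sub),
                paired=tuple(paired),
                crosstabs=crosstabs,
            )
        )
    return ComparisonReport(strata=tuple(strata), options=options)


def build_report(
    corpus: Corpus, options: AnalysisOptions = AnalysisOptions()
) -> ComparisonReport:
    """Analyze a corpus and assemble the stratified MD-vs-SMD report."""
    return report_from_table(build_review_table(corpus, options), options)
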
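"""Independent brute-force re-implementations used as test oracles.

These deliberately share no code with the package: effects and pooling are
recomputed with numpy array arithmetic straight from the defining formulas,
and the leave-one-out agreement is enumerated holdout by holdout.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm

Z = norm.ppf(0.975)


def oracle_effect(trial, metric):
    """(estimate, variance) for one trial, straight from the formulas."""
    n_t, m_t, s_t = trial.n_t, trial.mean_t, trial.sd_t
    n_c, m_c, s_c = trial.n_c, trial.mean_c, trial.sd_c
    if metric == "MD":
        return m_t - m_c, s_t**2 / n_t + s_c**2 / n_c
    df = n_t + n_c - 2
    sp = math.sqrt(((n_t - 1) * s_t**2 + (n_c - 1) * s_c**2) / df)
    d = (m_t - m_c) / sp
    j = 1 - 3 / (4 * df - 1)
    g = j * d
    n = n_t + n_c
    return g, n / (n_t * n_c) + g**2 / (2 * n)


def oracle_pool(y, v, model):
    """Weighted-mean pooling as a dict of numpy scalars."""
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    w = 1.0 / v
    est_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - est_fe) ** 2))
    df = len(y) - 1
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    if model == "fixed":
        tau2 = 0.0
        ww = w
    else:
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        ww = 1.0 / (v + tau2)
    est = float(np.sum(ww * y) / np.sum(ww))
    se = float(np.sum(ww) ** -0.5)
    return {
        "estimate": est,
        "se": se,
        "ci_low": est - Z * se,
        "ci_high": est + Z * se,
        "z": est / se,
        "p": 2 * float(norm.sf(abs(est / se))),
        "q": q,
        "df": df,
        "tau2": tau2,
        "i2": i2,
    }


def oracle_agreement_flags(group, metric, model):
    """Re-pool every holdout from the raw trials; return inclusion flags."""
    eff = [oracle_effect(t, metric) for t in group.trials]
    flags = []
    for i in range(len(eff)):
        rest = eff[:i] + eff[i + 1:]
        pooled = oracle_pool([e for e, _ in rest], [v for _, v in rest], model)
        est_i = eff[i][0]
        flags.append(pooled["ci_low"] <= est_i <= pooled["ci_high"])
    return flags


def oracle_binom_two_sided(k_min, n):
    """Two-sided exact binomial(1/2) p-value by direct pmf enumeration."""
    if n == 0:
        return 1.0
    tail = sum(math.comb(n, i) for i in range(k_min + 1)) / 2**n
    return min(1.0, 2.0 * tail)
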
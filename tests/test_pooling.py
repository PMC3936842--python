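"""Fixed-effect and DerSimonian–Laird pooling, heterogeneity, significance."""

import json
import shutil
import subprocess

import numpy as np
import pytest

from metamd import (
    EffectEstimate,
    Metric,
    Model,
    PooledResult,
    compute_hedges_g,
    compute_md,
    pool_fixed,
    pool_random,
    significance,
    tau_squared_dl,
)

from conftest import make_trial, random_group
from oracles import oracle_pool

REL = 1e-10


def eff(estimates, variances, metric=Metric.MD):
    return [
        EffectEstimate(study_id=f"s{i}", metric=metric, estimate=y, variance=v)
        for i, (y, v) in enumerate(zip(estimates, variances))
    ]


class TestFixedEffect:
    def test_identical_effects_degenerate_homogeneity(self):
        r = pool_fixed(eff([1.7] * 4, [0.5] * 4))
        assert r.estimate == pytest.approx(1.7, rel=REL)
        assert r.se == pytest.approx((0.5 / 4) ** 0.5, rel=REL)
        assert r.q == pytest.approx(0.0, abs=1e-12)
        assert r.i2 == 0.0

    def test_two_effect_hand_example(self):
        r = pool_fixed(eff([0.0, 2.0], [1.0, 1.0]))
        assert r.estimate == pytest.approx(1.0, rel=REL)
        assert r.se == pytest.approx(2**-0.5, rel=REL)
        assert r.q == pytest.approx(2.0, rel=REL)
        assert r.df == 1
        assert r.i2 == pytest.approx(50.0, rel=REL)

    def test_permutation_invariance(self, rng):
        ys, vs = rng.normal(size=6), rng.uniform(0.1, 2, 6)
        perm = rng.permutation(6)
        a = pool_fixed(eff(ys, vs))
        b = pool_fixed(eff(ys[perm], vs[perm]))
        for f in ("estimate", "se", "q", "i2"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-12)

    def test_rejects_single_effect_and_mixed_metrics(self):
        with pytest.raises(ValueError):
            pool_fixed(eff([1.0], [1.0]))
        mixed = eff([0.0, 1.0], [1.0, 1.0])[:1] + eff([0.0, 1.0], [1.0, 1.0], Metric.SMD)[1:]
        with pytest.raises(ValueError):
            pool_fixed(mixed)


class TestTauSquared:
    def test_homogeneous_truncates_to_zero(self):
        assert tau_squared_dl(eff([1.0] * 5, [1.0] * 5)) == 0.0

    def test_two_effect_hand_example(self):
        # q = 2, df = 1, C = 2 - 2/2 = 1
        assert tau_squared_dl(eff([0.0, 2.0], [1.0, 1.0])) == pytest.approx(1.0, rel=REL)

    def test_location_invariance(self, rng):
        ys, vs = rng.normal(size=8), rng.uniform(0.1, 2, 8)
        assert tau_squared_dl(eff(ys, vs)) == pytest.approx(
            tau_squared_dl(eff(ys + 13.7, vs)), rel=1e-9
        )


class TestRandomEffects:
    def test_reduces_to_fixed_when_tau2_zero(self):
        effects = eff([1.0] * 4, [0.3, 0.5, 0.7, 0.9])
        f, r = pool_fixed(effects), pool_random(effects)
        assert r.tau2 == 0.0
        assert r.estimate == pytest.approx(f.estimate, rel=REL)
        assert r.se == pytest.approx(f.se, rel=REL)

    def test_two_effect_hand_example(self):
        r = pool_random(eff([0.0, 2.0], [1.0, 1.0]))
        assert r.tau2 == pytest.approx(1.0, rel=REL)
        assert r.estimate == pytest.approx(1.0, rel=REL)
        assert r.se == pytest.approx(1.0, rel=REL)
        assert r.ci_low == pytest.approx(1 - 1.959963984540054, rel=1e-9)
        assert r.ci_high == pytest.approx(1 + 1.959963984540054, rel=1e-9)

    def test_random_se_never_below_fixed_se(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 12))
            effects = eff(rng.normal(size=k), rng.uniform(0.05, 3, k))
            assert pool_random(effects).se >= pool_fixed(effects).se - 1e-15


class TestOracleEquivalence:
    def test_brute_force_agreement_on_random_meta_analyses(self, rng):
        """FE/RE pooling matches an independent implementation to 1e-10."""
        fields = ("estimate", "se", "ci_low", "ci_high", "z", "p", "q", "tau2", "i2")
        for _ in range(1000):
            k = int(rng.integers(2, 11))
            ys = rng.normal(0, 2, k)
            vs = rng.uniform(0.01, 4, k)
            for model, fn in (("fixed", pool_fixed), ("random", pool_random)):
                ours = fn(eff(ys, vs))
                ref = oracle_pool(ys, vs, model)
                for f in fields:
                    got, want = getattr(ours, f), ref[f]
                    assert got == pytest.approx(want, rel=1e-10, abs=1e-12), (model, f)


class TestInvariantsUnderRescaling:
    def test_md_equivariant_smd_invariant(self, rng):
        group = random_group(rng, k=6)
        c = 3.7
        scaled = [
            make_trial(t.review_id, t.study_id, t.n_t, t.mean_t * c, t.sd_t * c,
                       t.n_c, t.mean_c * c, t.sd_c * c)
            for t in group.trials
        ]
        for fn in (pool_fixed, pool_random):
            a = fn([compute_md(t) for t in group.trials])
            b = fn([compute_md(t) for t in scaled])
            assert b.estimate == pytest.approx(c * a.estimate, rel=1e-9)
            assert b.se == pytest.approx(c * a.se, rel=1e-9)
            for f in ("z", "q", "i2", "p"):
                assert getattr(b, f) == pytest.approx(getattr(a, f), rel=1e-9)
            ga = fn([compute_hedges_g(t) for t in group.trials])
            gb = fn([compute_hedges_g(t) for t in scaled])
            for f in ("estimate", "se", "z", "q", "i2", "p"):
                assert getattr(gb, f) == pytest.approx(getattr(ga, f), rel=1e-9)


class TestSignificance:
    def test_zero_z_never_significant(self):
        r = pool_fixed(eff([0.0, 0.0], [1.0, 1.0]))
        assert not significance(r, alpha=0.999)

    def test_boundary_is_strict(self):
        # p exactly alpha must not count as significant
        r = pool_fixed(eff([1.0, 1.0], [1.0, 1.0]))
        assert not significance(r, alpha=r.p)

    def test_bonferroni_alpha_flips_borderline_calls(self):
        # z ~ 2.5: p ~ 0.012, significant at 0.05 but not at 0.0042
        r = pool_fixed(eff([1.25, 1.25], [0.5, 0.5]))
        assert 0.0042 <= r.p < 0.05
        assert significance(r, alpha=0.05)
        assert not significance(r, alpha=0.0042)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_matches_metafor_reference(tmp_path, rng):
    """Cross-check FE and DL pooling against R's metafor on one fixture."""
    k = 6
    ys = rng.normal(0.3, 0.5, k)
    vs = rng.uniform(0.02, 0.3, k)
    script = tmp_path / "ref.R"
    script.write_text(
        "suppressMessages(library(metafor))\n"
        f"yi <- c({','.join(repr(float(y)) for y in ys)})\n"
        f"vi <- c({','.join(repr(float(v)) for v in vs)})\n"
        "fe <- rma(yi, vi, method='FE')\n"
        "re <- rma(yi, vi, method='DL')\n"
        "cat(sprintf('%.12g %.12g %.12g %.12g %.12g %.12g %.12g %.12g\\n',\n"
        "    fe$beta, fe$se, fe$QE, fe$I2, re$beta, re$se, re$tau2, re$I2))\n"
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    fe_b, fe_se, fe_q, fe_i2, re_b, re_se, re_t2, re_i2 = map(float, out.stdout.split())
    f = pool_fixed(eff(ys, vs))
    r = pool_random(eff(ys, vs))
    assert f.estimate == pytest.approx(fe_b, rel=1e-8)
    assert f.se == pytest.approx(fe_se, rel=1e-8)
    assert f.q == pytest.approx(fe_q, rel=1e-8)
    assert f.i2 == pytest.approx(fe_i2, abs=1e-4)
    assert r.estimate == pytest.approx(re_b, rel=1e-8)
    assert r.se == pytest.approx(re_se, rel=1e-8)
    assert r.tau2 == pytest.approx(re_t2, rel=1e-6)
    assert r.i2 == pytest.approx(re_i2, abs=1e-4)
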
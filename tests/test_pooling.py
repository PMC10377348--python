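"""Pooling core: oracle equivalence, fixture reproduction, invariants."""

import math
import random

import numpy as np
import pytest
from scipy import stats

from allelemeta import (
    EffectEstimate,
    InsufficientStudiesError,
    cochran_q,
    meta_analyse,
    pool_fixed,
    pool_random_dl,
    select_model,
    z_test,
)


def _est(study_id, log_or, se):
    return EffectEstimate(
        study_id=study_id,
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain-Python transcription of the textbook
# inverse-variance / method-of-moments formulas, no numpy, no shared code
# ---------------------------------------------------------------------------
def oracle_pool(ys, ses, model):
    ws = [1.0 / s**2 for s in ses]
    mean_fixed = sum(w * y for w, y in zip(ws, ys)) / sum(ws)
    q = sum(w * (y - mean_fixed) ** 2 for w, y in zip(ws, ys))
    df = len(ys) - 1
    c = sum(ws) - sum(w * w for w in ws) / sum(ws)
    tau2 = max(0.0, (q - df) / c)
    if model == "fixed":
        weights = ws
    else:
        weights = [1.0 / (s**2 + tau2) for s in ses]
    mu = sum(w * y for w, y in zip(weights, ys)) / sum(weights)
    se = (1.0 / sum(weights)) ** 0.5
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return mu, se, q, tau2, i2


def test_pooling_matches_brute_force_oracle_on_random_instances():
    """200 random small meta-analyses agree with the independent oracle to 1e-10."""
    rng = random.Random(20230707)
    for _ in range(200):
        k = rng.randint(2, 6)
        ys = [rng.uniform(-1.5, 1.5) for _ in range(k)]
        ses = [rng.uniform(0.05, 0.8) for _ in range(k)]
        ests = [_est(f"s{i}", y, s) for i, (y, s) in enumerate(zip(ys, ses))]
        for model, fn in (("fixed", pool_fixed), ("random", pool_random_dl)):
            mu, se, q, tau2, i2 = oracle_pool(ys, ses, model)
            pool = fn(ests)
            assert pool.log_or == pytest.approx(mu, abs=1e-10)
            assert pool.se == pytest.approx(se, abs=1e-10)
            assert pool.het.q == pytest.approx(q, abs=1e-10)
            assert pool.het.tau2 == pytest.approx(tau2, abs=1e-10)
            assert pool.het.i2 == pytest.approx(i2, abs=1e-10)


def test_pooling_cross_checked_against_statsmodels(fixture_estimates):
    """Fixed and DL pooled effects on the fixture match statsmodels' meta-analysis."""
    sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
    y = np.array([e.log_or for e in fixture_estimates])
    v = np.array([e.se**2 for e in fixture_estimates])
    res = sm_meta.combine_effects(y, v, method_re="dl")
    frame = res.summary_frame()
    fixed = pool_fixed(fixture_estimates)
    rand = pool_random_dl(fixture_estimates)
    assert fixed.log_or == pytest.approx(frame.loc["fixed effect", "eff"], abs=1e-10)
    assert rand.log_or == pytest.approx(frame.loc["random effect", "eff"], abs=1e-10)
    assert rand.het.tau2 == pytest.approx(res.tau2, abs=1e-10)
    assert rand.het.q == pytest.approx(res.q, abs=1e-10)


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------
def test_identical_estimates_have_no_dispersion():
    ests = [_est(f"s{i}", 0.3, 0.1) for i in range(4)]
    het = cochran_q(ests)
    assert het.q == pytest.approx(0.0, abs=1e-12)
    assert het.i2 == 0.0
    assert het.tau2 == 0.0


def test_heterogeneity_requires_two_studies():
    with pytest.raises(InsufficientStudiesError):
        cochran_q([_est("only", 0.1, 0.2)])


def test_central_subgroup_extreme_heterogeneity(region_estimates):
    het = cochran_q(region_estimates("Central"))
    assert het.i2 == pytest.approx(98.6, abs=0.05)


def test_northeast_subgroup_homogeneous(region_estimates):
    het = cochran_q(region_estimates("Northeast"))
    assert het.i2 == 0.0


# ---------------------------------------------------------------------------
# pooling behaviour
# ---------------------------------------------------------------------------
def test_single_study_fixed_pool_is_identity():
    est = _est("only", 0.25, 0.12)
    pool = pool_fixed([est])
    assert pool.model == "fixed"
    assert pool.k == 1
    assert pool.log_or == pytest.approx(est.log_or)
    assert pool.se == pytest.approx(est.se)
    assert pool.het is None


def test_random_reduces_to_fixed_when_homogeneous():
    ests = [_est(f"s{i}", 0.3, se) for i, se in enumerate((0.1, 0.1, 0.1))]
    fixed, rand = pool_fixed(ests), pool_random_dl(ests)
    assert rand.het.tau2 == 0.0
    assert rand.log_or == pytest.approx(fixed.log_or, abs=1e-12)
    assert rand.se == pytest.approx(fixed.se, abs=1e-12)


def test_pooled_effect_is_convex_and_permutation_invariant(fixture_estimates):
    for fn in (pool_fixed, pool_random_dl, meta_analyse):
        pool = fn(fixture_estimates)
        los = [e.log_or for e in fixture_estimates]
        assert min(los) <= pool.log_or <= max(los)
        shuffled = list(fixture_estimates)
        random.Random(5).shuffle(shuffled)
        again = fn(shuffled)
        assert again.log_or == pytest.approx(pool.log_or, abs=1e-12)
        assert again.se == pytest.approx(pool.se, abs=1e-12)
        assert sum(pool.weights) == pytest.approx(1.0, abs=1e-12)


def test_random_se_never_below_fixed_se(fixture_estimates):
    fixed, rand = pool_fixed(fixture_estimates), pool_random_dl(fixture_estimates)
    assert rand.se >= fixed.se
    assert rand.het.tau2 > 0  # fixture is heterogeneous, so strictly wider


# ---------------------------------------------------------------------------
# model selection and Z test
# ---------------------------------------------------------------------------
def test_selection_rule_requires_both_conditions():
    from allelemeta.pooling import HeterogeneityResult

    assert select_model(HeterogeneityResult(50, 1, 1e-10, 98.6, 0.5)) == "random"
    assert select_model(HeterogeneityResult(1.0, 2, 0.6, 0.0, 0.0)) == "fixed"
    # i2 > 50 but p(Q) too large -> fixed
    assert select_model(HeterogeneityResult(3.0, 1, 0.2, 60.0, 0.1)) == "fixed"
    # p(Q) small but i2 at exactly 50 -> fixed (strict inequality)
    assert select_model(HeterogeneityResult(10.0, 5, 0.05, 50.0, 0.1)) == "fixed"


def test_selection_rule_on_fixture_regions(fixture_estimates, region_estimates):
    assert meta_analyse(fixture_estimates).model == "random"
    assert meta_analyse(region_estimates("Central")).model == "random"
    assert meta_analyse(region_estimates("East")).model == "random"
    assert meta_analyse(region_estimates("Northeast")).model == "fixed"
    assert meta_analyse(region_estimates("South")).model == "fixed"


def test_z_test_definition():
    z, p = z_test(0.0, 0.5)
    assert (z, p) == (0.0, pytest.approx(1.0))
    z, p = z_test(1.96 * 0.1, 0.1)
    assert p == pytest.approx(0.05, abs=1e-3)
    with pytest.raises(ValueError):
        z_test(0.1, 0.0)


def test_northeast_pooled_z_test_is_highly_significant(region_estimates):
    pool = pool_fixed(region_estimates("Northeast"))
    # printed as p = 1.00e-4; the Z statistic itself gives ~6e-5
    assert pool.p < 1.1e-4
    assert pool.p == pytest.approx(2 * stats.norm.sf(pool.log_or / pool.se), rel=1e-12)


def test_meta_analyse_requires_two_studies():
    with pytest.raises(InsufficientStudiesError):
        meta_analyse([_est("only", 0.1, 0.2)])
    with pytest.raises(InsufficientStudiesError):
        pool_fixed([])
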
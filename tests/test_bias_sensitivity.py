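"""Subgroups, leave-one-out sensitivity, funnel data, Egger's regression."""

import math

import numpy as np
import pytest

from allelemeta import (
    DegenerateDesignError,
    EffectEstimate,
    InsufficientStudiesError,
    StudyTable,
    egger_test,
    funnel_data,
    leave_one_out,
    study_effects,
    subgroup_analysis,
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
# subgroups
# ---------------------------------------------------------------------------
def test_subgroup_analysis_reproduces_regional_pools(fixture_table):
    by_region = {s.region: s for s in subgroup_analysis(fixture_table)}
    assert round(by_region["Northeast"].pool.or_value, 2) == 1.28
    assert by_region["Northeast"].pool.model == "fixed"
    assert round(by_region["East"].pool.or_value, 2) == 1.21
    assert by_region["East"].pool.model == "random"
    assert round(by_region["South"].pool.or_value, 2) == 1.16
    assert by_region["South"].pool.model == "fixed"
    assert round(by_region["Central"].pool.or_value, 2) == 0.94
    assert by_region["Central"].pool.model == "random"
    assert not by_region["North"].sufficient  # single study: not pooled


def test_multi_region_study_enters_no_subgroup(fixture_table):
    results = subgroup_analysis(fixture_table)
    assert "Multi" not in {s.region for s in results}
    pooled_ids = {sid for s in results if s.pool for sid in s.pool.study_ids}
    assert "Xue 2009" not in pooled_ids
    # accounting: pooled + insufficient + excluded == all studies
    insufficient = sum(s.k for s in results if not s.sufficient)
    assert len(pooled_ids) + insufficient + 1 == len(fixture_table)


def test_single_region_table_pools_like_whole_table(fixture_table):
    east = StudyTable([r for r in fixture_table.records if r.region == "East"])
    (only,) = subgroup_analysis(east)
    from allelemeta import meta_analyse

    whole = meta_analyse(study_effects(east.records))
    assert only.pool.log_or == pytest.approx(whole.log_or, abs=1e-12)


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------
def test_leave_one_out_cardinality_and_k(fixture_estimates):
    results = leave_one_out(fixture_estimates)
    assert len(results) == 14
    assert all(r.pool.k == 13 for r in results)
    assert {r.omitted_study for r in results} == {e.study_id for e in fixture_estimates}


def test_leave_one_out_of_identical_estimates_is_constant():
    ests = [_est(f"s{i}", 0.2, 0.1) for i in range(5)]
    results = leave_one_out(ests)
    first = results[0].pool
    for r in results[1:]:
        assert r.pool.log_or == pytest.approx(first.log_or, abs=1e-12)
        assert r.pool.model == first.model  # homogeneous: model never changes


def test_northeast_association_robust_to_any_single_omission(region_estimates):
    """Omitting any Northeast study leaves the pooled CI entirely above 1."""
    for r in leave_one_out(region_estimates("Northeast")):
        assert r.pool.or_value > 1
        assert r.pool.ci_low > 1


def test_leave_one_out_requires_three_studies():
    with pytest.raises(InsufficientStudiesError):
        leave_one_out([_est("a", 0.1, 0.2), _est("b", 0.2, 0.2)])


# ---------------------------------------------------------------------------
# funnel + Egger
# ---------------------------------------------------------------------------
def test_funnel_data_is_verbatim_coordinates(fixture_estimates):
    points = funnel_data(fixture_estimates)
    assert len(points) == 14
    assert funnel_data([]) == []
    two = funnel_data([_est("a", 0.1, 0.05), _est("b", -0.1, 0.5)])
    assert [p.y for p in two] == [0.05, 0.5]
    assert [p.x for p in two] == [pytest.approx(0.1), pytest.approx(-0.1)]


def test_egger_matches_statsmodels_ols(fixture_estimates):
    sm = pytest.importorskip("statsmodels.api")
    y = np.array([e.log_or / e.se for e in fixture_estimates])
    x = sm.add_constant(np.array([1 / e.se for e in fixture_estimates]))
    fit = sm.OLS(y, x).fit()
    res = egger_test(fixture_estimates)
    assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
    assert res.p == pytest.approx(fit.pvalues[0], abs=1e-10)
    assert res.df == 12


def test_symmetric_funnel_has_near_zero_intercept():
    # pairs mirrored about a common effect with matched se -> no asymmetry
    ests = []
    for i, (delta, se) in enumerate([(0.1, 0.1), (0.3, 0.25), (0.5, 0.4)]):
        ests.append(_est(f"up{i}", 0.2 + delta, se))
        ests.append(_est(f"dn{i}", 0.2 - delta, se))
    res = egger_test(ests)
    assert abs(res.intercept) < 1e-9


def test_egger_sign_equivariance(fixture_estimates):
    mirrored = [_est(e.study_id, -e.log_or, e.se) for e in fixture_estimates]
    forward = egger_test(fixture_estimates)
    backward = egger_test(mirrored)
    assert backward.intercept == pytest.approx(-forward.intercept, abs=1e-10)
    assert backward.p == pytest.approx(forward.p, abs=1e-10)


def test_egger_degenerate_and_small_inputs():
    with pytest.raises(InsufficientStudiesError):
        egger_test([_est("a", 0.1, 0.2), _est("b", 0.2, 0.2)])
    same_se = [_est(f"s{i}", y, 0.2) for i, y in enumerate((0.1, 0.2, 0.3))]
    with pytest.raises(DegenerateDesignError):
        egger_test(same_se)
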
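"""Subgroup analysis, leave-one-out sensitivity, funnel data, and Egger's test.

Subgroups are formed by region tag; studies spanning several regions (tag
"Multi" by default) belong to no subgroup, and regions with fewer studies than
``min_k`` are marked insufficient rather than pooled.  Leave-one-out
sensitivity re-pools after omitting each study in turn, re-running
heterogeneity and (in "auto" mode) model selection on each reduced set.

Publication-bias assessment uses the funnel-plot coordinates (log-OR vs
standard error) and Egger's regression in its classic form: unweighted
ordinary least squares of the standardized effect y_i/se_i on the precision
1/se_i, with the intercept tested two-sided against zero on a t distribution
with k-2 df.  A non-zero intercept indicates small-study asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effect_stats import EffectEstimate, study_effects
from .errors import DegenerateDesignError, InsufficientStudiesError
from .pooling import (
    DEFAULT_HET_I2_THRESHOLD,
    DEFAULT_HET_P_THRESHOLD,
    PoolResult,
    meta_analyse,
    pool_fixed,
    pool_random_dl,
)
from .study_data import StudyTable

MULTI_REGION_TAG = "Multi"


@dataclass(frozen=True)
class SubgroupResult:
    """One region's pooled result, or an insufficient-data marker (pool is None)."""

    region: str
    k: int
    pool: Optional[PoolResult]

    @property
    def sufficient(self) -> bool:
        return self.pool is not None


@dataclass(frozen=True)
class LeaveOneOutResult:
    omitted_study: str
    pool: PoolResult


@dataclass(frozen=True)
class EggerResult:
    """Egger regression intercept test: t on k-2 df against intercept = 0."""

    intercept: float
    intercept_se: float
    t: float
    df: int
    p: float
    slope: float


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    x: float  # log-OR
    y: float  # standard error


def subgroup_analysis(
    table: StudyTable,
    min_k: int = 2,
    exclude_tag: str = MULTI_REGION_TAG,
    p_threshold: float = DEFAULT_HET_P_THRESHOLD,
    i2_threshold: float = DEFAULT_HET_I2_THRESHOLD,
) -> list[SubgroupResult]:
    """Pool each region with at least ``min_k`` studies; mark the rest insufficient.

    Studies tagged ``exclude_tag`` (multi-region cohorts) enter no subgroup.
    Regions are reported in first-appearance order.
    """
    results = []
    for region in table.regions:
        if region == exclude_tag:
            continue
        members = [r for r in table.records if r.region == region]
        if len(members) >= min_k:
            pool = meta_analyse(
                study_effects(members), p_threshold=p_threshold, i2_threshold=i2_threshold
            )
        else:
            pool = None
        results.append(SubgroupResult(region=region, k=len(members), pool=pool))
    return results


def leave_one_out(
    estimates: Sequence[EffectEstimate],
    model_rule: str = "auto",
    p_threshold: float = DEFAULT_HET_P_THRESHOLD,
    i2_threshold: float = DEFAULT_HET_I2_THRESHOLD,
) -> list[LeaveOneOutResult]:
    """Re-pool k times, each run omitting one study.

    ``model_rule`` is "auto" (re-select fixed/random per reduced set), "fixed",
    or "random".
    """
    if len(estimates) < 3:
        raise InsufficientStudiesError(
            f"leave-one-out requires at least 3 studies, got {len(estimates)}"
        )
    if model_rule not in ("auto", "fixed", "random"):
        raise ValueError(f"unknown model_rule {model_rule!r}")
    results = []
    for i, omitted in enumerate(estimates):
        rest = [e for j, e in enumerate(estimates) if j != i]
        if model_rule == "fixed":
            pool = pool_fixed(rest)
        elif model_rule == "random":
            pool = pool_random_dl(rest)
        else:
            pool = meta_analyse(rest, p_threshold=p_threshold, i2_threshold=i2_threshold)
        results.append(LeaveOneOutResult(omitted_study=omitted.study_id, pool=pool))
    return results


def funnel_data(estimates: Sequence[EffectEstimate]) -> list[FunnelPoint]:
    """Funnel-plot coordinates: effect (log-OR) against its standard error."""
    return [FunnelPoint(study_id=e.study_id, x=e.log_or, y=e.se) for e in estimates]


def egger_test(estimates: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry (classic unweighted OLS)."""
    if len(estimates) < 3:
        raise InsufficientStudiesError(
            f"Egger's test requires at least 3 studies, got {len(estimates)}"
        )
    y = np.array([e.log_or for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    precision = 1.0 / se
    if np.ptp(precision) == 0.0:
        raise DegenerateDesignError(
            "all studies share one standard error; Egger precision term is constant "
            "and the regression is unidentifiable"
        )
    fit = stats.linregress(precision, y / se)
    df = len(estimates) - 2
    t = fit.intercept / fit.intercept_stderr
    p = float(2.0 * stats.t.sf(abs(t), df))
    return EggerResult(
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
        t=float(t),
        df=df,
        p=p,
        slope=float(fit.slope),
    )
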
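"""Meta-analysis core: inverse-variance pooling, heterogeneity, model selection.

Two pooling models operate on per-study log odds ratios y_i with Woolf
standard errors se_i:

* **fixed effect** — one common true effect; weights w_i = 1/se_i^2, pooled
  effect sum(w_i y_i)/sum(w_i), SE 1/sqrt(sum w_i).
* **random effects (DerSimonian-Laird)** — true effects vary between studies
  with variance tau^2 estimated by the method of moments,
  tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w); weights
  become w_i* = 1/(se_i^2 + tau^2).

Heterogeneity is quantified by Cochran's Q (chi-squared with k-1 df under
homogeneity) and I^2 = max(0, (Q - (k-1))/Q) * 100%.  The model-selection rule
follows the conventional screening used in genetic-association meta-analyses:
random effects when Q's p-value < 0.1 AND I^2 > 50%, fixed effect otherwise.
Pooled effects are tested against zero (OR of 1) with a Z test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effect_stats import EffectEstimate
from .errors import InsufficientStudiesError

#: Thresholds of the heterogeneity-driven model-selection rule.
DEFAULT_HET_P_THRESHOLD = 0.1
DEFAULT_HET_I2_THRESHOLD = 50.0
DEFAULT_Z_CRIT = 1.96


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its df and p, I^2 (percent), and DL tau^2 (log-OR scale)."""

    q: float
    df: int
    p_q: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PoolResult:
    """A pooled log-OR with CI, Z test, per-study relative weights, and heterogeneity."""

    model: str  # "fixed" | "random"
    k: int
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    study_ids: tuple[str, ...]
    weights: tuple[float, ...]  # relative, sum to 1
    het: Optional[HeterogeneityResult]  # None when k == 1


def _arrays(estimates: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.log_or for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    return y, se


def cochran_q(estimates: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q over fixed-effect weights, with I^2 and DL tau^2."""
    if len(estimates) < 2:
        raise InsufficientStudiesError(
            f"heterogeneity requires at least 2 studies, got {len(estimates)}"
        )
    y, se = _arrays(estimates)
    w = 1.0 / se**2
    y_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fixed) ** 2))
    df = len(estimates) - 1
    p_q = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_q=p_q, i2=i2, tau2=tau2)


def z_test(log_or: float, se: float) -> tuple[float, float]:
    """Two-sided Z test of a log odds ratio against zero: returns (z, p)."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = log_or / se
    return z, float(2.0 * stats.norm.sf(abs(z)))


def _assemble(
    model: str,
    estimates: Sequence[EffectEstimate],
    weights: np.ndarray,
    het: Optional[HeterogeneityResult],
    z_crit: float,
) -> PoolResult:
    y, _ = _arrays(estimates)
    w_sum = float(np.sum(weights))
    log_or = float(np.sum(weights * y) / w_sum)
    se = 1.0 / math.sqrt(w_sum)
    z, p = z_test(log_or, se)
    rel = weights / w_sum
    return PoolResult(
        model=model,
        k=len(estimates),
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z_crit * se),
        ci_high=math.exp(log_or + z_crit * se),
        z=z,
        p=p,
        study_ids=tuple(e.study_id for e in estimates),
        weights=tuple(float(v) for v in rel),
        het=het,
    )


def pool_fixed(estimates: Sequence[EffectEstimate], z_crit: float = DEFAULT_Z_CRIT) -> PoolResult:
    """Inverse-variance fixed-effect pooling; k = 1 returns the single estimate."""
    if len(estimates) == 0:
        raise InsufficientStudiesError("fixed-effect pooling requires at least 1 study")
    _, se = _arrays(estimates)
    het = cochran_q(estimates) if len(estimates) >= 2 else None
    return _assemble("fixed", estimates, 1.0 / se**2, het, z_crit)


def pool_random_dl(
    estimates: Sequence[EffectEstimate], z_crit: float = DEFAULT_Z_CRIT
) -> PoolResult:
    """DerSimonian-Laird random-effects pooling (reduces to fixed when tau^2 = 0)."""
    if len(estimates) < 2:
        raise InsufficientStudiesError(
            f"random-effects pooling requires at least 2 studies, got {len(estimates)}"
        )
    _, se = _arrays(estimates)
    het = cochran_q(estimates)
    return _assemble("random", estimates, 1.0 / (se**2 + het.tau2), het, z_crit)


def select_model(
    het: HeterogeneityResult,
    p_threshold: float = DEFAULT_HET_P_THRESHOLD,
    i2_threshold: float = DEFAULT_HET_I2_THRESHOLD,
) -> str:
    """Model-selection rule: "random" iff p(Q) < 0.1 AND I^2 > 50%, else "fixed"."""
    return "random" if (het.p_q < p_threshold and het.i2 > i2_threshold) else "fixed"


def meta_analyse(
    estimates: Sequence[EffectEstimate],
    p_threshold: float = DEFAULT_HET_P_THRESHOLD,
    i2_threshold: float = DEFAULT_HET_I2_THRESHOLD,
    z_crit: float = DEFAULT_Z_CRIT,
) -> PoolResult:
    """Heterogeneity test, model selection, then the selected pooling."""
    if len(estimates) < 2:
        raise InsufficientStudiesError(
            f"meta-analysis requires at least 2 studies, got {len(estimates)}"
        )
    het = cochran_q(estimates)
    if select_model(het, p_threshold, i2_threshold) == "random":
        return pool_random_dl(estimates, z_crit=z_crit)
    return pool_fixed(estimates, z_crit=z_crit)
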
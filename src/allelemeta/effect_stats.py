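"""Per-study statistics: allele tables, odds ratios, and the HWE chi-squared test.

The association contrast is the additive (allelic) model: each genotyped
subject contributes two alleles, so the genotype triple (CC, CT, TT) collapses
to allele counts C = 2*CC + CT and T = 2*TT + CT, giving a 2x2 allele-by-arm
table.  The effect measure is the allelic odds ratio; its log is estimated by
the cross-product ratio with the Woolf variance (sum of reciprocal cell
counts).  A table containing a zero cell receives the Haldane-Anscombe +0.5
continuity correction in all four cells before estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .errors import DegenerateTableError, MonomorphicError
from .study_data import StudyRecord


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table (C/T alleles by case/control arm).

    Cells are floats because the continuity correction adds 0.5; uncorrected
    tables hold exact integers.
    """

    case_c: float
    case_t: float
    control_c: float
    control_t: float
    corrected: bool = False

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.case_c, self.case_t, self.control_c, self.control_t)


@dataclass(frozen=True)
class EffectEstimate:
    """A study's log odds ratio, its standard error, and the 95% CI on the OR scale."""

    study_id: str
    log_or: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class HWEResult:
    """Hardy-Weinberg goodness-of-fit chi-squared for one genotype triple."""

    chi2: float
    df: int
    p: float
    allele_freq: float  # C-allele frequency in the tested group


def allele_table(record: StudyRecord) -> AlleleTable:
    """Collapse a study's genotype counts to the 2x2 allele table (additive model)."""
    c_cc, c_ct, c_tt = record.case_genotypes
    g_cc, g_ct, g_tt = record.control_genotypes
    return AlleleTable(
        case_c=2 * c_cc + c_ct,
        case_t=2 * c_tt + c_ct,
        control_c=2 * g_cc + g_ct,
        control_t=2 * g_tt + g_ct,
        corrected=False,
    )


def odds_ratio(table: AlleleTable, z_crit: float = 1.96, study_id: str = "") -> EffectEstimate:
    """Allelic odds ratio with Woolf (log-scale) standard error and 95% CI.

    If any raw cell is zero, 0.5 is added to all four cells first
    (Haldane-Anscombe) and the returned computation uses the corrected table.
    A table with an entire zero margin (no alleles in one row or column) has
    no defined odds ratio and raises :class:`DegenerateTableError`.
    """
    a, b, c, d = table.cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise DegenerateTableError(
            f"allele table {table.cells} has an empty margin; odds ratio undefined"
        )
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        study_id=study_id,
        log_or=log_or,
        se=se,
        or_value=math.exp(log_or),
        ci_low=math.exp(log_or - z_crit * se),
        ci_high=math.exp(log_or + z_crit * se),
    )


def study_effect(record: StudyRecord, z_crit: float = 1.96) -> EffectEstimate:
    """Convenience: allele table then odds ratio for one study record."""
    return odds_ratio(allele_table(record), z_crit=z_crit, study_id=record.study_id)


def study_effects(records: Sequence[StudyRecord], z_crit: float = 1.96) -> list[EffectEstimate]:
    return [study_effect(r, z_crit=z_crit) for r in records]


def hwe_chisq(genotypes: Sequence[int]) -> HWEResult:
    """Plain (uncorrected) 1-df chi-squared goodness-of-fit test of Hardy-Weinberg
    proportions for one genotype triple (CC, CT, TT).

    The allele frequency is estimated from the data, which costs one degree of
    freedom: df = 3 categories - 1 - 1 estimated parameter = 1.  Monomorphic
    input (one allele absent) leaves nothing to test and raises
    :class:`MonomorphicError`.
    """
    cc, ct, tt = genotypes
    if min(cc, ct, tt) < 0:
        raise ValueError(f"negative genotype count in {genotypes!r}")
    n = cc + ct + tt
    if n == 0:
        raise ValueError("empty genotype triple")
    p_hat = (2 * cc + ct) / (2 * n)
    if p_hat == 0.0 or p_hat == 1.0:
        raise MonomorphicError(f"genotypes {tuple(genotypes)} are monomorphic; HWE test undefined")
    q_hat = 1.0 - p_hat
    expected = (n * p_hat * p_hat, 2 * n * p_hat * q_hat, n * q_hat * q_hat)
    chi2 = sum((obs - exp) ** 2 / exp for obs, exp in zip((cc, ct, tt), expected))
    return HWEResult(chi2=chi2, df=1, p=float(stats.chi2.sf(chi2, 1)), allele_freq=p_hat)
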
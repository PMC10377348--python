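"""Synthetic case-control cohorts with known truth, for estimator validation.

The generator mirrors the statistical structure the meta-analysis assumes.
Per study i:

* a control C-allele frequency p0_i is drawn uniformly on ``p0_range``;
* the study's true allelic log odds ratio is theta_i = mu + N(0, tau2),
  so ``tau2`` is the between-study variance on the log-OR scale;
* the case allele frequency follows from the allelic odds model,
  p1_i = odds/(1+odds) with odds = exp(theta_i) * p0_i/(1-p0_i);
* genotype counts in each arm are drawn from the trinomial of Hardy-Weinberg
  proportions (p^2, 2pq, q^2) at that arm's allele frequency.

Giving cases HWE proportions at their shifted allele frequency matches the
allele-level (additive) analysis; it is an approximation to any particular
genotype-level penetrance model.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .effect_stats import study_effects
from .errors import ConfigError
from .pooling import PoolResult, meta_analyse
from .study_data import StudyRecord, StudyTable


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one synthetic meta-analysis.

    Defaults mirror the fixture's shape: 14 studies of a few hundred subjects
    per arm, a common C-allele frequency in the 0.2-0.5 band, a true allelic
    OR of 1.15, and moderate between-study variance (tau ~ 0.3 on the log-OR
    scale), which is the territory the fixture's estimates occupy.
    """

    k_studies: int = 14
    n_cases_range: tuple[int, int] = (100, 900)
    n_controls_range: tuple[int, int] = (100, 900)
    p0_range: tuple[float, float] = (0.2, 0.5)
    true_log_or: float = math.log(1.15)
    tau2: float = 0.09
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_studies < 1:
            raise ConfigError(f"k_studies must be >= 1, got {self.k_studies}")
        for name, (lo, hi) in (
            ("n_cases_range", self.n_cases_range),
            ("n_controls_range", self.n_controls_range),
        ):
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} must be a non-empty positive interval, got ({lo}, {hi})")
        lo, hi = self.p0_range
        if not (0.01 <= lo <= hi <= 0.99):
            raise ConfigError(
                f"p0_range must lie within [0.01, 0.99] and be non-empty, got ({lo}, {hi})"
            )
        if self.tau2 < 0:
            raise ConfigError(f"tau2 must be non-negative, got {self.tau2}")


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregates over repeated simulated meta-analyses."""

    reps: int
    mean_pooled_log_or: float
    ci_coverage: float  # fraction of reps whose 95% CI covers true_log_or
    rejection_rate: float  # fraction of reps with Z-test p < 0.05
    mean_tau2_hat: float


def _hwe_genotypes(rng: np.random.Generator, n: int, p: float) -> tuple[int, int, int]:
    cc, ct, tt = rng.multinomial(n, [p * p, 2 * p * (1 - p), (1 - p) ** 2])
    return int(cc), int(ct), int(tt)


def simulate_studies(config: SimulationConfig) -> StudyTable:
    """Draw one synthetic study table under the allelic odds model."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.k_studies):
        n_cases = int(rng.integers(config.n_cases_range[0], config.n_cases_range[1] + 1))
        n_controls = int(rng.integers(config.n_controls_range[0], config.n_controls_range[1] + 1))
        p0 = float(rng.uniform(*config.p0_range))
        theta = config.true_log_or + math.sqrt(config.tau2) * float(rng.standard_normal())
        odds1 = math.exp(theta) * p0 / (1.0 - p0)
        p1 = odds1 / (1.0 + odds1)
        # redraw the rare monomorphic arm so every record is analysable
        while True:
            case_g = _hwe_genotypes(rng, n_cases, p1)
            control_g = _hwe_genotypes(rng, n_controls, p0)
            if sum(case_g) > 0 and sum(control_g) > 0:
                break
        records.append(
            StudyRecord(
                study_id=f"sim{i + 1:03d}",
                region="Sim",
                n_cases=n_cases,
                n_controls=n_controls,
                case_genotypes=case_g,
                control_genotypes=control_g,
            )
        )
    return StudyTable(records=records, provenance=f"simulated:seed={config.seed}")


def run_recovery(config: SimulationConfig, reps: int) -> SimulationSummary:
    """Repeatedly simulate + meta-analyse; summarise bias, coverage, and power.

    Coverage and rejection refer to the pooled 95% CI / Z test produced by the
    heterogeneity-driven model selection, judged against ``true_log_or``.
    Per-rep seeds are spawned from ``config.seed`` so the whole run is
    reproducible.
    """
    if reps < 1:
        raise ConfigError(f"reps must be >= 1, got {reps}")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(reps) & 0x7FFFFFFF
    pooled, covered, rejected, tau2_hats = [], 0, 0, []
    for s in child_seeds:
        table = simulate_studies(replace(config, seed=int(s)))
        pool = meta_analyse(study_effects(table.records))
        pooled.append(pool.log_or)
        lo = pool.log_or - 1.96 * pool.se
        hi = pool.log_or + 1.96 * pool.se
        covered += int(lo <= config.true_log_or <= hi)
        rejected += int(pool.p < 0.05)
        tau2_hats.append(pool.het.tau2 if pool.het is not None else 0.0)
    return SimulationSummary(
        reps=reps,
        mean_pooled_log_or=float(np.mean(pooled)),
        ci_coverage=covered / reps,
        rejection_rate=rejected / reps,
        mean_tau2_hat=float(np.mean(tau2_hats)),
    )
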
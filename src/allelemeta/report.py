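"""Pipeline orchestration and report emission.

``run_pipeline`` executes the full analysis on a study table — validation,
per-study effects, overall pooling with heterogeneity-driven model selection,
region subgroups, leave-one-out sensitivity, and funnel/Egger publication-bias
assessment — and (optionally) writes a report bundle: ``summary.json``,
``forest.csv`` (study_id, OR, ci_low, ci_high, weight_pct, se),
``funnel.csv`` (study_id, log_or, se), and a plain-text ``report.txt``.

Displayed numbers are rounded half-even to 2 decimals (1 decimal for I^2
percentages); the JSON carries full precision.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Optional, Union

import yaml

from .bias_sensitivity import (
    EggerResult,
    FunnelPoint,
    LeaveOneOutResult,
    SubgroupResult,
    egger_test,
    funnel_data,
    leave_one_out,
    subgroup_analysis,
)
from .effect_stats import EffectEstimate, study_effects
from .errors import AlleleMetaError
from .pooling import PoolResult, meta_analyse
from .study_data import (
    StudyTable,
    ValidationReport,
    load_study_table,
    total_counts,
    validate_studies,
)

logger = logging.getLogger("allelemeta")


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Display rounding: IEEE round-half-even at a decimal precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and paths for one pipeline run (defaults are the package's
    standard screening levels: HWE p < 0.001, random effects when p(Q) < 0.1
    and I^2 > 50%, z critical value 1.96, subgroups pooled from 2 studies)."""

    input_path: Union[str, Path]
    hwe_threshold: float = 0.001
    het_p_threshold: float = 0.1
    het_i2_threshold: float = 50.0
    z_crit: float = 1.96
    min_subgroup_k: int = 2
    output_dir: Optional[Union[str, Path]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name, v, lo, hi in (
            ("hwe_threshold", self.hwe_threshold, 0.0, 1.0),
            ("het_p_threshold", self.het_p_threshold, 0.0, 1.0),
            ("het_i2_threshold", self.het_i2_threshold, 0.0, 100.0),
        ):
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if self.z_crit <= 0:
            raise ValueError(f"z_crit must be positive, got {self.z_crit}")
        if self.min_subgroup_k < 1:
            raise ValueError(f"min_subgroup_k must be >= 1, got {self.min_subgroup_k}")


def config_from_yaml(path: Union[str, Path], **overrides) -> PipelineConfig:
    """Read a PipelineConfig from a YAML mapping; keyword arguments override."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


@dataclass
class ReportBundle:
    """Everything one pipeline run produced, in memory."""

    config: PipelineConfig
    table: StudyTable
    validation: list[ValidationReport]
    estimates: list[EffectEstimate]
    overall: PoolResult
    subgroups: list[SubgroupResult]
    loo: list[LeaveOneOutResult]
    funnel: list[FunnelPoint]
    egger: EggerResult


def _pool_dict(pool: PoolResult) -> dict:
    d = {
        "model": pool.model,
        "k": pool.k,
        "log_or": pool.log_or,
        "se": pool.se,
        "or": pool.or_value,
        "ci_low": pool.ci_low,
        "ci_high": pool.ci_high,
        "z": pool.z,
        "p": pool.p,
        "study_ids": list(pool.study_ids),
        "weights": list(pool.weights),
    }
    if pool.het is not None:
        d["heterogeneity"] = {
            "q": pool.het.q,
            "df": pool.het.df,
            "p_q": pool.het.p_q,
            "i2": pool.het.i2,
            "tau2": pool.het.tau2,
        }
    return d


def summary_dict(bundle: ReportBundle) -> dict:
    """JSON-ready summary of a pipeline run (full precision, schema-stable)."""
    cases, controls = total_counts(bundle.table)
    return {
        "input": str(bundle.config.input_path),
        "n_studies": len(bundle.table),
        "total_cases": cases,
        "total_controls": controls,
        "validation": [
            {
                "study_id": v.study_id,
                "case_sum_mismatch": v.case_sum_mismatch,
                "control_sum_mismatch": v.control_sum_mismatch,
                "hwe_flag": v.hwe_flag,
                "messages": list(v.messages),
            }
            for v in bundle.validation
        ],
        "studies": [
            {
                "study_id": e.study_id,
                "log_or": e.log_or,
                "se": e.se,
                "or": e.or_value,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in bundle.estimates
        ],
        "overall": _pool_dict(bundle.overall),
        "subgroups": [
            {
                "region": s.region,
                "k": s.k,
                "pool": _pool_dict(s.pool) if s.pool is not None else None,
                "sufficient": s.sufficient,
            }
            for s in bundle.subgroups
        ],
        "leave_one_out": [
            {"omitted_study": r.omitted_study, "pool": _pool_dict(r.pool)} for r in bundle.loo
        ],
        "egger": {
            "intercept": bundle.egger.intercept,
            "intercept_se": bundle.egger.intercept_se,
            "t": bundle.egger.t,
            "df": bundle.egger.df,
            "p": bundle.egger.p,
            "slope": bundle.egger.slope,
        },
    }


def _fmt_pool(pool: PoolResult) -> str:
    r2 = round_half_even
    parts = [
        f"model={pool.model}",
        f"k={pool.k}",
        f"OR={r2(pool.or_value):.2f}",
        f"95% CI {r2(pool.ci_low):.2f}-{r2(pool.ci_high):.2f}",
        f"Z={r2(pool.z):.2f}",
        f"p={pool.p:.3g}",
    ]
    if pool.het is not None:
        parts.append(f"I2={round_half_even(pool.het.i2, 1):.1f}%")
        parts.append(f"p(Q)={pool.het.p_q:.3g}")
    return ", ".join(parts)


def render_text_report(bundle: ReportBundle) -> str:
    """Human-readable report covering every stage of the run."""
    cases, controls = total_counts(bundle.table)
    lines = [
        "Allelic odds-ratio meta-analysis report",
        "=" * 41,
        f"Input: {bundle.config.input_path}",
        f"Studies: {len(bundle.table)} ({cases} cases, {controls} controls)",
        "",
        "Validation",
        "-" * 10,
    ]
    flagged = [v for v in bundle.validation if v.messages]
    if not flagged:
        lines.append("No inconsistencies detected.")
    for v in flagged:
        for m in v.messages:
            lines.append(f"  {v.study_id}: {m}")
    lines += ["", "Per-study allelic odds ratios", "-" * 29]
    for e in bundle.estimates:
        lines.append(
            f"  {e.study_id:<12s} OR={round_half_even(e.or_value):.2f} "
            f"(95% CI {round_half_even(e.ci_low):.2f}-{round_half_even(e.ci_high):.2f})"
        )
    lines += ["", "Overall pooled estimate", "-" * 23, "  " + _fmt_pool(bundle.overall)]
    lines += ["", "Subgroups by region", "-" * 19]
    for s in bundle.subgroups:
        if s.pool is None:
            lines.append(f"  {s.region:<10s} k={s.k}: insufficient data to pool")
        else:
            lines.append(f"  {s.region:<10s} " + _fmt_pool(s.pool))
    lines += ["", "Leave-one-out sensitivity", "-" * 25]
    for r in bundle.loo:
        lines.append(f"  without {r.omitted_study:<12s} " + _fmt_pool(r.pool))
    lines += [
        "",
        "Publication bias (Egger's regression)",
        "-" * 37,
        f"  intercept={round_half_even(bundle.egger.intercept):.2f} "
        f"(SE {round_half_even(bundle.egger.intercept_se):.2f}), "
        f"t={round_half_even(bundle.egger.t):.2f} on {bundle.egger.df} df, "
        f"p={bundle.egger.p:.2f}",
        "",
    ]
    return "\n".join(lines)


def write_bundle(bundle: ReportBundle, output_dir: Union[str, Path]) -> dict[str, Path]:
    """Write summary.json, forest.csv, funnel.csv and report.txt; return paths."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out / "summary.json",
        "forest": out / "forest.csv",
        "funnel": out / "funnel.csv",
        "report": out / "report.txt",
    }
    paths["summary"].write_text(
        json.dumps(summary_dict(bundle), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    with paths["forest"].open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["study_id", "OR", "ci_low", "ci_high", "weight_pct", "se"])
        weight = dict(zip(bundle.overall.study_ids, bundle.overall.weights))
        for e in bundle.estimates:
            w.writerow(
                [
                    e.study_id,
                    repr(e.or_value),
                    repr(e.ci_low),
                    repr(e.ci_high),
                    repr(100.0 * weight[e.study_id]),
                    repr(e.se),
                ]
            )
    with paths["funnel"].open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["study_id", "log_or", "se"])
        for pt in bundle.funnel:
            w.writerow([pt.study_id, repr(pt.x), repr(pt.y)])
    paths["report"].write_text(render_text_report(bundle), encoding="utf-8")
    return paths


def run_pipeline(config: PipelineConfig, table: Optional[StudyTable] = None) -> ReportBundle:
    """Execute the full analysis; write the report bundle if output_dir is set.

    Stages: validate -> per-study effects -> overall meta-analysis -> region
    subgroups -> leave-one-out -> funnel/Egger.  Any stage failure surfaces as
    an :class:`AlleleMetaError` naming the stage.
    """
    if table is None:
        table = load_study_table(config.input_path)
    if len(table) == 0:
        raise AlleleMetaError("validate: the study table contains no records")

    validation = validate_studies(table, hwe_threshold=config.hwe_threshold)
    for v in validation:
        for m in v.messages:
            logger.warning("%s: %s", v.study_id, m)

    estimates = study_effects(table.records, z_crit=config.z_crit)
    overall = meta_analyse(
        estimates,
        p_threshold=config.het_p_threshold,
        i2_threshold=config.het_i2_threshold,
        z_crit=config.z_crit,
    )
    subgroups = subgroup_analysis(
        table,
        min_k=config.min_subgroup_k,
        p_threshold=config.het_p_threshold,
        i2_threshold=config.het_i2_threshold,
    )
    for s in subgroups:
        if not s.sufficient:
            logger.warning("subgroup %s: only %d study(ies); not pooled", s.region, s.k)
    excluded = [r.study_id for r in table.records if r.region == "Multi"]
    for sid in excluded:
        logger.warning("subgroup analysis: %s spans multiple regions; excluded", sid)

    loo = leave_one_out(
        estimates,
        model_rule="auto",
        p_threshold=config.het_p_threshold,
        i2_threshold=config.het_i2_threshold,
    )
    funnel = funnel_data(estimates)
    egger = egger_test(estimates)

    bundle = ReportBundle(
        config=config,
        table=table,
        validation=validation,
        estimates=estimates,
        overall=overall,
        subgroups=subgroups,
        loo=loo,
        funnel=funnel,
        egger=egger,
    )
    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle
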
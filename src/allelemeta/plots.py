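"""Optional forest and funnel plot rendering (decoration over the data tables)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

from .bias_sensitivity import FunnelPoint
from .effect_stats import EffectEstimate
from .pooling import PoolResult


def forest_plot(
    estimates: Sequence[EffectEstimate], pool: PoolResult, path: Union[str, Path]
) -> None:
    """Per-study ORs with 95% CIs on a log axis, plus the pooled diamond row."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.45 * (len(estimates) + 2) + 1))
    ys = range(len(estimates), 0, -1)
    for y, e in zip(ys, estimates):
        ax.plot([e.ci_low, e.ci_high], [y, y], color="0.3", lw=1)
        ax.plot(e.or_value, y, "s", color="0.1", ms=4)
    ax.plot([pool.ci_low, pool.ci_high], [0, 0], color="tab:red", lw=2)
    ax.plot(pool.or_value, 0, "D", color="tab:red", ms=6)
    ax.axvline(1.0, color="0.7", lw=0.8, ls="--")
    ax.set_yticks(list(ys) + [0])
    ax.set_yticklabels([e.study_id for e in estimates] + [f"Pooled ({pool.model})"])
    ax.set_xscale("log")
    ax.set_xlabel("Odds ratio (log scale)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def funnel_plot(points: Sequence[FunnelPoint], pool: PoolResult, path: Union[str, Path]) -> None:
    """Study OR against standard error, inverted y axis, pooled effect line."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot([math.exp(p.x) for p in points], [p.y for p in points], "o", color="0.2", ms=5)
    ax.axvline(pool.or_value, color="tab:red", lw=1, ls="--")
    ax.set_xscale("log")
    ax.invert_yaxis()
    ax.set_xlabel("Odds ratio (log scale)")
    ax.set_ylabel("Standard error of log OR")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
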
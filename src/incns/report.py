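"""Cohort accounting, proportion formatting and report assembly."""

from __future__ import annotations

from dataclasses import asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np

from .valstats import (
    CutoffMetrics,
    DiagnosticComparison,
    OutcomeRecord,
    ProbabilityCurve,
    RocResult,
)

__all__ = [
    "enrolled_count",
    "proportion_percent",
    "cohort_summary",
    "roc_to_dict",
    "cutoff_to_dict",
    "comparison_to_dict",
    "build_report",
    "plot_roc_overlay",
    "plot_metric_bars",
    "plot_probability_curve",
]


def enrolled_count(admitted: int, lost_to_followup: int) -> int:
    """Patients available for analysis after follow-up losses."""
    if lost_to_followup < 0 or admitted < 0:
        raise ValueError("counts must be non-negative")
    if lost_to_followup > admitted:
        raise ValueError("lost-to-follow-up exceeds admitted")
    return admitted - lost_to_followup


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding at ``decimals`` places, the way
    cohort tables print proportions."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(outcomes: Iterable[OutcomeRecord]) -> dict:
    """Outcome accounting: favorable/unfavorable/died counts and
    one-decimal percentages."""
    recs = list(outcomes)
    n = len(recs)
    if n == 0:
        raise ValueError("no outcome records")
    fav = sum(1 for r in recs if not r.unfavorable)
    unfav = n - fav
    died = sum(1 for r in recs if r.died)
    return {
        "n": n,
        "favorable": fav,
        "unfavorable": unfav,
        "died": died,
        "favorable_pct": proportion_percent(fav, n),
        "unfavorable_pct": proportion_percent(unfav, n),
        "died_pct": proportion_percent(died, n),
    }


def roc_to_dict(r: RocResult) -> dict:
    return {
        "name": r.name,
        "window": r.window,
        "auc": r.auc,
        "ci95": list(r.ci95),
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
    }


def cutoff_to_dict(c: CutoffMetrics) -> dict:
    d = asdict(c)
    d["youden"] = c.youden
    return d


def comparison_to_dict(c: DiagnosticComparison) -> dict:
    d = asdict(c)
    d["ci_a"] = list(c.ci_a)
    d["ci_b"] = list(c.ci_b)
    return d


def build_report(
    rocs: Sequence[RocResult],
    cutoffs: dict[str, CutoffMetrics],
    comparisons: Sequence[DiagnosticComparison],
    probability: Optional[ProbabilityCurve] = None,
    cohort: Optional[dict] = None,
) -> dict:
    report = {
        "roc": [roc_to_dict(r) for r in rocs],
        "cutoffs": {name: cutoff_to_dict(c) for name, c in cutoffs.items()},
        "comparisons": [comparison_to_dict(c) for c in comparisons],
    }
    if probability is not None:
        report["probability_curve"] = {
            "intercept": probability.intercept,
            "slope": probability.slope,
            "penalized": probability.penalized,
            "score": probability.grid.tolist(),
            "p_unfavorable": probability.probability.tolist(),
        }
    if cohort is not None:
        report["cohort"] = cohort
    return report


# --------------------------------------------------------------------------
# plots (optional; figures mirror the usual score-validation layout)


def _mpl_axes(ax):
    if ax is not None:
        return ax, None
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    return ax, fig


def plot_roc_overlay(rocs: Sequence[RocResult], ax=None, path=None):
    ax, fig = _mpl_axes(ax)
    for r in rocs:
        ax.plot(r.fpr, r.tpr, label=f"{r.name} AUC={r.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    if fig is not None and path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax


def plot_metric_bars(cutoffs: dict[str, CutoffMetrics], ax=None, path=None):
    ax, fig = _mpl_axes(ax)
    metrics = ["sensitivity", "specificity", "ppv", "npv", "cc"]
    names = list(cutoffs)
    width = 0.8 / max(len(names), 1)
    x = np.arange(len(metrics))
    for i, name in enumerate(names):
        vals = [getattr(cutoffs[name], m) for m in metrics]
        ax.bar(x + i * width, vals, width=width, label=name)
    ax.set_xticks(x + width * (len(names) - 1) / 2)
    ax.set_xticklabels([m.upper() if len(m) <= 3 else m for m in metrics], fontsize=8)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    if fig is not None and path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax


def plot_probability_curve(curve: ProbabilityCurve, ax=None, path=None):
    ax, fig = _mpl_axes(ax)
    ax.plot(curve.grid, curve.probability, marker="o", ms=3)
    ax.set_xlabel("score")
    ax.set_ylabel("P(unfavorable outcome)")
    ax.set_ylim(0, 1)
    if fig is not None and path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax
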
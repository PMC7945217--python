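"""Paired cohort statistics: mean ± SD summaries and the two-sided Wilcoxon
matched-pair signed-rank test.

The signed-rank p-value is exact (full null distribution of the positive rank
sum, computed by a generating-function recursion over midranks) whenever the
number of non-zero differences is at most ``EXACT_N_MAX``; beyond that a
normal approximation with continuity and tie corrections is used.  Zero
differences are dropped before ranking and tied absolute differences receive
midranks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .complexity import DEFAULT_CLOSED_GAP, score_plan
from .rtplan import Plan

__all__ = [
    "PairedCohort",
    "ComparisonRow",
    "ALPHA",
    "EXACT_N_MAX",
    "summarize",
    "signed_rank_statistic",
    "exact_signed_rank_pvalue",
    "wilcoxon_paired",
    "plan_metric_table",
    "compare_cohorts",
    "adjust_pvalues",
    "rows_to_records",
    "COMPARISON_METRICS",
]

ALPHA = 0.05
EXACT_N_MAX = 25

COMPARISON_METRICS = ("MU", "SW", "SA", "LSV", "AAV", "MCS")


@dataclass
class PairedCohort:
    """Matched per-plan (or per-segment) values for one metric on two systems."""

    metric_name: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired value lists must be equal-length 1-D arrays")
        if self.values_a.size < 2:
            raise ValueError("paired cohort needs at least 2 pairs")


@dataclass
class ComparisonRow:
    """One line of a two-system comparison table (mean ± SD and p-value)."""

    metric_name: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: float
    significant: bool
    n: int
    method: str = "exact"
    all_zero_differences: bool = False


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n − 1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("summary requires at least 2 values")
    return float(np.mean(v)), float(np.std(v, ddof=1))


def signed_rank_statistic(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """Positive rank sum W+ and the midranks of the non-zero |differences|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 0.0, np.empty(0)
    ranks = sps.rankdata(np.abs(d))
    return float(np.sum(ranks[d > 0])), ranks


def exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p-value of W+ under the signed-rank null.

    Works on midranks (multiples of 1/2): ranks are doubled to integers and
    the distribution of the doubled positive rank sum is built by the usual
    polynomial recursion over the 2^n equiprobable sign assignments.
    """
    r2 = np.rint(2.0 * np.asarray(ranks, dtype=float)).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    cdf = float(counts[: w2 + 1].sum())
    sf = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def _normal_approx_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided normal approximation with continuity and tie corrections."""
    n = ranks.size
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = np.sum(tie_counts**3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    dev = w_plus - mean
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_paired(cohort: PairedCohort) -> ComparisonRow:
    """Two-sided Wilcoxon matched-pair signed-rank comparison of one metric."""
    a, b = cohort.values_a, cohort.values_b
    mean_a, sd_a = summarize(a)
    mean_b, sd_b = summarize(b)
    diffs = a - b
    w_plus, ranks = signed_rank_statistic(diffs)
    n = ranks.size
    if n == 0:
        return ComparisonRow(
            cohort.metric_name, mean_a, sd_a, mean_b, sd_b,
            p_value=1.0, significant=False, n=0,
            method="degenerate", all_zero_differences=True,
        )
    if n <= EXACT_N_MAX:
        p = exact_signed_rank_pvalue(ranks, w_plus)
        method = "exact"
    else:
        p = _normal_approx_pvalue(ranks, w_plus)
        method = "normal"
    return ComparisonRow(
        cohort.metric_name, mean_a, sd_a, mean_b, sd_b,
        p_value=p, significant=p < ALPHA, n=n, method=method,
    )


def plan_metric_table(
    plans: Sequence[Plan], closed_gap_threshold: float = DEFAULT_CLOSED_GAP
) -> dict[str, dict[str, float]]:
    """Per-plan metric values keyed by plan id, for cohort comparison.

    MU is the plan total; SW/SA/LSV/AAV are the plan's pooled per-control-point
    means; MCS is the MU-weighted plan score.
    """
    table: dict[str, dict[str, float]] = {}
    for plan in plans:
        rep = score_plan(plan, closed_gap_threshold)
        table[plan.plan_id] = {
            "MU": rep.mu,
            "SW": rep.segment_means["sw_cm"],
            "SA": rep.segment_means["sa_cm2"],
            "LSV": rep.segment_means["lsv"],
            "AAV": rep.segment_means["aav"],
            "MCS": rep.mcs,
        }
    return table


def _segment_metric_table(
    plans: Sequence[Plan], closed_gap_threshold: float
) -> dict[str, dict[str, np.ndarray]]:
    table: dict[str, dict[str, np.ndarray]] = {}
    for plan in plans:
        rep = score_plan(plan, closed_gap_threshold)
        rows = rep.to_rows()
        table[plan.plan_id] = {
            "MU": np.array([rep.mu]),
            "SW": np.array([r["sw_cm"] for r in rows]),
            "SA": np.array([r["sa_cm2"] for r in rows]),
            "LSV": np.array([r["lsv"] for r in rows]),
            "AAV": np.array([r["aav"] for r in rows]),
            "MCS": np.array([rep.mcs]),
        }
    return table


def adjust_pvalues(rows: Sequence[ComparisonRow], method: str) -> list[ComparisonRow]:
    """Multiple-testing adjustment across a comparison table.

    ``method`` is ``"bonferroni"`` or ``"holm"``; returns new rows with
    adjusted p-values and re-derived significance flags.
    """
    m = len(rows)
    p = np.array([r.p_value for r in rows])
    if method == "bonferroni":
        adj = np.minimum(1.0, p * m)
    elif method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for k, idx in enumerate(order):
            running = max(running, min(1.0, (m - k) * p[idx]))
            adj[idx] = running
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return [
        replace(r, p_value=float(adj[i]), significant=bool(adj[i] < ALPHA))
        for i, r in enumerate(rows)
    ]


def compare_cohorts(
    plans_a: Sequence[Plan],
    plans_b: Sequence[Plan],
    unit: str = "plan",
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
    correction: str | None = None,
) -> list[ComparisonRow]:
    """Paired two-system comparison over {MU, SW, SA, LSV, AAV, MCS}.

    Plans are paired by ``plan_id``.  ``unit="plan"`` compares one value per
    plan; ``unit="segment"`` pairs per-control-point values positionally
    (requires identical arc layouts, as the paired synthetic cohorts provide).
    ``correction`` optionally adjusts the six p-values for multiple testing
    (``"bonferroni"`` or ``"holm"``); per-metric α = 0.05 with no correction
    is the default reporting convention.
    """
    ids_a = [p.plan_id for p in plans_a]
    ids_b = [p.plan_id for p in plans_b]
    unpaired = sorted(set(ids_a) ^ set(ids_b))
    if unpaired:
        raise ValueError(f"unpaired plan ids: {unpaired}")
    order = sorted(ids_a)

    rows: list[ComparisonRow] = []
    if unit == "plan":
        ta = plan_metric_table(plans_a, closed_gap_threshold)
        tb = plan_metric_table(plans_b, closed_gap_threshold)
        for metric in COMPARISON_METRICS:
            rows.append(
                wilcoxon_paired(
                    PairedCohort(
                        metric,
                        np.array([ta[i][metric] for i in order]),
                        np.array([tb[i][metric] for i in order]),
                    )
                )
            )
    elif unit == "segment":
        ta = _segment_metric_table(plans_a, closed_gap_threshold)
        tb = _segment_metric_table(plans_b, closed_gap_threshold)
        for metric in COMPARISON_METRICS:
            va = np.concatenate([ta[i][metric] for i in order])
            vb = np.concatenate([tb[i][metric] for i in order])
            if va.shape != vb.shape:
                raise ValueError(
                    f"segment-unit comparison needs matching layouts for {metric}"
                )
            rows.append(wilcoxon_paired(PairedCohort(metric, va, vb)))
    else:
        raise ValueError(f"unknown comparison unit {unit!r}")
    if correction is not None:
        rows = adjust_pvalues(rows, correction)
    return rows


def rows_to_records(rows: Sequence[ComparisonRow]) -> list[dict]:
    """Flatten comparison rows for CSV/JSON export (Table-style layout)."""
    return [
        {
            "metric": r.metric_name,
            "mean_a": r.mean_a,
            "sd_a": r.sd_a,
            "mean_b": r.mean_b,
            "sd_b": r.sd_b,
            "p_value": r.p_value,
            "significant": r.significant,
            "n": r.n,
            "method": r.method,
            "all_zero_differences": r.all_zero_differences,
        }
        for r in rows
    ]
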
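"""Per-segment and per-arc beam-complexity scores for arc therapy plans.

The modulation complexity score (MCS) decomposes plan modulation into two
dimensionless factors evaluated at each control point and combined with MU
weighting:

* **LSV** (leaf-sequence variability) — how much adjacent leaves within each
  bank differ, normalized by that bank's in-field position range.  A flat bank
  (all leaves aligned) scores 1; a jagged bank scores toward 0.
* **AAV** (aperture-area variability) — the control point's open aperture area
  relative to the arc's maximal per-leaf aperture (per pair: the widest
  left-bank excursion minus the narrowest right-bank excursion seen anywhere
  in the arc).  A static aperture scores 1 everywhere.

``MCS_arc = Σ_i  (LSV_i + LSV_{i+1})/2 · (AAV_i + AAV_{i+1})/2 · w_i``

where ``w_i`` is the fraction of arc MU delivered between control points
``i`` and ``i+1``.  MCS lies in [0, 1]; 1 means no modulation.  Alongside the
MCS the module reports the segment width SW (largest open leaf-pair gap, cm)
and segment area SA (Σ gap × leaf width, cm²).

Leaf pairs count as *in-field* when their gap exceeds a small closed-gap
threshold and their leaf strip overlaps the open y-jaw interval; pairs that
stay closed are ignored throughout, and the y-jaws alone decide field
membership (x-jaws do not clip gaps unless explicitly enabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .rtplan import ArcBeam, ControlPoint, InvalidPlanError, Plan
from .machines import MLCModel

__all__ = [
    "DEFAULT_CLOSED_GAP",
    "SegmentMetrics",
    "ArcComplexity",
    "ComplexityReport",
    "ClosedArcError",
    "infield_pairs",
    "segment_width",
    "segment_area",
    "pos_max",
    "lsv",
    "arc_aperture_extent",
    "aav",
    "segment_weights",
    "combine_scores",
    "mcs_arc",
    "arc_complexity",
    "score_plan",
]

#: Gap (cm) at or below which a leaf pair is treated as closed/parked.
DEFAULT_CLOSED_GAP = 0.05


class ClosedArcError(InvalidPlanError):
    """Every control point of the arc has a fully closed aperture."""


def infield_pairs(
    cp: ControlPoint,
    machine: MLCModel,
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
) -> np.ndarray:
    """Indices of leaf pairs that are open and inside the y-jaw interval.

    A pair qualifies when its gap is strictly greater than
    ``closed_gap_threshold`` and its leaf strip overlaps the open jaw_y
    interval with positive measure.
    """
    b = machine.boundaries
    y1, y2 = cp.jaw_y
    open_enough = cp.gaps > closed_gap_threshold
    overlaps = (b[:-1] < y2) & (b[1:] > y1)
    return np.nonzero(open_enough & overlaps)[0]


def segment_width(
    cp: ControlPoint,
    machine: MLCModel,
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
) -> float:
    """SW: largest in-field leaf-pair opening, cm (0 for a closed aperture)."""
    idx = infield_pairs(cp, machine, closed_gap_threshold)
    if idx.size == 0:
        return 0.0
    return float(np.max(cp.gaps[idx]))


def segment_area(
    cp: ControlPoint,
    machine: MLCModel,
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
) -> float:
    """SA: Σ gap × leaf width over in-field pairs, cm² (closed pairs add 0)."""
    idx = infield_pairs(cp, machine, closed_gap_threshold)
    if idx.size == 0:
        return 0.0
    return float(np.sum(cp.gaps[idx] * machine.widths[idx]))


def pos_max(
    cp: ControlPoint,
    machine: MLCModel,
    bank: str,
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
) -> float:
    """Position range (max − min, cm) of one bank over the in-field pairs."""
    idx = infield_pairs(cp, machine, closed_gap_threshold)
    if idx.size == 0:
        return 0.0
    pos = _bank_positions(cp, bank)[idx]
    return float(np.max(pos) - np.min(pos))


def _bank_positions(cp: ControlPoint, bank: str) -> np.ndarray:
    if bank in ("A", "a", "right"):
        return cp.leaf_pos_a
    if bank in ("B", "b", "left"):
        return cp.leaf_pos_b
    raise ValueError(f"unknown bank {bank!r}")


def _lsv_bank_factor(pos: np.ndarray) -> float:
    """One bank's LSV factor over the in-field positions in physical order.

    Degenerate banks (fewer than two in-field pairs, or zero position range)
    carry no shape variability and score 1 — required so that a rectangular,
    static aperture reaches MCS = 1 exactly.
    """
    n = pos.size
    if n <= 1:
        return 1.0
    pmax = float(np.max(pos) - np.min(pos))
    if pmax == 0.0:
        return 1.0
    diffs = np.abs(np.diff(pos))
    return float(np.sum(pmax - diffs) / ((n - 1) * pmax))


def lsv(
    cp: ControlPoint,
    machine: MLCModel,
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
) -> float:
    """Leaf-sequence variability: product of the two per-bank factors, in [0, 1]."""
    idx = infield_pairs(cp, machine, closed_gap_threshold)
    return _lsv_bank_factor(cp.leaf_pos_b[idx]) * _lsv_bank_factor(cp.leaf_pos_a[idx])


def arc_aperture_extent(
    arc: ArcBeam, closed_gap_threshold: float = DEFAULT_CLOSED_GAP
) -> float:
    """Denominator of AAV: the arc's maximal aperture area, cm².

    Per leaf pair, the extent is (max left-bank position − min right-bank
    position) over the control points where that pair is in-field, times the
    leaf width; pairs never in-field anywhere in the arc contribute 0.
    """
    machine = arc.machine
    n = machine.n_pairs
    max_b = np.full(n, -np.inf)
    min_a = np.full(n, np.inf)
    ever = np.zeros(n, dtype=bool)
    for cp in arc.cps:
        idx = infield_pairs(cp, machine, closed_gap_threshold)
        if idx.size == 0:
            continue
        ever[idx] = True
        max_b[idx] = np.maximum(max_b[idx], cp.leaf_pos_b[idx])
        min_a[idx] = np.minimum(min_a[idx], cp.leaf_pos_a[idx])
    if not np.any(ever):
        raise ClosedArcError(
            f"beam {arc.name}: aperture closed at every control point; "
            "AAV denominator is zero"
        )
    return float(np.sum((max_b[ever] - min_a[ever]) * machine.widths[ever]))


def aav(
    cp: ControlPoint,
    arc: ArcBeam,
    closed_gap_threshold: float = DEFAULT_CLOSED_GAP,
    _extent: float | None = None,
) -> float:
    """Aperture-area variability: SA of this CP over the arc's maximal aperture."""
    extent = (
        arc_aperture_extent(arc, closed_gap_threshold) if _extent is None else _extent
    )
    return segment_area(cp, arc.machine, closed_gap_threshold) / extent


def segment_weights(arc: ArcBeam) -> np.ndarray:
    """MU fractions between consecutive control points (length I − 1, sums to 1)."""
    return np.diff(arc.cum_weights())


def combine_scores(
    lsvs: Sequence[float], aavs: Sequence[float], weights: Sequence[float]
) -> float:
    """MU-weighted combination of per-CP LSV and AAV into the arc MCS.

    ``Σ_i (LSV_i + LSV_{i+1})/2 · (AAV_i + AAV_{i+1})/2 · w_i`` with one more
    control point than weights.  fsum keeps the unmodulated limit exact: all
    factors 1 reduce the sum to Σ w_i = 1.0.
    """
    if len(lsvs) != len(aavs) or len(weights) != len(lsvs) - 1:
        raise ValueError("need I control-point scores and I - 1 weights")
    return math.fsum(
        0.5 * (lsvs[i] + lsvs[i + 1]) * 0.5 * (aavs[i] + aavs[i + 1]) * weights[i]
        for i in range(len(weights))
    )


def mcs_arc(
    arc: ArcBeam, closed_gap_threshold: float = DEFAULT_CLOSED_GAP
) -> float:
    """Modulation complexity score of one arc, in [0, 1] (1 = no modulation)."""
    machine = arc.machine
    extent = arc_aperture_extent(arc, closed_gap_threshold)
    lsvs = [lsv(cp, machine, closed_gap_threshold) for cp in arc.cps]
    aavs = [
        aav(cp, arc, closed_gap_threshold, _extent=extent) for cp in arc.cps
    ]
    return combine_scores(lsvs, aavs, segment_weights(arc))


@dataclass
class SegmentMetrics:
    """Scores evaluated at one control point (weight = MU fraction of the
    span starting here; 0 for the final control point)."""

    index: int
    sw: float
    sa: float
    lsv: float
    aav: float
    weight: float
    n_infield: int
    #: False when the in-field set has interior holes; LSV then differences
    #: consecutive in-field members across the hole.
    contiguous: bool = True


@dataclass
class ArcComplexity:
    """Arc-level aggregate of the per-control-point scores."""

    name: str
    mcs: float
    mean_sw: float
    mean_sa: float
    mean_lsv: float
    mean_aav: float
    mu: float
    segments: list[SegmentMetrics]


@dataclass
class ComplexityReport:
    """Plan-level aggregates: per-arc scores plus pooled and MU-weighted means.

    ``segment_means`` pools per-control-point values across arcs without
    weighting; ``mu_weighted_means`` weights each inter-CP span's endpoint
    average by its MU fraction (and each arc by its MU).  Both are exported
    because cohort summaries can reasonably be defined either way.
    """

    plan_id: str
    arcs: list[ArcComplexity]
    mcs: float
    mu: float
    segment_means: dict[str, float]
    mu_weighted_means: dict[str, float]

    def to_rows(self) -> list[dict]:
        rows = []
        for arc in self.arcs:
            for seg in arc.segments:
                rows.append(
                    {
                        "plan_id": self.plan_id,
                        "arc": arc.name,
                        "cp": seg.index,
                        "sw_cm": seg.sw,
                        "sa_cm2": seg.sa,
                        "lsv": seg.lsv,
                        "aav": seg.aav,
                        "weight": seg.weight,
                        "n_infield": seg.n_infield,
                    }
                )
        return rows

    def to_dict(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "mu": self.mu,
            "mcs": self.mcs,
            "segment_means": dict(self.segment_means),
            "mu_weighted_means": dict(self.mu_weighted_means),
            "arcs": [
                {
                    "name": a.name,
                    "mu": a.mu,
                    "mcs": a.mcs,
                    "mean_sw_cm": a.mean_sw,
                    "mean_sa_cm2": a.mean_sa,
                    "mean_lsv": a.mean_lsv,
                    "mean_aav": a.mean_aav,
                    "segments": [
                        {
                            "cp": s.index,
                            "sw_cm": s.sw,
                            "sa_cm2": s.sa,
                            "lsv": s.lsv,
                            "aav": s.aav,
                            "weight": s.weight,
                            "n_infield": s.n_infield,
                        }
                        for s in a.segments
                    ],
                }
                for a in self.arcs
            ],
        }


def arc_complexity(
    arc: ArcBeam, closed_gap_threshold: float = DEFAULT_CLOSED_GAP
) -> ArcComplexity:
    """Score one arc: per-CP SW/SA/LSV/AAV, MU weights and the arc MCS."""
    machine = arc.machine
    extent = arc_aperture_extent(arc, closed_gap_threshold)
    w = segment_weights(arc)
    segs: list[SegmentMetrics] = []
    for i, cp in enumerate(arc.cps):
        idx = infield_pairs(cp, machine, closed_gap_threshold)
        segs.append(
            SegmentMetrics(
                index=i,
                sw=segment_width(cp, machine, closed_gap_threshold),
                sa=segment_area(cp, machine, closed_gap_threshold),
                lsv=lsv(cp, machine, closed_gap_threshold),
                aav=aav(cp, arc, closed_gap_threshold, _extent=extent),
                weight=float(w[i]) if i < len(w) else 0.0,
                n_infield=int(idx.size),
                contiguous=bool(
                    idx.size <= 1 or idx[-1] - idx[0] == idx.size - 1
                ),
            )
        )
    mcs = combine_scores([s.lsv for s in segs], [s.aav for s in segs], w)
    return ArcComplexity(
        name=arc.name,
        mcs=mcs,
        mean_sw=float(np.mean([s.sw for s in segs])),
        mean_sa=float(np.mean([s.sa for s in segs])),
        mean_lsv=float(np.mean([s.lsv for s in segs])),
        mean_aav=float(np.mean([s.aav for s in segs])),
        mu=arc.beam_mu,
        segments=segs,
    )


def _mu_weighted_mean(arcs: list[ArcComplexity], attr: str) -> float:
    """MU-weighted mean of a per-CP metric: spans weighted by MU fraction
    within each arc, arcs weighted by their MU."""
    num = 0.0
    den = 0.0
    for arc in arcs:
        vals = [getattr(s, attr) for s in arc.segments]
        w = [s.weight for s in arc.segments[:-1]]
        span_mean = math.fsum(
            0.5 * (vals[i] + vals[i + 1]) * w[i] for i in range(len(w))
        )
        num += span_mean * arc.mu
        den += arc.mu
    return num / den


def score_plan(
    plan: Plan, closed_gap_threshold: float = DEFAULT_CLOSED_GAP
) -> ComplexityReport:
    """Score every arc of a plan; plan MCS is the MU-weighted mean of arc MCS."""
    plan.validate()
    arcs = [arc_complexity(a, closed_gap_threshold) for a in plan.arcs]
    total_mu = sum(a.mu for a in arcs)
    plan_mcs = sum(a.mcs * a.mu for a in arcs) / total_mu
    pooled = {
        name: float(
            np.mean([getattr(s, attr) for a in arcs for s in a.segments])
        )
        for name, attr in (("sw_cm", "sw"), ("sa_cm2", "sa"), ("lsv", "lsv"), ("aav", "aav"))
    }
    weighted = {
        name: _mu_weighted_mean(arcs, attr)
        for name, attr in (("sw_cm", "sw"), ("sa_cm2", "sa"), ("lsv", "lsv"), ("aav", "aav"))
    }
    return ComplexityReport(
        plan_id=plan.plan_id,
        arcs=arcs,
        mcs=float(plan_mcs),
        mu=float(total_mu),
        segment_means=pooled,
        mu_weighted_means=weighted,
    )
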
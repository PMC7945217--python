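"""Forward delivery-kinematics model for arc plans.

Per inter-control-point span the linac must simultaneously (a) rotate the
gantry, (b) deliver the span's MU, and (c) move every leaf to its next
position.  With piecewise-constant speeds the span duration is the largest of
the three minimal times:

    dt = max( Δgantry / v_gantry_max,
              ΔMU / DR_max · 60,
              max leaf travel / v_leaf_max )

and the realized gantry speed and dose rate follow from dt.  For binned
dose-rate machines the commanded rate is snapped to the largest bin not above
the continuous solution and dt recomputed, which can only lengthen the span;
when the continuous solution falls below the smallest bin the machine gates
the beam at that smallest bin and dt is unchanged.

This is a plan-side estimator (no acceleration limits, no delivery logs): it
reproduces the speed/dose-rate regimes a plan demands, not the trace a
particular delivery produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rtplan import ArcBeam, Plan, segment_mu

__all__ = [
    "SegmentKinematics",
    "KinematicsError",
    "gantry_deltas",
    "estimate_kinematics",
    "beam_on_time",
    "plan_beam_on_time",
]


class KinematicsError(Exception):
    """A span's duration is undefined (no MU, no gantry motion, no leaf motion)."""


@dataclass
class SegmentKinematics:
    """Estimated delivery state over one inter-control-point span."""

    index: int
    dt: float  # s
    gantry_speed: float  # deg/s
    dose_rate: float  # MU/min (commanded bin for binned machines)
    limiting_factor: str  # {"gantry", "dose_rate", "leaf"}


def gantry_deltas(arc: ArcBeam) -> np.ndarray:
    """Unsigned gantry travel (deg) per span, following the rotation direction."""
    angles = np.array([cp.gantry_angle for cp in arc.cps], dtype=float)
    if arc.rotation == "CW":
        d = np.diff(angles) % 360.0
    else:
        d = (-np.diff(angles)) % 360.0
    return d


def estimate_kinematics(arc: ArcBeam) -> list[SegmentKinematics]:
    """Per-span duration, gantry speed, dose rate and the binding constraint."""
    c = arc.constraints
    dg = gantry_deltas(arc)
    dmu = segment_mu(arc)
    out: list[SegmentKinematics] = []
    for i in range(len(dg)):
        a, b = arc.cps[i], arc.cps[i + 1]
        travel = max(
            float(np.max(np.abs(b.leaf_pos_a - a.leaf_pos_a))),
            float(np.max(np.abs(b.leaf_pos_b - a.leaf_pos_b))),
        )
        dt_parts = {
            "gantry": dg[i] / c.max_gantry_speed,
            "dose_rate": dmu[i] / c.max_dose_rate * 60.0,
            "leaf": travel / c.max_leaf_speed,
        }
        dt = max(dt_parts.values())
        if dt <= 0.0:
            raise KinematicsError(
                f"beam {arc.name}, segment {i}: zero MU and zero motion; "
                "span duration undefined"
            )
        dose_rate = dmu[i] / dt * 60.0
        if c.dose_rate_mode == "binned" and dmu[i] > 0:
            bins = sorted(c.dose_rate_bins, reverse=True)
            below = [v for v in bins if v <= dose_rate + 1e-9]
            commanded = below[0] if below else bins[-1]
            dt_parts["dose_rate"] = dmu[i] / commanded * 60.0
            dt = max(dt_parts.values())
            dose_rate = commanded
        limiting = max(dt_parts, key=dt_parts.get)
        out.append(
            SegmentKinematics(
                index=i,
                dt=float(dt),
                gantry_speed=float(dg[i] / dt),
                dose_rate=float(dose_rate),
                limiting_factor=limiting,
            )
        )
    return out


def beam_on_time(arc: ArcBeam) -> float:
    """Total arc delivery time, s (sum of span durations)."""
    return float(sum(k.dt for k in estimate_kinematics(arc)))


def plan_beam_on_time(plan: Plan) -> float:
    """Total beam-on time across all arcs, s (inter-arc idle time excluded)."""
    return float(sum(beam_on_time(a) for a in plan.arcs))
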
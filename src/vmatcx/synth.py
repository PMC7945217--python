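"""Synthetic arc-plan generation with controlled modulation.

Real arc plans cannot be redistributed, so every stage of the package is
exercised on generated plans whose modulation is a single dial.  Each control
point's aperture is conformed to a projected ellipse (per leaf pair, the gap
is the ellipse chord at the pair's y-midpoint; pairs whose strip misses the
ellipse stay closed), then independent zero-mean Gaussian perturbations of a
chosen standard deviation (``modulation_amplitude``, cm) are added to every
open leaf, clipped to the machine's overtravel and travel limits.  Amplitude 0
with a rectangular aperture reproduces the unmodulated limit (MCS = 1);
growing amplitude drives LSV and AAV — and hence the MCS — down.

Arc layouts mirror common clinical geometries: ``full_dual`` is two full
rotations (181°→179° CW, then back CCW) at 2° control-point spacing, as used
for head-and-neck targets; ``partial_dual`` is two 40° partial arcs
(296°→336° and 104°→144°, CW) typical of tangential breast treatments.

All randomness flows through one explicitly threaded seeded generator; plans
are byte-identical across runs for the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .machines import MachineConstraints, MLCModel, default_constraints
from .rtplan import ArcBeam, ControlPoint, Plan

__all__ = [
    "GeneratorConfig",
    "generate_plan",
    "unmodulated_fixture",
    "paired_cohort_fixture",
    "random_arc",
]

_LAYOUTS = ("full_dual", "partial_dual")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator (defaults mirror the modeled study
    geometry: 2° spacing, dual full arcs, plan-level MU typical of a
    head-and-neck arc plan)."""

    machine: MLCModel
    constraints: MachineConstraints | None = None
    arc_layout: str = "full_dual"
    n_cp_per_arc: int | None = None  # None -> derived from layout and spacing
    gantry_spacing: float = 2.0  # deg
    ellipse_a: float = 4.0  # semi-axis along leaf travel, cm
    ellipse_b: float = 4.0  # semi-axis across leaves, cm
    center_x: float = 0.0
    center_y: float = 0.0
    aperture: str = "ellipse"  # {"ellipse", "rect"}
    modulation_amplitude: float = 0.0  # SD of leaf perturbation, cm
    mu_total: float = 800.0
    mu_profile: str = "uniform"  # {"uniform", "random-dirichlet"}
    seed: int = 0
    plan_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.arc_layout not in _LAYOUTS:
            raise ValueError(f"arc_layout must be one of {_LAYOUTS}")
        if self.modulation_amplitude < 0:
            raise ValueError("modulation_amplitude must be >= 0")
        if self.gantry_spacing <= 0:
            raise ValueError("gantry_spacing must be positive")
        if self.n_cp_per_arc is not None and self.n_cp_per_arc < 2:
            raise ValueError("n_cp_per_arc must be >= 2")
        if self.mu_total <= 0:
            raise ValueError("mu_total must be positive")
        if self.ellipse_a <= 0 or self.ellipse_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


def _arc_angle_tracks(cfg: GeneratorConfig) -> list[tuple[np.ndarray, str]]:
    """Gantry-angle sequences (deg, already wrapped) and rotation senses."""
    sp = cfg.gantry_spacing
    if cfg.arc_layout == "full_dual":
        # 181 -> 179 CW through 0, then 179 -> 181 CCW
        span = 358.0
        n = cfg.n_cp_per_arc or int(round(span / sp)) + 1
        cw = (181.0 + np.linspace(0.0, span, n)) % 360.0
        ccw = (179.0 - np.linspace(0.0, span, n)) % 360.0
        return [(cw, "CW"), (ccw, "CCW")]
    # partial_dual: two 40-degree CW arcs
    span = 40.0
    n = cfg.n_cp_per_arc or int(round(span / sp)) + 1
    a1 = (296.0 + np.linspace(0.0, span, n)) % 360.0
    a2 = (104.0 + np.linspace(0.0, span, n)) % 360.0
    return [(a1, "CW"), (a2, "CW")]


def _aperture_template(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair (bank_a, bank_b, open_mask) of the unperturbed aperture."""
    m = cfg.machine
    centers = m.leaf_centers
    a_pos = np.zeros(m.n_pairs)
    b_pos = np.zeros(m.n_pairs)
    if cfg.aperture == "rect":
        y1, y2 = cfg.center_y - cfg.ellipse_b, cfg.center_y + cfg.ellipse_b
        open_mask = (centers > y1) & (centers < y2)
        a_pos[open_mask] = cfg.center_x - cfg.ellipse_a
        b_pos[open_mask] = cfg.center_x + cfg.ellipse_a
        return a_pos, b_pos, open_mask
    dy = (centers - cfg.center_y) / cfg.ellipse_b
    open_mask = np.abs(dy) < 1.0
    half = np.zeros(m.n_pairs)
    half[open_mask] = cfg.ellipse_a * np.sqrt(1.0 - dy[open_mask] ** 2)
    a_pos[open_mask] = cfg.center_x - half[open_mask]
    b_pos[open_mask] = cfg.center_x + half[open_mask]
    return a_pos, b_pos, open_mask


def _check_fits(cfg: GeneratorConfig) -> None:
    m = cfg.machine
    if cfg.center_y - cfg.ellipse_b < m.boundaries[0] or (
        cfg.center_y + cfg.ellipse_b > m.boundaries[-1]
    ):
        raise ValueError("target extends beyond the MLC leaf bank")
    if cfg.ellipse_a + abs(cfg.center_x) > m.max_leaf_position:
        raise ValueError("target extends beyond the leaf travel range")


def _cum_weights(cfg: GeneratorConfig, n_cp: int, rng: np.random.Generator) -> np.ndarray:
    if cfg.mu_profile == "uniform":
        return np.linspace(0.0, 1.0, n_cp)
    if cfg.mu_profile == "random-dirichlet":
        w = rng.dirichlet(np.ones(n_cp - 1))
        cum = np.concatenate([[0.0], np.cumsum(w)])
        cum[-1] = 1.0
        return cum
    raise ValueError(f"unknown mu_profile {cfg.mu_profile!r}")


def generate_plan(cfg: GeneratorConfig) -> Plan:
    """Generate a deterministic synthetic plan from a configuration."""
    _check_fits(cfg)
    m = cfg.machine
    constraints = cfg.constraints or default_constraints(
        "binned-type" if m.name == "elekta_mlci" else "continuous-type"
    )
    rng = np.random.default_rng(cfg.seed)
    a0, b0, open_mask = _aperture_template(cfg)

    tracks = _arc_angle_tracks(cfg)
    mu_per_arc = cfg.mu_total / len(tracks)
    jaw_y = (cfg.center_y - cfg.ellipse_b, cfg.center_y + cfg.ellipse_b)
    jaw_x = (
        max(cfg.center_x - cfg.ellipse_a, -m.max_leaf_position),
        min(cfg.center_x + cfg.ellipse_a, m.max_leaf_position),
    )

    arcs = []
    for k, (angles, rotation) in enumerate(tracks):
        n_cp = angles.size
        cum = _cum_weights(cfg, n_cp, rng)
        cps = []
        for i in range(n_cp):
            a = a0.copy()
            b = b0.copy()
            if cfg.modulation_amplitude > 0 and open_mask.any():
                n_open = int(open_mask.sum())
                a[open_mask] += rng.normal(0.0, cfg.modulation_amplitude, n_open)
                b[open_mask] += rng.normal(0.0, cfg.modulation_amplitude, n_open)
                a = np.clip(a, -m.max_leaf_position, m.overtravel)
                b = np.clip(b, -m.overtravel, m.max_leaf_position)
                crossed = open_mask & (b - a < m.min_gap)
                mid = 0.5 * (a[crossed] + b[crossed])
                a[crossed] = mid
                b[crossed] = mid
            cps.append(
                ControlPoint(
                    index=i,
                    gantry_angle=float(angles[i]),
                    leaf_pos_a=a,
                    leaf_pos_b=b,
                    jaw_x=jaw_x,
                    jaw_y=jaw_y,
                    cum_weight=float(cum[i]),
                )
            )
        arcs.append(
            ArcBeam(
                machine=m,
                constraints=constraints,
                cps=cps,
                beam_mu=mu_per_arc,
                rotation=rotation,
                collimator_angle=15.0 if k == 0 else 345.0,
                name=f"arc{k + 1}",
            )
        )
    plan = Plan(plan_id=cfg.plan_id, arcs=arcs, meta={"generator": "vmatcx.synth"})
    plan.validate()
    return plan


def unmodulated_fixture(machine: MLCModel) -> Plan:
    """One full arc with a constant rectangular 10 × 10 cm aperture and
    uniform MU weighting — the MCS = 1 reference case."""
    cfg = GeneratorConfig(
        machine=machine,
        arc_layout="full_dual",
        aperture="rect",
        ellipse_a=5.0,
        ellipse_b=5.0,
        modulation_amplitude=0.0,
        mu_total=800.0,
        plan_id=f"unmodulated-{machine.name}",
    )
    plan = generate_plan(cfg)
    plan.arcs = plan.arcs[:1]  # a single arc suffices for the reference case
    plan.arcs[0].beam_mu = cfg.mu_total
    return plan


def random_arc(
    machine: MLCModel,
    seed: int,
    amplitude: float | None = None,
    layout: str = "partial_dual",
):
    """One randomized arc: random ellipse target, amplitude ~ U(0, 1) cm unless
    given, Dirichlet MU profile.  Used for property checks and range scans."""
    rng = np.random.default_rng(seed)
    if amplitude is None:
        amplitude = float(rng.uniform(0.0, 1.0))
    cfg = GeneratorConfig(
        machine=machine,
        arc_layout=layout,
        ellipse_a=float(rng.uniform(1.5, 6.0)),
        ellipse_b=float(rng.uniform(1.5, 6.0)),
        center_x=float(rng.uniform(-2.0, 2.0)),
        center_y=float(rng.uniform(-2.0, 2.0)),
        modulation_amplitude=amplitude,
        mu_total=float(rng.uniform(300.0, 900.0)),
        mu_profile="random-dirichlet",
        seed=int(rng.integers(0, 2**31 - 1)),
        plan_id=f"random-{machine.name}-{seed}",
    )
    return generate_plan(cfg).arcs[0]


def paired_cohort_fixture(
    n_plans: int,
    machine_a: MLCModel,
    machine_b: MLCModel,
    seed: int = 0,
    arc_layout: str = "full_dual",
    amplitude_a: float | None = None,
    amplitude_b: float | None = None,
) -> tuple[list[Plan], list[Plan]]:
    """Matched cohorts: plan *i* shares target shape, MU and layout in both
    lists but is realized on each machine's leaf grid (same-patient,
    two-machine pairing).  Optional per-system amplitudes let tests dial in a
    complexity contrast; by default both systems share the drawn amplitude."""
    if n_plans < 2:
        raise ValueError("need at least 2 plans for a paired cohort")
    rng = np.random.default_rng(seed)
    plans_a: list[Plan] = []
    plans_b: list[Plan] = []
    for i in range(n_plans):
        shape = dict(
            ellipse_a=float(rng.uniform(2.0, 5.5)),
            ellipse_b=float(rng.uniform(2.0, 5.5)),
            center_x=float(rng.uniform(-1.5, 1.5)),
            center_y=float(rng.uniform(-1.5, 1.5)),
            mu_total=float(rng.uniform(350.0, 900.0)),
        )
        amp = float(rng.uniform(0.1, 0.6))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pid = f"plan-{i:03d}"
        for machine, plans, amp_k in (
            (machine_a, plans_a, amplitude_a),
            (machine_b, plans_b, amplitude_b),
        ):
            cfg = GeneratorConfig(
                machine=machine,
                arc_layout=arc_layout,
                modulation_amplitude=amp if amp_k is None else amp_k,
                mu_profile="random-dirichlet",
                seed=sub_seed,
                plan_id=pid,
                **shape,
            )
            plans.append(generate_plan(cfg))
    return plans_a, plans_b
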
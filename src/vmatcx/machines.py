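"""Delivery-system geometry and constraint models.

Two MLC geometries are built in, matching the systems typically compared in
two-linac VMAT studies: a 120-leaf Millennium-style MLC (60 opposed pairs,
10/5/10 mm leaf-width pattern projected to isocenter) driven with a
continuously variable dose rate, and a 40-pair MLCi-style MLC (uniform 10 mm
leaves) driven with binned dose rates.

All geometry is expressed in cm at the isocenter plane; DICOM millimetre
values are converted at the I/O boundary.  Machine maxima (gantry speed, dose
rate, leaf speed) are configuration assumptions, not vendor claims — they ship
in an editable YAML template (``vmatcx/data/machines.yaml``) and can be
overridden without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "MLCModel",
    "MachineConstraints",
    "millennium120",
    "elekta_mlci",
    "default_constraints",
    "boundaries_from_widths",
    "load_machines",
    "save_machines",
    "default_registry",
]

_BOUNDARY_TOL = 1e-9


def boundaries_from_widths(widths: Sequence[float]) -> np.ndarray:
    """Leaf-pair edge coordinates (cm) for a bank symmetric about the axis."""
    w = np.asarray(widths, dtype=float)
    if w.ndim != 1 or w.size == 0 or np.any(w <= 0):
        raise ValueError("leaf widths must be a non-empty 1-D positive array")
    edges = np.concatenate([[0.0], np.cumsum(w)])
    return edges - edges[-1] / 2.0


@dataclass(frozen=True)
class MLCModel:
    """Static multileaf-collimator geometry at the isocenter plane.

    Parameters
    ----------
    name : str
        Identifier used for registry matching and reporting.
    n_pairs : int
        Number of opposed leaf pairs.
    leaf_widths : tuple of float
        Per-pair projected widths, cm, ordered along the leaf-travel-orthogonal
        (y) axis.
    leaf_boundaries : tuple of float
        ``n_pairs + 1`` strictly increasing pair-edge y coordinates, cm.
    overtravel : float
        Maximum distance a leaf tip may cross the central axis, cm.
    min_gap : float
        Minimum allowed leaf-pair opening, cm (0 = leaves may abut).
    """

    name: str
    n_pairs: int
    leaf_widths: tuple[float, ...]
    leaf_boundaries: tuple[float, ...]
    overtravel: float
    min_gap: float = 0.0
    max_leaf_position: float = 20.0  # retraction limit on the travel axis, cm

    def __post_init__(self) -> None:
        w = np.asarray(self.leaf_widths, dtype=float)
        b = np.asarray(self.leaf_boundaries, dtype=float)
        if len(w) != self.n_pairs:
            raise ValueError("leaf_widths length must equal n_pairs")
        if len(b) != self.n_pairs + 1:
            raise ValueError("leaf_boundaries must have n_pairs + 1 entries")
        if np.any(w <= 0):
            raise ValueError("all leaf widths must be positive")
        if np.any(np.diff(b) <= 0):
            raise ValueError("leaf boundaries must be strictly increasing")
        if not np.allclose(np.diff(b), w, rtol=0, atol=_BOUNDARY_TOL):
            raise ValueError("boundary differences must equal leaf widths")
        if self.overtravel < 0:
            raise ValueError("overtravel must be non-negative")

    @property
    def widths(self) -> np.ndarray:
        return np.asarray(self.leaf_widths, dtype=float)

    @property
    def boundaries(self) -> np.ndarray:
        return np.asarray(self.leaf_boundaries, dtype=float)

    @property
    def leaf_centers(self) -> np.ndarray:
        b = self.boundaries
        return 0.5 * (b[:-1] + b[1:])

    def matches_boundaries(self, boundaries: Iterable[float], atol: float = 1e-3) -> bool:
        b = np.asarray(list(boundaries), dtype=float)
        return b.size == self.n_pairs + 1 and bool(
            np.allclose(b, self.boundaries, rtol=0, atol=atol)
        )


@dataclass(frozen=True)
class MachineConstraints:
    """Delivery limits used by the kinematic estimator.

    ``dose_rate_mode`` is ``"continuous"`` for linacs that vary the dose rate
    freely and ``"binned"`` for linacs restricted to a discrete ladder of
    dose-rate levels (``dose_rate_bins``, MU/min, descending).
    """

    max_gantry_speed: float  # deg/s
    max_dose_rate: float  # MU/min
    dose_rate_mode: str = "continuous"
    dose_rate_bins: tuple[float, ...] | None = None
    max_leaf_speed: float = 2.5  # cm/s

    def __post_init__(self) -> None:
        if self.max_gantry_speed <= 0 or self.max_dose_rate <= 0 or self.max_leaf_speed <= 0:
            raise ValueError("machine maxima must be positive")
        if self.dose_rate_mode not in ("continuous", "binned"):
            raise ValueError(f"unknown dose_rate_mode {self.dose_rate_mode!r}")
        if self.dose_rate_mode == "binned":
            if not self.dose_rate_bins:
                raise ValueError("binned mode requires a non-empty dose_rate_bins list")
            bins = np.asarray(self.dose_rate_bins, dtype=float)
            if np.any(bins <= 0) or np.any(bins > self.max_dose_rate + 1e-9):
                raise ValueError("dose-rate bins must be positive and <= max_dose_rate")


def millennium120() -> MLCModel:
    """60-pair MLC: outer 10+10 pairs of 1.0 cm, inner 40 pairs of 0.5 cm."""
    widths = (1.0,) * 10 + (0.5,) * 40 + (1.0,) * 10
    return MLCModel(
        name="millennium120",
        n_pairs=60,
        leaf_widths=widths,
        leaf_boundaries=tuple(boundaries_from_widths(widths)),
        overtravel=15.0,
    )


def elekta_mlci() -> MLCModel:
    """40-pair MLC with uniform 1.0 cm projected leaf width."""
    widths = (1.0,) * 40
    return MLCModel(
        name="elekta_mlci",
        n_pairs=40,
        leaf_widths=widths,
        leaf_boundaries=tuple(boundaries_from_widths(widths)),
        overtravel=12.5,
    )


#: Assumed delivery limits; the study machines' true maxima are not published
#: with the geometry, so these are editable configuration, not measurements.
_DEFAULT_CONSTRAINTS: dict[str, MachineConstraints] = {
    "continuous-type": MachineConstraints(
        max_gantry_speed=4.8,
        max_dose_rate=600.0,
        dose_rate_mode="continuous",
        max_leaf_speed=2.5,
    ),
    "binned-type": MachineConstraints(
        max_gantry_speed=6.0,
        max_dose_rate=600.0,
        dose_rate_mode="binned",
        # geometric ladder, each bin half the previous
        dose_rate_bins=(600.0, 300.0, 150.0, 75.0, 37.5, 18.75),
        max_leaf_speed=2.0,
    ),
}


def default_constraints(system_label: str) -> MachineConstraints:
    """Constraint set for ``"continuous-type"`` or ``"binned-type"`` systems."""
    try:
        return _DEFAULT_CONSTRAINTS[system_label]
    except KeyError:
        raise ValueError(
            f"unknown system label {system_label!r}; "
            f"expected one of {sorted(_DEFAULT_CONSTRAINTS)}"
        ) from None


def default_registry() -> tuple[MLCModel, ...]:
    """Built-in machine models, used for auto-detection when reading plans."""
    return (millennium120(), elekta_mlci())


# ---------------------------------------------------------------------------
# plain-text (YAML) machine templates


def _machine_to_dict(machine: MLCModel, constraints: MachineConstraints | None) -> dict:
    d = {
        "name": machine.name,
        "n_pairs": machine.n_pairs,
        "leaf_widths": [float(w) for w in machine.leaf_widths],
        "overtravel": float(machine.overtravel),
        "min_gap": float(machine.min_gap),
    }
    if constraints is not None:
        d["constraints"] = {
            "max_gantry_speed": constraints.max_gantry_speed,
            "max_dose_rate": constraints.max_dose_rate,
            "dose_rate_mode": constraints.dose_rate_mode,
            "dose_rate_bins": (
                list(constraints.dose_rate_bins) if constraints.dose_rate_bins else None
            ),
            "max_leaf_speed": constraints.max_leaf_speed,
        }
    return d


def _machine_from_dict(d: dict) -> tuple[MLCModel, MachineConstraints | None]:
    widths = tuple(float(w) for w in d["leaf_widths"])
    machine = MLCModel(
        name=str(d["name"]),
        n_pairs=int(d.get("n_pairs", len(widths))),
        leaf_widths=widths,
        leaf_boundaries=tuple(boundaries_from_widths(widths)),
        overtravel=float(d["overtravel"]),
        min_gap=float(d.get("min_gap", 0.0)),
    )
    constraints = None
    if "constraints" in d and d["constraints"] is not None:
        c = d["constraints"]
        bins = c.get("dose_rate_bins")
        constraints = MachineConstraints(
            max_gantry_speed=float(c["max_gantry_speed"]),
            max_dose_rate=float(c["max_dose_rate"]),
            dose_rate_mode=str(c.get("dose_rate_mode", "continuous")),
            dose_rate_bins=tuple(float(b) for b in bins) if bins else None,
            max_leaf_speed=float(c.get("max_leaf_speed", 2.5)),
        )
    return machine, constraints


def save_machines(
    entries: Sequence[tuple[MLCModel, MachineConstraints | None]], path
) -> None:
    """Write machine templates to a YAML file users can edit by hand."""
    payload = {"machines": [_machine_to_dict(m, c) for m, c in entries]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_machines(path=None) -> list[tuple[MLCModel, MachineConstraints | None]]:
    """Load machine templates from YAML; defaults to the packaged template."""
    if path is None:
        text = (
            resources.files("vmatcx").joinpath("data/machines.yaml").read_text()
        )
        payload = yaml.safe_load(text)
    else:
        with open(path) as fh:
            payload = yaml.safe_load(fh)
    return [_machine_from_dict(d) for d in payload["machines"]]
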
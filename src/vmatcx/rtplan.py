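"""DICOM RT Plan reading/writing and the neutral in-memory arc model.

The complexity and kinematics layers never touch DICOM directly: they operate
on :class:`Plan` / :class:`ArcBeam` / :class:`ControlPoint`, where every length
is cm at the isocenter plane and leaf banks follow a fixed sign convention —
bank B ("left bank", the higher-coordinate bank) minus bank A ("right bank")
is the non-negative leaf-pair gap.

DICOM files store leaf and jaw positions in mm and do not fix which physical
bank comes first in ``LeafJawPositions``; the reader resolves the bank order
per file by choosing the assignment that makes the gap non-negative for the
majority of pairs, and records that decision in ``Plan.meta``.  Jaw and MLC
positions absent at a control point inherit from the previous one, per DICOM
control-point semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .machines import (
    MachineConstraints,
    MLCModel,
    default_constraints,
    default_registry,
)

__all__ = [
    "ControlPoint",
    "ArcBeam",
    "Plan",
    "RTPlanError",
    "MissingMLCError",
    "NonMonotoneWeightError",
    "UnmatchedMachineError",
    "InvalidPlanError",
    "read_rtplan",
    "write_rtplan",
    "segment_mu",
]

RTPLAN_SOP_CLASS_UID = "1.2.840.10008.5.1.4.1.1.481.5"

_WEIGHT_TOL = 1e-6
_GAP_TOL = 1e-4  # cm; tiny negative gaps from mm rounding are clamped


class RTPlanError(Exception):
    """Base class for RT Plan parsing/validation errors."""


class MissingMLCError(RTPlanError):
    """A beam lacks an MLC device or MLC positions at its control points."""


class NonMonotoneWeightError(RTPlanError):
    """Cumulative meterset weights decrease along a beam."""


class UnmatchedMachineError(RTPlanError):
    """No registered MLC model matches the file's leaf-boundary table."""


class InvalidPlanError(RTPlanError):
    """An in-memory plan violates its invariants."""


@dataclass
class ControlPoint:
    """One instantaneous machine state along an arc.

    ``leaf_pos_a`` is the right (lower-coordinate) bank, ``leaf_pos_b`` the
    left bank; the per-pair aperture gap is ``leaf_pos_b - leaf_pos_a >= 0``.
    All positions in cm at isocenter, gantry angle in degrees in [0, 360).
    """

    index: int
    gantry_angle: float
    leaf_pos_a: np.ndarray
    leaf_pos_b: np.ndarray
    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]
    cum_weight: float

    def __post_init__(self) -> None:
        self.leaf_pos_a = np.asarray(self.leaf_pos_a, dtype=float)
        self.leaf_pos_b = np.asarray(self.leaf_pos_b, dtype=float)

    @property
    def gaps(self) -> np.ndarray:
        return self.leaf_pos_b - self.leaf_pos_a

    def validate(self, machine: MLCModel) -> None:
        if self.leaf_pos_a.shape != (machine.n_pairs,) or self.leaf_pos_b.shape != (
            machine.n_pairs,
        ):
            raise InvalidPlanError(
                f"CP {self.index}: leaf arrays must have length {machine.n_pairs}"
            )
        if np.any(self.gaps < -_GAP_TOL):
            raise InvalidPlanError(f"CP {self.index}: negative leaf-pair gap")
        if not (self.jaw_x[0] < self.jaw_x[1] and self.jaw_y[0] < self.jaw_y[1]):
            raise InvalidPlanError(f"CP {self.index}: jaw intervals must be non-empty")
        if not -_WEIGHT_TOL <= self.cum_weight <= 1 + _WEIGHT_TOL:
            raise InvalidPlanError(f"CP {self.index}: cum_weight outside [0, 1]")


@dataclass
class ArcBeam:
    """An ordered control-point sequence with its total monitor units."""

    machine: MLCModel
    constraints: MachineConstraints
    cps: list[ControlPoint]
    beam_mu: float
    rotation: str = "CW"
    collimator_angle: float = 0.0
    name: str = "arc"

    def validate(self) -> None:
        if len(self.cps) < 2:
            raise InvalidPlanError(f"beam {self.name}: needs >= 2 control points")
        if self.beam_mu <= 0:
            raise InvalidPlanError(f"beam {self.name}: beam_mu must be positive")
        if self.rotation not in ("CW", "CCW"):
            raise InvalidPlanError(f"beam {self.name}: rotation must be CW or CCW")
        w = np.array([cp.cum_weight for cp in self.cps])
        if np.any(np.diff(w) < -_WEIGHT_TOL):
            raise NonMonotoneWeightError(
                f"beam {self.name}: cumulative weights decrease"
            )
        if abs(w[0]) > _WEIGHT_TOL or abs(w[-1] - 1.0) > _WEIGHT_TOL:
            raise InvalidPlanError(
                f"beam {self.name}: cumulative weights must run from 0 to 1"
            )
        for cp in self.cps:
            cp.validate(self.machine)

    @property
    def n_cp(self) -> int:
        return len(self.cps)

    def cum_weights(self) -> np.ndarray:
        return np.array([cp.cum_weight for cp in self.cps], dtype=float)


@dataclass
class Plan:
    """A treatment plan: one or more arc beams plus parse/provenance metadata."""

    plan_id: str
    arcs: list[ArcBeam]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.arcs:
            raise InvalidPlanError("plan must contain at least one arc")
        for arc in self.arcs:
            arc.validate()

    @property
    def total_mu(self) -> float:
        return float(sum(a.beam_mu for a in self.arcs))


def segment_mu(arc: ArcBeam) -> np.ndarray:
    """MU delivered in each of the ``I - 1`` spans between control points."""
    return np.diff(arc.cum_weights()) * arc.beam_mu


# ---------------------------------------------------------------------------
# writing


def _jaw_item(device: str, lo_cm: float, hi_cm: float) -> Dataset:
    item = Dataset()
    item.RTBeamLimitingDeviceType = device
    item.LeafJawPositions = [f"{lo_cm * 10.0:.6f}", f"{hi_cm * 10.0:.6f}"]
    return item


def write_rtplan(plan: Plan, path) -> None:
    """Serialize a validated plan as a DICOM RT Plan file."""
    plan.validate()

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS_UID
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS_UID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id[:16]  # SH VR caps at 16 chars
    ds.RTPlanName = plan.plan_id
    ds.RTPlanGeometry = "TREATMENT_DEVICE"
    ds.PatientName = "vmatcx^synthetic"
    ds.PatientID = plan.plan_id

    beams = []
    refs = []
    for k, arc in enumerate(plan.arcs, start=1):
        machine = arc.machine
        beam = Dataset()
        beam.BeamNumber = k
        beam.BeamName = arc.name
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        beam.TreatmentMachineName = machine.name[:16]
        beam.PrimaryDosimeterUnit = "MU"
        beam.NumberOfControlPoints = arc.n_cp
        beam.FinalCumulativeMetersetWeight = 1.0

        mlc_dev = Dataset()
        mlc_dev.RTBeamLimitingDeviceType = "MLCX"
        mlc_dev.NumberOfLeafJawPairs = machine.n_pairs
        mlc_dev.LeafPositionBoundaries = [
            f"{b * 10.0:.6f}" for b in machine.leaf_boundaries
        ]
        beam.BeamLimitingDeviceSequence = []
        for dev in ("ASYMX", "ASYMY"):
            d = Dataset()
            d.RTBeamLimitingDeviceType = dev
            d.NumberOfLeafJawPairs = 1
            beam.BeamLimitingDeviceSequence.append(d)
        beam.BeamLimitingDeviceSequence.append(mlc_dev)

        jaws_constant = all(
            cp.jaw_x == arc.cps[0].jaw_x and cp.jaw_y == arc.cps[0].jaw_y
            for cp in arc.cps
        )
        cp_items = []
        for i, cp in enumerate(arc.cps):
            item = Dataset()
            item.ControlPointIndex = i
            item.GantryAngle = float(cp.gantry_angle % 360.0)
            item.GantryRotationDirection = "CW" if arc.rotation == "CW" else "CC"
            item.CumulativeMetersetWeight = float(cp.cum_weight)
            pos_seq = []
            # common planning-system dialect: jaws only at CP 0 when static
            if i == 0 or not jaws_constant:
                pos_seq.append(_jaw_item("ASYMX", *cp.jaw_x))
                pos_seq.append(_jaw_item("ASYMY", *cp.jaw_y))
            mlc = Dataset()
            mlc.RTBeamLimitingDeviceType = "MLCX"
            mlc.LeafJawPositions = [
                f"{p * 10.0:.6f}"
                for p in np.concatenate([cp.leaf_pos_a, cp.leaf_pos_b])
            ]
            pos_seq.append(mlc)
            item.BeamLimitingDevicePositionSequence = pos_seq
            if i == 0:
                item.BeamLimitingDeviceAngle = float(arc.collimator_angle % 360.0)
                item.NominalBeamEnergy = 6.0
            cp_items.append(item)
        beam.ControlPointSequence = cp_items
        beams.append(beam)

        ref = Dataset()
        ref.ReferencedBeamNumber = k
        ref.BeamMeterset = float(arc.beam_mu)
        refs.append(ref)

    ds.BeamSequence = beams
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 25
    fg.NumberOfBeams = len(beams)
    fg.ReferencedBeamSequence = refs
    ds.FractionGroupSequence = [fg]

    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# reading


def _resolve_banks(
    raw: np.ndarray, n_pairs: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Split stacked (I, 2N) leaf positions into (A, B) with B - A >= 0.

    Returns (bank_a, bank_b, swapped): ``swapped`` is True when the second
    half of ``LeafJawPositions`` turned out to be the lower-coordinate bank.
    """
    first, second = raw[:, :n_pairs], raw[:, n_pairs:]
    diff = second - first
    moving = np.abs(diff) > _GAP_TOL  # closed pairs carry no sign information
    if not moving.any():
        return first, second, False
    frac_nonneg = float(np.mean(diff[moving] >= 0))
    if frac_nonneg >= 0.5:
        return first, second, False
    return second, first, True


def read_rtplan(
    path,
    machine_registry: Sequence[MLCModel] | None = None,
    mu_overrides: Mapping[str, float] | None = None,
    constraints_map: Mapping[str, MachineConstraints] | None = None,
) -> Plan:
    """Parse a DICOM RT Plan into the neutral arc model (units: cm, MU).

    Static beams (single control point, or zero/absent meterset) are skipped.
    ``mu_overrides`` maps beam name to MU for files whose fraction-group
    metersets are missing (sidecar fallback).  The MLC model is auto-detected
    by matching the file's leaf-boundary table against ``machine_registry``.
    """
    registry = tuple(machine_registry) if machine_registry else default_registry()
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTPLAN" or "BeamSequence" not in ds:
        raise RTPlanError(f"{path}: not an RT Plan with beams")

    metersets: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(ref, "BeamMeterset"):
                metersets[int(ref.ReferencedBeamNumber)] = float(ref.BeamMeterset)

    meta: dict = {"source": str(path), "beams": {}}
    plan_arcs: list[ArcBeam] = []
    for beam in ds.BeamSequence:
        name = str(getattr(beam, "BeamName", f"beam{beam.BeamNumber}"))
        if getattr(beam, "TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
            continue
        n_cp = int(getattr(beam, "NumberOfControlPoints", len(beam.ControlPointSequence)))
        if n_cp < 2:
            continue
        beam_mu = metersets.get(int(beam.BeamNumber))
        if mu_overrides and name in mu_overrides:
            beam_mu = float(mu_overrides[name])
        if not beam_mu:
            continue  # zero/absent meterset -> not a treatment arc

        mlc_dev = None
        for dev in getattr(beam, "BeamLimitingDeviceSequence", []):
            if dev.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                mlc_dev = dev
        if mlc_dev is None:
            raise MissingMLCError(f"beam {name}: no MLC device in limiting-device sequence")
        boundaries_cm = np.asarray(
            [float(b) for b in mlc_dev.LeafPositionBoundaries], dtype=float
        ) / 10.0
        machine = next(
            (m for m in registry if m.matches_boundaries(boundaries_cm)), None
        )
        if machine is None:
            raise UnmatchedMachineError(
                f"beam {name}: leaf-boundary table ({len(boundaries_cm)} edges) "
                "matches no registered MLC model"
            )

        gantry = 0.0
        rotation = "CW"
        collimator = 0.0
        jaw_x: tuple[float, float] | None = None
        jaw_y: tuple[float, float] | None = None
        mlc_raw: np.ndarray | None = None
        rows, angles, weights, jx_list, jy_list = [], [], [], [], []
        for item in beam.ControlPointSequence:
            if hasattr(item, "GantryAngle"):
                gantry = float(item.GantryAngle)
            if hasattr(item, "GantryRotationDirection"):
                rotation = "CCW" if str(item.GantryRotationDirection) == "CC" else "CW"
            if hasattr(item, "BeamLimitingDeviceAngle"):
                collimator = float(item.BeamLimitingDeviceAngle)
            for dev in getattr(item, "BeamLimitingDevicePositionSequence", []):
                kind = dev.RTBeamLimitingDeviceType
                vals = np.asarray([float(v) for v in dev.LeafJawPositions]) / 10.0
                if kind in ("X", "ASYMX"):
                    jaw_x = (float(vals[0]), float(vals[1]))
                elif kind in ("Y", "ASYMY"):
                    jaw_y = (float(vals[0]), float(vals[1]))
                elif kind in ("MLCX", "MLCY"):
                    mlc_raw = vals
            if mlc_raw is None:
                raise MissingMLCError(
                    f"beam {name}: control point {len(rows)} has no MLC positions"
                )
            if jaw_x is None or jaw_y is None:
                raise RTPlanError(f"beam {name}: jaw positions never defined")
            rows.append(mlc_raw.copy())
            angles.append(gantry % 360.0)
            weights.append(float(item.CumulativeMetersetWeight))
            jx_list.append(jaw_x)
            jy_list.append(jaw_y)

        w = np.asarray(weights, dtype=float)
        if np.any(np.diff(w) < -_WEIGHT_TOL):
            raise NonMonotoneWeightError(
                f"beam {name}: cumulative meterset weights decrease"
            )
        final = float(getattr(beam, "FinalCumulativeMetersetWeight", w[-1]) or w[-1])
        if final <= 0:
            raise RTPlanError(f"beam {name}: final cumulative weight is not positive")
        w = np.clip(w / final, 0.0, 1.0)

        raw = np.vstack(rows)
        if raw.shape[1] != 2 * machine.n_pairs:
            raise MissingMLCError(
                f"beam {name}: expected {2 * machine.n_pairs} leaf positions per CP"
            )
        bank_a, bank_b, swapped = _resolve_banks(raw, machine.n_pairs)
        # clamp sub-tolerance negative gaps introduced by mm rounding
        neg = (bank_b - bank_a < 0) & (bank_b - bank_a >= -_GAP_TOL)
        bank_b = np.where(neg, bank_a, bank_b)

        cmap = constraints_map or {}
        constraints = cmap.get(machine.name)
        if constraints is None:
            constraints = default_constraints(
                "binned-type" if machine.name == "elekta_mlci" else "continuous-type"
            )

        cps = [
            ControlPoint(
                index=i,
                gantry_angle=angles[i],
                leaf_pos_a=bank_a[i],
                leaf_pos_b=bank_b[i],
                jaw_x=jx_list[i],
                jaw_y=jy_list[i],
                cum_weight=float(w[i]),
            )
            for i in range(len(rows))
        ]
        arc = ArcBeam(
            machine=machine,
            constraints=constraints,
            cps=cps,
            beam_mu=float(beam_mu),
            rotation=rotation,
            collimator_angle=collimator,
            name=name,
        )
        arc.validate()
        plan_arcs.append(arc)
        meta["beams"][name] = {"machine": machine.name, "bank_swapped": swapped}

    plan_id = str(getattr(ds, "RTPlanName", "") or getattr(ds, "RTPlanLabel", "plan"))
    plan = Plan(plan_id=plan_id, arcs=plan_arcs, meta=meta)
    plan.validate()
    return plan
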
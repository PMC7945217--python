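import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for naive_reference

from vmatcx.machines import (
    MLCModel,
    boundaries_from_widths,
    default_constraints,
    elekta_mlci,
    millennium120,
)
from vmatcx.rtplan import ArcBeam, ControlPoint


@pytest.fixture(scope="session")
def millennium():
    return millennium120()


@pytest.fixture(scope="session")
def mlci():
    return elekta_mlci()


@pytest.fixture(scope="session", params=["millennium120", "elekta_mlci"])
def machine(request, millennium, mlci):
    """Both built-in MLC geometries."""
    return millennium if request.param == "millennium120" else mlci


@pytest.fixture(scope="session")
def tiny_machine():
    """Three unit-width pairs — small enough to hand-check every score."""
    widths = (1.0, 1.0, 1.0)
    return MLCModel(
        name="tiny3",
        n_pairs=3,
        leaf_widths=widths,
        leaf_boundaries=tuple(boundaries_from_widths(widths)),
        overtravel=10.0,
    )


def make_cp(index, bank_a, bank_b, jaw_y=(-10.0, 10.0), jaw_x=(-10.0, 10.0), cum=0.0,
            gantry=0.0):
    return ControlPoint(
        index=index,
        gantry_angle=gantry,
        leaf_pos_a=np.asarray(bank_a, dtype=float),
        leaf_pos_b=np.asarray(bank_b, dtype=float),
        jaw_x=jaw_x,
        jaw_y=jaw_y,
        cum_weight=cum,
    )


def make_arc(machine, cps, beam_mu=100.0, constraints=None, rotation="CW"):
    return ArcBeam(
        machine=machine,
        constraints=constraints or default_constraints("continuous-type"),
        cps=cps,
        beam_mu=beam_mu,
        rotation=rotation,
    )


@pytest.fixture
def tiny_arc_factory(tiny_machine):
    """Build a small arc on the 3-pair machine from (bank_a, bank_b) lists."""

    def build(cp_specs, cum_weights=None, beam_mu=100.0, jaw_y=(-1.5, 1.5)):
        n = len(cp_specs)
        cums = cum_weights if cum_weights is not None else np.linspace(0, 1, n)
        cps = [
            make_cp(i, a, b, jaw_y=jaw_y, cum=float(cums[i]), gantry=float(2 * i))
            for i, (a, b) in enumerate(cp_specs)
        ]
        return make_arc(tiny_machine, cps, beam_mu=beam_mu)

    return build
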
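import copy

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmatcx.complexity import (
    ClosedArcError,
    aav,
    arc_aperture_extent,
    arc_complexity,
    combine_scores,
    infield_pairs,
    lsv,
    mcs_arc,
    pos_max,
    score_plan,
    segment_area,
    segment_weights,
    segment_width,
)
from vmatcx.machines import millennium120
from vmatcx.rtplan import Plan
from vmatcx.synth import random_arc, unmodulated_fixture

from conftest import make_arc, make_cp
from naive_reference import naive_arc_scores

RECT = ([-2.0, -2.0, -2.0], [2.0, 2.0, 2.0])


class TestInfieldPairs:
    def test_all_closed_is_empty(self, tiny_machine):
        cp = make_cp(0, [0, 0, 0], [0, 0, 0], jaw_y=(-1.5, 1.5))
        assert infield_pairs(cp, tiny_machine).size == 0

    def test_jaw_excludes_pairs_fully_outside(self, millennium):
        # three open pairs inside the jaws, two open pairs fully above jaw_y[1]
        a = np.zeros(60)
        b = np.zeros(60)
        inside, above = [29, 30, 31], [40, 41]  # strips [-0.5, 1] and [5, 6]
        a[inside + above] = -3.0
        b[inside + above] = 3.0
        cp = make_cp(0, a, b, jaw_y=(-1.0, 1.5))
        assert list(infield_pairs(cp, millennium)) == inside

    def test_gap_at_threshold_excluded(self, tiny_machine):
        cp = make_cp(0, [0, 0, 0], [0.05, 0.05, 0.05], jaw_y=(-1.5, 1.5))
        assert infield_pairs(cp, tiny_machine, closed_gap_threshold=0.05).size == 0


class TestSegmentScores:
    def test_sw_is_max_gap(self, tiny_machine):
        cp = make_cp(0, [0, 0, 0], [2, 3, 4], jaw_y=(-1.5, 1.5))
        assert segment_width(cp, tiny_machine) == 4.0

    def test_sw_rectangular(self, tiny_machine):
        cp = make_cp(0, [-5, -5, -5], [5, 5, 5], jaw_y=(-1.5, 1.5))
        assert segment_width(cp, tiny_machine) == 10.0

    def test_sw_sa_closed_aperture_are_zero(self, tiny_machine):
        cp = make_cp(0, [0, 0, 0], [0, 0, 0], jaw_y=(-1.5, 1.5))
        assert segment_width(cp, tiny_machine) == 0.0
        assert segment_area(cp, tiny_machine) == 0.0

    def test_sa_hand_value(self, tiny_machine):
        """Three unit-width pairs with gaps 2, 3, 4 cm open 9 cm²."""
        cp = make_cp(0, [0, 0, 0], [2, 3, 4], jaw_y=(-1.5, 1.5))
        assert segment_area(cp, tiny_machine) == pytest.approx(9.0)

    def test_sa_rectangle_on_clinical_mlc(self, millennium):
        # 10 cm gap across the ten central 10 mm-equivalent strips: y in [-5, 5]
        a = np.full(60, 0.0)
        b = np.full(60, 0.0)
        sel = (millennium.leaf_centers > -5) & (millennium.leaf_centers < 5)
        a[sel] = -5.0
        b[sel] = 5.0
        cp = make_cp(0, a, b, jaw_y=(-5.0, 5.0))
        assert segment_area(cp, millennium) == pytest.approx(100.0)

    def test_pos_max_range_and_degenerate(self, tiny_machine):
        cp = make_cp(0, [0, 1, 2], [10, 11, 12], jaw_y=(-1.5, 1.5))
        assert pos_max(cp, tiny_machine, "A") == pytest.approx(2.0)
        flat = make_cp(0, [1, 1, 1], [5, 5, 5], jaw_y=(-1.5, 1.5))
        assert pos_max(flat, tiny_machine, "A") == 0.0


class TestLSV:
    def test_hand_value_both_banks_0_1_2(self, tiny_machine):
        """Both banks with in-field positions {0,1,2}: each factor 0.5."""
        cp = make_cp(0, [0, 1, 2], [10, 11, 12], jaw_y=(-1.5, 1.5))
        assert lsv(cp, tiny_machine) == pytest.approx(0.25)

    def test_rectangular_aperture_scores_one(self, tiny_machine):
        cp = make_cp(0, [-2, -2, -2], [2, 2, 2], jaw_y=(-1.5, 1.5))
        assert lsv(cp, tiny_machine) == 1.0

    def test_single_infield_pair_scores_one(self, tiny_machine):
        cp = make_cp(0, [0, -2, 0], [0, 2, 0], jaw_y=(-1.5, 1.5))
        assert lsv(cp, tiny_machine) == 1.0


class TestAAV:
    def test_constant_aperture_is_one_everywhere(self, tiny_arc_factory):
        arc = tiny_arc_factory([RECT, RECT, RECT])
        for cp in arc.cps:
            assert aav(cp, arc) == pytest.approx(1.0)

    def test_hand_value_one_pair_two_cps(self, tiny_arc_factory):
        """Gaps 2 then 4 cm with shared right positions: AAV 0.5 and 1.0."""
        arc = tiny_arc_factory(
            [([0, 0, 0], [0, 2, 0]), ([0, 0, 0], [0, 4, 0])]
        )
        assert aav(arc.cps[0], arc) == pytest.approx(0.5)
        assert aav(arc.cps[1], arc) == pytest.approx(1.0)

    def test_closed_cp_inside_open_arc_is_zero(self, tiny_arc_factory):
        arc = tiny_arc_factory(
            [RECT, ([0, 0, 0], [0, 0, 0]), RECT], cum_weights=[0, 0.5, 1]
        )
        assert aav(arc.cps[1], arc) == 0.0

    def test_fully_closed_arc_is_an_error(self, tiny_arc_factory):
        closed = ([0, 0, 0], [0, 0, 0])
        arc = tiny_arc_factory([closed, closed])
        with pytest.raises(ClosedArcError):
            arc_aperture_extent(arc)


class TestMCS:
    def test_weights_hand_values(self, tiny_arc_factory):
        arc = tiny_arc_factory([RECT, RECT, RECT], cum_weights=[0.0, 0.4, 1.0])
        np.testing.assert_allclose(segment_weights(arc), [0.4, 0.6])

    def test_combination_hand_value(self):
        """LSV {1,.5,1}, AAV {1,.5,1}, weights {.5,.5} combine to 0.5625."""
        assert combine_scores([1, 0.5, 1], [1, 0.5, 1], [0.5, 0.5]) == 0.5625

    def test_unmodulated_arc_scores_exactly_one(self, machine):
        plan = unmodulated_fixture(machine)
        assert mcs_arc(plan.arcs[0]) == 1.0

    def test_mu_rescaling_leaves_mcs_unchanged(self, millennium):
        arc = random_arc(millennium, seed=7)
        before = mcs_arc(arc)
        arc.beam_mu *= 10.0
        assert mcs_arc(arc) == before


class TestOracleEquivalence:
    """Production vectorized scores vs the naive per-leaf double loop."""

    @pytest.mark.parametrize("machine_name", ["millennium120", "elekta_mlci"])
    def test_random_arcs_match_naive_reference(self, machine_name, millennium, mlci):
        machine = millennium if machine_name == "millennium120" else mlci
        for seed in range(100):
            arc = random_arc(machine, seed=seed)
            ref = naive_arc_scores(arc)
            got = arc_complexity(arc)
            for s, sw, sa, l, a in zip(
                got.segments, ref["sw"], ref["sa"], ref["lsv"], ref["aav"]
            ):
                for x, y in ((s.sw, sw), (s.sa, sa), (s.lsv, l), (s.aav, a)):
                    assert abs(x - y) <= 1e-12 * max(1.0, abs(y))
            assert abs(got.mcs - ref["mcs"]) <= 1e-12 * max(1.0, abs(ref["mcs"]))


class TestInvariances:
    def test_translation_invariance(self, millennium):
        """A common offset on both banks (and x-jaws) changes nothing."""
        arc = random_arc(millennium, seed=3)
        base = arc_complexity(arc)
        shifted = copy.deepcopy(arc)
        for cp in shifted.cps:
            cp.leaf_pos_a = cp.leaf_pos_a + 1.75
            cp.leaf_pos_b = cp.leaf_pos_b + 1.75
            cp.jaw_x = (cp.jaw_x[0] + 1.75, cp.jaw_x[1] + 1.75)
        got = arc_complexity(shifted)
        assert got.mcs == pytest.approx(base.mcs, rel=1e-12)
        for s1, s2 in zip(base.segments, got.segments):
            assert s2.sw == pytest.approx(s1.sw, rel=1e-12)
            assert s2.sa == pytest.approx(s1.sa, rel=1e-12)
            assert s2.lsv == pytest.approx(s1.lsv, rel=1e-12)
            assert s2.aav == pytest.approx(s1.aav, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 50),
        widen=st.floats(min_value=0.1, max_value=2.0),
        cp_pick=st.integers(0, 10**6),
    )
    def test_widening_a_gap_increases_sa_and_never_shrinks_sw(
        self, seed, widen, cp_pick
    ):
        machine = millennium120()
        arc = random_arc(machine, seed=seed)
        cp = arc.cps[cp_pick % len(arc.cps)]
        idx = infield_pairs(cp, machine)
        if idx.size == 0:
            return
        n = int(idx[cp_pick % idx.size])
        sa0, sw0 = segment_area(cp, machine), segment_width(cp, machine)
        cp.leaf_pos_b = cp.leaf_pos_b.copy()
        new_b = min(cp.leaf_pos_b[n] + widen, machine.max_leaf_position)
        if new_b <= cp.leaf_pos_b[n]:  # already at the travel limit
            return
        cp.leaf_pos_b[n] = new_b
        assert segment_area(cp, machine) > sa0
        assert segment_width(cp, machine) >= sw0

    def test_range_laws_on_random_arcs(self, machine):
        for seed in range(20):
            arc = random_arc(machine, seed=seed)
            res = arc_complexity(arc)
            assert 0.0 <= res.mcs <= 1.0
            w = segment_weights(arc)
            assert w.sum() == pytest.approx(1.0, abs=1e-6)
            for s in res.segments:
                assert 0.0 <= s.lsv <= 1.0
                assert 0.0 <= s.aav <= 1.0


class TestPlanAggregation:
    def test_single_arc_plan_mcs_is_arc_mcs(self, millennium):
        arc = random_arc(millennium, seed=1)
        plan = Plan("one", [arc])
        rep = score_plan(plan)
        assert rep.mcs == pytest.approx(mcs_arc(arc))

    def test_two_identical_arcs(self, millennium):
        arc = random_arc(millennium, seed=2)
        plan = Plan("two", [arc, copy.deepcopy(arc)])
        rep = score_plan(plan)
        assert rep.mcs == pytest.approx(mcs_arc(arc))

    def test_plan_mcs_is_mu_weighted_mean_of_arc_mcs(self, millennium):
        a1 = random_arc(millennium, seed=5)
        a2 = random_arc(millennium, seed=6)
        a1.beam_mu, a2.beam_mu = 100.0, 300.0
        rep = score_plan(Plan("w", [a1, a2]))
        expected = (mcs_arc(a1) * 100 + mcs_arc(a2) * 300) / 400
        assert rep.mcs == pytest.approx(expected, rel=1e-12)
        # the weighting rule itself, on the hand numbers: 0.2/0.4 at 100/300 MU
        assert (0.2 * 100 + 0.4 * 300) / 400 == 0.35
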
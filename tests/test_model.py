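"""Structural and dynamical properties of the factored exercise model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reachpomdp as rp
from reachpomdp.model import (
    ACTIONS,
    PERF_STATES,
    CalibrationError,
    InvariantError,
    PaceFunction,
    ParameterError,
    RangeProfile,
    UndefinedStretchError,
    admissible_profiles,
    stretch_of,
)

profiles_st = st.sampled_from(admissible_profiles())
set_target_st = st.sampled_from(ACTIONS[:-1])


class TestStretch:
    @pytest.mark.parametrize(
        "action, profile, expected",
        [
            (("d3", "none"), (3, 0, 0), 0),  # target at the user's range
            (("d3", "max"), (0, 0, 0), 9),  # hardest ask for an empty profile
            (("d1", "none"), (3, 0, 0), -2),
            (("d1", "none"), (3, 3, 3), -2),  # raw -8, floored at the domain min
        ],
    )
    def test_worked_examples(self, action, profile, expected):
        assert stretch_of(rp.make_action(*action), RangeProfile(*profile)) == expected

    def test_image_is_exactly_the_twelve_domain_values(self):
        image = {
            stretch_of(a, p) for a in ACTIONS[:-1] for p in admissible_profiles()
        }
        assert image == set(range(-2, 10))

    def test_stop_action_has_no_stretch(self):
        with pytest.raises(UndefinedStretchError):
            stretch_of(rp.STOP, RangeProfile(0, 0, 0))

    def test_inadmissible_profile_rejected(self):
        with pytest.raises(InvariantError):
            stretch_of(rp.make_action("d1", "none"), RangeProfile(0, 1, 0))


class TestEnumeration:
    def test_ten_actions(self):
        assert len(ACTIONS) == 10
        assert sum(a.is_stop for a in ACTIONS) == 1

    def test_twenty_admissible_profiles(self):
        profs = admissible_profiles()
        assert len(profs) == 20
        assert all(p.admissible for p in profs)

    def test_relaxed_joint_state_count(self, model):
        assert model.count_full_states(relaxed=True) == 82944

    def test_hidden_state_count(self, model):
        assert len(model.hidden_states) == 2 * 20 * 3


class TestPaceFunction:
    def test_two_point_calibration_closed_form(self):
        p = rp.calibrate_pace((-1, 0.10), (3, 0.90))
        assert p.m == pytest.approx(1.0, abs=1e-12)
        assert p.sigma_s == pytest.approx(2.0 / math.log(9.0), abs=1e-12)
        # both anchors reproduced to high precision
        assert p(-1) == pytest.approx(0.10, abs=1e-9)
        assert p(3) == pytest.approx(0.90, abs=1e-9)

    def test_half_probability_anchor_pins_the_mean(self):
        p = rp.calibrate_pace((-1, 0.5), (3, 0.9))
        assert p.m == pytest.approx(-1.0, abs=1e-9)

    def test_non_monotone_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            rp.calibrate_pace((0, 0.5), (1, 0.5))
        with pytest.raises(CalibrationError):
            rp.calibrate_pace((1, 0.2), (0, 0.8))

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ParameterError):
            PaceFunction(m=0.0, sigma_s=0.0)

    def test_value_at_mean_stretch_is_half(self):
        assert PaceFunction(m=2.5, sigma_s=1.7)(2.5) == pytest.approx(0.5)

    @given(
        m=st.floats(-5, 5),
        # sigma bounded away from 0 so the logistic stays representable
        # (strictly inside (0,1)) across the whole stretch domain
        sigma=st.floats(0.5, 5),
        shift=st.floats(-3, 0),
        s1=st.integers(-2, 8),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_stretch_and_fatigue_makes_event_likelier(
        self, m, sigma, shift, s1
    ):
        p = PaceFunction(m=m, sigma_s=sigma, fatigue_shift=shift)
        assert 0.0 < p(s1) < 1.0
        assert p(s1 + 1) > p(s1)
        assert p(s1, fatigued=True) >= p(s1, fatigued=False)


class TestPerformanceModel:
    @given(prof=profiles_st, action=set_target_st, fat=st.booleans())
    @settings(max_examples=60, deadline=None)
    def test_distribution_sums_to_one(self, model, prof, action, fat):
        h = rp.HiddenState(fat, prof, 1)
        dist = model.transition_performance(h, action)
        assert dist.shape == (18,)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        assert (dist >= 0).all()

    def test_compensation_probability_matches_pace_limits(self, model):
        # stretch 3: d3@none against an empty profile
        h = rp.HiddenState(False, RangeProfile(0, 0, 0), 1)
        dist = model.transition_performance(h, rp.make_action("d3", "none"))
        p_comp = sum(p for p, perf in zip(dist, PERF_STATES) if perf.comp)
        assert p_comp == pytest.approx(0.90, abs=1e-9)

    def test_fatigue_raises_compensation_at_equal_stretch(self, model):
        a = rp.make_action("d2", "none")
        prof = RangeProfile(1, 0, 0)
        p = {}
        for fat in (False, True):
            dist = model.transition_performance(rp.HiddenState(fat, prof, 1), a)
            p[fat] = sum(q for q, perf in zip(dist, PERF_STATES) if perf.comp)
        assert p[True] >= p[False]


class TestFatigueTransition:
    def test_fatigue_is_sticky(self, model):
        h = rp.HiddenState(True, RangeProfile(2, 1, 0), 0)
        assert model.transition_fatigue(h, rp.make_action("d1", "none"), 0) == 1.0

    def test_onset_hazard_monotone_in_stretch(self, model):
        h = rp.HiddenState(False, RangeProfile(0, 0, 0), 0)
        a = rp.make_action("d1", "none")
        hazards = [model.transition_fatigue(h, a, s) for s in range(-2, 10)]
        assert all(b > a_ for a_, b in zip(hazards, hazards[1:]))


class TestRangeGrowth:
    def test_ceiling_profile_cannot_grow(self, model):
        h = rp.HiddenState(False, RangeProfile(3, 3, 3), 2)
        perf = rp.PerformanceState("norm", "max", False)
        dist = model.transition_ranges(h, rp.make_action("d3", "max"), perf)
        assert dist == {RangeProfile(3, 3, 3): 1.0}

    def test_spillover_to_next_resistance(self, model):
        # n_min already at d3: practising d3@min can open n_max (none -> d1)
        h = rp.HiddenState(False, RangeProfile(3, 3, 0), 1)
        perf = rp.PerformanceState("norm", "max", False)
        dist = model.transition_ranges(h, rp.make_action("d3", "min"), perf)
        assert dist.get(RangeProfile(3, 3, 1), 0.0) > 0.0

    def test_failure_blocks_growth(self, model):
        h = rp.HiddenState(False, RangeProfile(0, 0, 0), 2)
        perf = rp.PerformanceState("none", "min", False)
        dist = model.transition_ranges(h, rp.make_action("d1", "none"), perf)
        assert dist == {RangeProfile(0, 0, 0): 1.0}

    def test_higher_learnrate_grows_faster(self, model):
        perf = rp.PerformanceState("norm", "max", False)
        a = rp.make_action("d1", "none")
        grown = RangeProfile(1, 0, 0)
        p_lo = model.transition_ranges(
            rp.HiddenState(False, RangeProfile(0, 0, 0), 0), a, perf
        )[grown]
        p_hi = model.transition_ranges(
            rp.HiddenState(False, RangeProfile(0, 0, 0), 2), a, perf
        )[grown]
        assert p_hi > p_lo

    @given(prof=profiles_st, action=set_target_st)
    @settings(max_examples=60, deadline=None)
    def test_outputs_admissible_and_normalised(self, model, prof, action):
        h = rp.HiddenState(False, prof, 2)
        perf = rp.PerformanceState("slow", "min", False)
        dist = model.transition_ranges(h, action, perf)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p.admissible for p in dist)


class TestJointTransition:
    def test_all_rows_sum_to_one(self, model):
        model.tabular.validate()

    def test_full_state_transition_normalised(self, model):
        full = rp.FullState(
            rp.HiddenState(False, RangeProfile(1, 1, 0), 1),
            rp.PerformanceState("norm", "max", False),
            0,
        )
        for a in ACTIONS:
            dist = model.transition(full, a)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_joint_row_matches_hand_composed_product(self, model):
        """Brute-force oracle: recompute one kernel row from raw sigmoids."""
        prof = RangeProfile(1, 0, 0)
        h = rp.HiddenState(False, prof, 1)
        action = rp.make_action("d2", "none")
        s = 2 - 1  # action ladder 2, profile ladder 1

        def sig(x):
            return 1.0 / (1.0 + math.exp(-x))

        dyn = model.dynamics
        pv = {
            name: sig((s - dyn.pace(name).m) / dyn.pace(name).sigma_s)
            for name in ("fail", "slow", "ctrl_none", "ctrl_min", "comp", "fatigue")
        }
        p_ttt = {
            "none": pv["fail"],
            "slow": (1 - pv["fail"]) * pv["slow"],
            "norm": (1 - pv["fail"]) * (1 - pv["slow"]),
        }
        p_ctrl = {
            "none": pv["ctrl_none"],
            "min": (1 - pv["ctrl_none"]) * pv["ctrl_min"],
            "max": (1 - pv["ctrl_none"]) * (1 - pv["ctrl_min"]),
        }
        p_up = dyn.p_up[1, 0]
        expected = np.zeros((18, len(model.hidden_states)))
        for oi, perf in enumerate(PERF_STATES):
            po = (
                p_ttt[perf.ttt]
                * p_ctrl[perf.ctrl]
                * (pv["comp"] if perf.comp else 1 - pv["comp"])
            )
            grows = perf.ttt != "none"  # s=1 is inside the growth window
            for fat_next, pf in ((True, pv["fatigue"]), (False, 1 - pv["fatigue"])):
                targets = (
                    [(RangeProfile(2, 0, 0), p_up), (prof, 1 - p_up)]
                    if grows
                    else [(prof, 1.0)]
                )
                for nprof, pr in targets:
                    hi = model.hidden_index[rp.HiddenState(fat_next, nprof, 1)]
                    expected[oi, hi] += po * pf * pr
        ai = ACTIONS.index(action)
        row = model.tabular.joint[ai, model.hidden_index[h]]
        assert np.allclose(row, expected, atol=1e-12)

    def test_stop_resets_fatigue_and_keeps_ranges(self, model):
        h = rp.HiddenState(True, RangeProfile(2, 1, 1), 0)
        out = model.hidden_step(h, rp.STOP)
        assert list(out.values()) == [1.0]
        (_, h_next), = out.keys()
        assert h_next == rp.HiddenState(False, RangeProfile(2, 1, 1), 0)


class TestObservationModel:
    def test_deterministic_mixed_observability(self, model):
        full = rp.FullState(
            rp.HiddenState(False, RangeProfile(0, 0, 0), 0),
            rp.PerformanceState("slow", "min", True),
            1,
        )
        a = rp.make_action("d1", "none")
        total = 0.0
        for perf in PERF_STATES:
            p = model.observation_prob(perf, a, full)
            assert p == (1.0 if perf == full.perf else 0.0)
            total += p
        assert total == 1.0


class TestReward:
    def test_no_reward_when_fatigued(self, model):
        h = rp.HiddenState(True, RangeProfile(3, 3, 3), 1)
        perf = rp.PerformanceState("norm", "max", False)
        for a in ACTIONS[:-1]:
            assert model.reward(h, a, perf) == 0.0

    def test_goal_trial_is_the_global_maximum(self, model):
        best = rp.HiddenState(False, RangeProfile(3, 3, 3), 1)
        perf = rp.PerformanceState("norm", "max", False)
        top = model.reward(best, rp.make_action("d3", "max"), perf)
        for h in model.hidden_states:
            for a in ACTIONS:
                for p in PERF_STATES:
                    assert model.reward(h, a, p) <= top

    def test_zero_weights_give_zero_reward(self):
        spec = rp.RewardSpec(r_goal=0, r_stretch=0, r_perform=0, c_stop=0)
        m = rp.RehabModel(reward_spec=spec)
        h = rp.HiddenState(False, RangeProfile(3, 3, 3), 1)
        perf = rp.PerformanceState("norm", "max", False)
        for a in ACTIONS:
            assert m.reward(h, a, perf) == 0.0

    def test_stop_costs_its_configured_price(self, model):
        h = rp.HiddenState(False, RangeProfile(0, 0, 0), 0)
        perf = rp.PerformanceState("none", "none", False)
        assert model.reward(h, rp.STOP, perf) == -model.reward_spec.c_stop

    def test_gamma_bounds_enforced(self):
        with pytest.raises(ParameterError):
            rp.RewardSpec(gamma=1.0)
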
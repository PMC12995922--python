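"""Regime grid, cohort/state invariants and the management scheduler."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from standres.stand_model import (
    Cohort,
    ManagementAction,
    Regime,
    StandState,
    advance_one_step,
    apply_action,
    clearcut_baseline,
    enumerate_regimes,
    enumerate_reachable_states,
    scheduled_actions,
)


class TestRegimeGrid:
    @pytest.mark.parametrize(
        "sizes, ages, expected",
        [
            ([0.1, 0.15, 0.2, 0.25, 0.3], [20, 40, 60], 15),
            ([], [20], 0),
            ([0.1], [20, 40, 60], 3),
        ],
    )
    def test_grid_size_is_cartesian_product(self, sizes, ages, expected):
        regimes = enumerate_regimes(sizes, ages)
        assert len(regimes) == expected
        assert len({r.id for r in regimes}) == expected

    def test_grid_order_is_stable(self):
        a = enumerate_regimes([0.3, 0.1], [60, 20])
        b = enumerate_regimes([0.1, 0.3], [20, 60])
        assert [r.id for r in a] == [r.id for r in b]

    def test_duplicate_grid_entries_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_regimes([0.1, 0.1], [20])
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_regimes([0.1], [20, 20])

    def test_baseline_is_separate_and_clean(self):
        base = clearcut_baseline()
        assert base.kind == "clearcut" and base.s_gap is None
        assert all(r.kind == "gapcut" for r in enumerate_regimes([0.1], [20]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(id="x", kind="gapcut", s_gap=1.2, age_gap=20),
            dict(id="x", kind="gapcut", s_gap=0.3, age_gap=90),
            dict(id="x", kind="gapcut", s_gap=0.3, age_gap=None),
            dict(id="x", kind="clearcut", s_gap=0.3),
        ],
    )
    def test_invalid_regimes_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Regime(**kwargs)


class TestStateInvariants:
    def test_two_cohorts_require_strictly_older_leader(self):
        lead = Cohort(40, 0.7, leading=True)
        with pytest.raises(ValueError):
            StandState((lead, Cohort(40, 0.3, leading=False)))
        with pytest.raises(ValueError):
            StandState((Cohort(30, 0.7, leading=True), Cohort(40, 0.3, leading=False)))

    def test_exactly_one_leading_cohort(self):
        with pytest.raises(ValueError):
            StandState((Cohort(40, 0.5, leading=True), Cohort(20, 0.5, leading=True)))

    def test_bare_soil_key(self):
        assert StandState((), "r").key() == ("r", -1, -1)


class TestScheduler:
    def test_clearcut_harvest_and_replant_at_rotation(self):
        state = StandState((Cohort(85, 1.0),), "clearcut")
        kinds = [a.kind for a in scheduled_actions(state, clearcut_baseline())]
        assert kinds == ["final_harvest", "replant"]

    def test_gap_cut_at_gap_age_on_single_cohort(self):
        regime = Regime("g", "gapcut", s_gap=0.3, age_gap=40)
        state = StandState((Cohort(40, 1.0),), "g")
        actions = scheduled_actions(state, regime)
        assert [a.kind for a in actions] == ["gap_cut"]
        assert actions[0].share == 0.3

    def test_two_cohorts_off_trigger_ages_get_thinnings(self):
        regime = Regime("g", "gapcut", s_gap=0.3, age_gap=40)
        state = StandState(
            (Cohort(70, 0.7, leading=True), Cohort(30, 0.3, leading=False)), "g"
        )
        assert [a.kind for a in scheduled_actions(state, regime)] == [
            "thinning",
            "thinning",
        ]

    def test_single_cohort_past_gap_age_gets_no_gap_cut(self):
        regime = Regime("g", "gapcut", s_gap=0.3, age_gap=40)
        state = StandState((Cohort(45, 1.0),), "g")
        assert [a.kind for a in scheduled_actions(state, regime)] == ["thinning"]


class TestApplyAction:
    def test_gap_cut_splits_shares(self):
        state = StandState((Cohort(40, 1.0),), "g")
        new = apply_action(state, ManagementAction("gap_cut", 0, share=0.3))
        assert new.leading_age == 40 and new.gap_age == 0
        assert new.leading_cohort.share == pytest.approx(0.7)
        assert new.gap_cohort.share == pytest.approx(0.3)

    def test_replant_merges_equal_ages(self):
        state = StandState((Cohort(0, 0.6),), "g")
        new = apply_action(
            state, ManagementAction("replant", -1, share=0.4)
        )
        assert len(new.cohorts) == 1
        assert new.cohorts[0].share == pytest.approx(1.0)
        assert new.cohorts[0].age == 0

    def test_harvest_of_leader_promotes_gap_cohort(self):
        # Hand-traced cycle for regime s=0.3 / age_gap=40: the leading
        # cohort reaches rotation with the former gap cohort at age 45.
        state = StandState(
            (Cohort(85, 0.7, leading=True), Cohort(45, 0.3, leading=False)), "g"
        )
        state = apply_action(state, ManagementAction("final_harvest", 0))
        state = apply_action(state, ManagementAction("replant", -1, share=0.7))
        assert state.leading_age == 45 and state.leading_cohort.share == pytest.approx(0.3)
        assert state.gap_age == 0 and state.gap_cohort.share == pytest.approx(0.7)

    def test_illegal_gap_cut_on_two_cohorts_rejected(self):
        state = StandState(
            (Cohort(70, 0.7, leading=True), Cohort(30, 0.3, leading=False)), "g"
        )
        with pytest.raises(ValueError, match="single-cohort"):
            apply_action(state, ManagementAction("gap_cut", 0, share=0.3))


class TestZeroHazardDynamics:
    def test_clearcut_trajectory_is_periodic_with_rotation(self):
        regime = clearcut_baseline()
        state = StandState((), regime.id)
        states = []
        for _ in range(3 * 17 + 1):
            states.append(state.key())
            state = advance_one_step(state, regime)
        # After the bare-soil start the state cycles with period 85 yr.
        assert states[1:18] == states[18:35] == states[35:52]

    @pytest.mark.parametrize("s_gap, age_gap", [(0.3, 40), (0.1, 20), (0.2, 60)])
    def test_share_conservation_along_deterministic_paths(self, s_gap, age_gap):
        regime = Regime("g", "gapcut", s_gap=s_gap, age_gap=age_gap)
        state = StandState((), regime.id)
        for _ in range(200):
            state = advance_one_step(state, regime)
            assert state.share_total() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("s_gap, age_gap", [(0.3, 40), (0.25, 20), (0.1, 60)])
    def test_reachable_closure_matches_long_simulation(self, s_gap, age_gap):
        regime = Regime("g", "gapcut", s_gap=s_gap, age_gap=age_gap)
        closure = enumerate_reachable_states(regime)
        state = StandState((), regime.id)
        visited = set()
        for _ in range(500):
            visited.add(state.key())
            state = advance_one_step(state, regime)
        assert visited == closure


@given(
    s_gap=st.floats(0.05, 0.95),
    age_gap=st.sampled_from([20, 40, 60]),
    n_steps=st.integers(1, 60),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_share_conservation_property(s_gap, age_gap, n_steps):
    """Every reachable state under any gap regime keeps total share 1."""
    regime = Regime("g", "gapcut", s_gap=s_gap, age_gap=age_gap)
    state = StandState((), regime.id)
    for _ in range(n_steps):
        state = advance_one_step(state, regime)
    assert state.share_total() == pytest.approx(1.0, abs=1e-12)
    assert 1 <= len(state.cohorts) <= 2
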
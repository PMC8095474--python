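"""Harvest-oldest-class transition dynamics: permutation structure,
rotation periodicity, backcasting, trajectory bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfmsim import (
    AgeClassDistribution,
    FORECAST,
    BACKCAST,
    forward_transition_matrix,
    initialize_state,
    run_trajectory,
    step_backward,
    step_forward,
)
from conftest import random_states


def permutation_oracle(areas):
    """Direct index-level transcription of the three-step recipe."""
    nxt = np.empty_like(areas)
    nxt[0] = areas[23]          # harvested oldest class regenerates
    nxt[1:] = areas[:23]        # everything else ages one class
    return nxt


class TestStepForward:
    def test_mature_forest_is_clearcut_and_regenerated(self, growth):
        areas = np.zeros(24)
        areas[23] = 10_000.0
        res = step_forward(AgeClassDistribution(areas), growth)
        assert res.next_state.areas[0] == 10_000.0
        assert res.next_state.areas[1:].sum() == 0.0
        assert res.harvested_area == 10_000.0
        assert round(res.harvested_volume) == 9877

    def test_empty_oldest_class_harvests_nothing(self, growth):
        areas = np.zeros(24)
        areas[0] = 10_000.0
        res = step_forward(AgeClassDistribution(areas), growth)
        assert res.harvested_area == 0.0
        assert res.harvested_volume == 0.0

    def test_uniform_state_is_stationary(self, growth, uniform_state):
        res = step_forward(uniform_state, growth)
        np.testing.assert_array_equal(res.next_state.areas, uniform_state.areas)

    def test_matches_permutation_matrix_on_random_states(self, growth):
        mat = forward_transition_matrix()
        for st_ in random_states(100, seed=42):
            by_step = step_forward(st_, growth).next_state.areas
            by_matrix = mat @ st_.areas
            assert np.abs(by_step - by_matrix).max() == 0.0
            np.testing.assert_array_equal(by_step, permutation_oracle(st_.areas))

    def test_harvested_volume_is_area_times_oldest_class_volume(self, growth):
        for st_ in random_states(10, seed=3):
            res = step_forward(st_, growth)
            v120 = (1 - math.exp(-0.05 * 120)) ** 5
            assert res.harvested_volume == pytest.approx(st_.areas[23] * v120, rel=1e-12)


class TestInverseAndRotation:
    def test_backward_inverts_forward(self, growth):
        for st_ in random_states(20, seed=5):
            fwd = step_forward(st_, growth).next_state
            back = step_backward(fwd)
            np.testing.assert_array_equal(back.areas, st_.areas)

    def test_forward_inverts_backward(self, growth):
        for st_ in random_states(20, seed=6):
            back = step_backward(st_)
            fwd = step_forward(back, growth).next_state
            np.testing.assert_array_equal(fwd.areas, st_.areas)

    def test_full_rotation_returns_initial_state(self, growth):
        """24 five-year steps (one 120-year rotation) are the identity."""
        for st_ in random_states(50, seed=11):
            state = st_
            for _ in range(24):
                state = step_forward(state, growth).next_state
            np.testing.assert_array_equal(state.areas, st_.areas)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1e5), min_size=24, max_size=24).filter(lambda a: sum(a) > 0))
    def test_area_conserved_under_any_steps(self, areas):
        """Steps permute the area vector bitwise, so the multiset of class
        areas (and hence the total, up to summation order) is conserved."""
        initial = np.array(areas)
        state = AgeClassDistribution(initial)
        for _ in range(7):
            state = step_forward(state).next_state
        np.testing.assert_array_equal(np.sort(state.areas), np.sort(initial))
        for _ in range(3):
            state = step_backward(state)
        np.testing.assert_array_equal(np.sort(state.areas), np.sort(initial))
        assert state.total_area == pytest.approx(initial.sum(), rel=1e-12)


class TestInitialization:
    def test_forecast_mode_is_identity(self, uniform_state):
        init = initialize_state(uniform_state, FORECAST)
        np.testing.assert_array_equal(init.areas, uniform_state.areas)
        assert init.nominal_year == 2000

    def test_backcast_then_forward_recovers_generated_state(self, growth, catalog):
        from hfmsim import sample_age_distribution

        for spec in catalog:
            dist = sample_age_distribution(spec)
            state = initialize_state(dist, BACKCAST, backcast_steps=4)
            for _ in range(4):
                state = step_forward(state, growth).next_state
            np.testing.assert_array_equal(state.areas, dist.areas)

    def test_backcast_of_uniform_is_uniform(self, uniform_state):
        init = initialize_state(uniform_state, BACKCAST)
        np.testing.assert_array_equal(init.areas, uniform_state.areas)

    def test_unknown_mode_rejected(self, uniform_state):
        with pytest.raises(ValueError, match="mode"):
            initialize_state(uniform_state, "hindcast")


class TestTrajectory:
    def test_period_structure(self, growth, uniform_state):
        traj = run_trajectory(uniform_state, n_periods=13, params=growth)
        assert len(traj.states) == 14
        assert traj.n_periods == 13
        assert traj.period_years[0] == 2000 and traj.period_years[-1] == 2060
        assert np.all(np.diff(traj.period_years) == 5)

    def test_uniform_harvest_is_constant(self, growth, uniform_state):
        traj = run_trajectory(uniform_state, n_periods=13, params=growth)
        assert np.allclose(traj.harvested_volume, traj.harvested_volume[0])
        assert np.allclose(traj.stock_pre_harvest, traj.stock_pre_harvest[0])

    def test_rotation_length_trajectory_closes(self, growth):
        for st_ in random_states(5, seed=9):
            traj = run_trajectory(st_, n_periods=24, params=growth)
            np.testing.assert_array_equal(traj.states[-1].areas, st_.areas)

    def test_zero_periods_rejected(self, uniform_state):
        with pytest.raises(ValueError):
            run_trajectory(uniform_state, n_periods=0)

    def test_stock_bounds(self, growth):
        for st_ in random_states(10, seed=13):
            traj = run_trajectory(st_, n_periods=13, params=growth)
            assert np.all(traj.stock_pre_harvest >= 0)
            assert np.all(traj.stock_pre_harvest <= st_.total_area * growth.vmax + 1e-9)

    def test_frame_has_one_row_per_period(self, growth, uniform_state):
        traj = run_trajectory(uniform_state, n_periods=13, params=growth)
        frame = traj.to_frame()
        assert len(frame) == 13
        states = traj.states_frame()
        assert len(states) == 14 and states["year_start"].iloc[-1] == 2065
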
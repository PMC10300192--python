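"""Unit and property tests for the core growth/death/consumption model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glucodyn.model import (
    BystanderRelation,
    GlobalParams,
    InhibitionParams,
    ModelState,
    Well,
    accessible_glucose,
    bystander_rate,
    cells_to_confluence,
    confluence_to_cells,
    default_time_grid,
    rhs,
    simulate_batch,
    simulate_forward,
    state_functions,
)

from helpers import logistic, rk4_simulate


class TestStateFunctions:
    def test_hand_evaluated_value(self):
        # G_acs == G_min makes the glucose factor exactly 1/2
        s_p, s_d = state_functions(0.01, 1.0, 0.01)
        assert s_d == pytest.approx(0.5 * math.tanh(1.0), abs=1e-12)
        assert s_p == pytest.approx(1.0 - 0.5 * math.tanh(1.0), abs=1e-12)

    def test_zero_glucose_long_time_limit(self):
        s_p, s_d = state_functions(0.0, 50.0, 0.01)
        assert s_d == pytest.approx(1.0, abs=1e-12)
        assert s_p == pytest.approx(0.0, abs=1e-12)

    @given(g=st.floats(0, 100), t=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_complement_and_range(self, g, t):
        s_p, s_d = state_functions(g, t, 0.01)
        assert s_p + s_d == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= s_d <= 1.0

    @pytest.mark.parametrize("g,t,gmin", [(-1, 1, 0.01), (1, -1, 0.01), (1, 1, 0)])
    def test_domain_errors(self, g, t, gmin):
        with pytest.raises(ValueError):
            state_functions(g, t, gmin)


class TestAccessibleGlucose:
    @pytest.mark.parametrize("g,n,gin,expected", [
        (5.0, 40000, 0.0, 5.0),              # no treatment: G_acs == G_total
        (10.0, 0, 4.55e-4, 10.0),            # empty well
        (10.0, 50000, 4.55e-4, 10.0 / 23.75),
    ])
    def test_examples(self, g, n, gin, expected):
        assert accessible_glucose(g, n, gin) == pytest.approx(expected, rel=1e-12)

    @given(g=st.floats(0, 20), n=st.floats(0, 1e5), gin=st.floats(0, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_total(self, g, n, gin):
        g_acs = accessible_glucose(g, n, gin)
        assert g_acs <= g + 1e-12
        if gin * n == 0:
            assert g_acs == pytest.approx(g, abs=1e-12)
        elif g > 0 and gin * n > 1e-12:
            assert g_acs < g

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            accessible_glucose(-1.0, 10.0, 0.0)


class TestBystanderRate:
    def test_limits_and_hand_value(self):
        rel = BystanderRelation(0.1, 0.5, 0.01)
        assert bystander_rate(0.0, rel) == pytest.approx(0.11)
        assert bystander_rate(1e6, rel) == pytest.approx(0.01)
        assert bystander_rate(2.0, rel) == pytest.approx(0.1 * math.exp(-1.0) + 0.01, rel=1e-12)

    def test_monotone_non_increasing(self):
        rel = BystanderRelation(0.8, 0.4, 0.03)
        g = np.linspace(0, 10, 50)
        k = rel.rate(g)
        assert np.all(np.diff(k) <= 1e-15)

    def test_negative_coefficients_rejected(self):
        with pytest.raises(ValueError):
            BystanderRelation(-0.1, 0.5, 0.01)


class TestConversions:
    def test_round_trip_and_examples(self, params):
        assert confluence_to_cells(100.0, params.theta) == pytest.approx(8e4)
        assert confluence_to_cells(0.0, params.theta) == 0.0
        assert confluence_to_cells(50.0, params.theta) == pytest.approx(4e4)
        x = 37.25
        assert cells_to_confluence(confluence_to_cells(x, params.theta), params.theta) \
            == pytest.approx(x, rel=1e-12)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            confluence_to_cells(101.0, params.theta)
        with pytest.raises(ValueError):
            cells_to_confluence(params.theta * 1.01, params.theta)


class TestRhs:
    def test_no_live_cells_freezes_everything(self, params):
        d = rhs(ModelState(N=0.0, D=500.0, G_total=5.0, t=1.0), params, 0.3, 1e-4)
        assert d == (0.0, 0.0, 0.0)

    def test_no_dead_cells_no_bystander_death(self, params):
        state = ModelState(N=1e4, D=0.0, G_total=5.0, t=1.0)
        dn, dd, dg = rhs(state, params, 5.0, 0.0)  # huge k_bys must be inert
        s_p, s_d = state_functions(5.0, 1.0, params.G_min)
        assert dd == pytest.approx(params.k_d * 1e4 * s_d, rel=1e-12)

    def test_pure_consumption(self):
        p = GlobalParams(k_p=1e-12, k_d=1e-12, v=4.48e-5)
        state = ModelState(N=2e4, D=0.0, G_total=5.0, t=0.5)
        dn, dd, dg = rhs(state, p, 0.0, 0.0)
        assert dn == pytest.approx(0.0, abs=1e-4)
        assert dd == pytest.approx(0.0, abs=1e-4)
        assert dg == pytest.approx(-4.48e-5 * 2e4 * 5.0 / 5.5, rel=1e-9)

    def test_death_terms_have_opposite_signs(self, params):
        state = ModelState(N=3e4, D=1e3, G_total=0.1, t=2.0)
        dn, dd, dg = rhs(state, params, 0.5, 0.0)
        assert dd > 0
        assert dg < 0

    def test_non_finite_state_rejected(self):
        with pytest.raises(ValueError):
            ModelState(N=float("nan"), D=0.0, G_total=1.0, t=0.0)


class TestSimulateForward:
    def test_zero_rates_constant_trajectories(self):
        p = GlobalParams(k_p=1e-15, k_d=1e-15, v=1e-18)
        well = Well("w", 0.5, 5.0, 0.0, initial_dead_confluence=0.05)
        sim = simulate_forward(well, p, 0.0, 0.0)
        assert np.allclose(sim.course.live, sim.course.live[0], atol=1e-6)
        assert np.allclose(sim.course.dead, sim.course.dead[0], atol=1e-6)

    def test_agrees_with_fixed_step_rk4(self, params):
        well = Well("w", 0.45, 2.0, 0.0, initial_dead_confluence=0.02)
        k_bys, g_in = 0.4, 0.0
        sim = simulate_forward(well, params, k_bys, g_in)
        _, n_ref, d_ref, _ = rk4_simulate(
            0.45 * params.theta, 0.02 * params.theta, 2.0,
            params.k_p, params.k_d, params.v, params.theta, params.G_star,
            params.G_min, k_bys, g_in, dt=5e-4)
        live_ref = 100.0 * np.array(n_ref) / params.theta
        dead_ref = 100.0 * np.array(d_ref) / params.theta
        assert np.abs(sim.course.live - live_ref).max() < 1e-3
        assert np.abs(sim.course.dead - dead_ref).max() < 1e-3

    def test_logistic_closed_form_limit(self, params):
        # abundant glucose, no death channels: logistic growth
        well = Well("w", 0.10, 10.0, 0.0)
        sim = simulate_forward(well, params, 0.0, 0.0)
        expected = np.array([logistic(0.10 * params.theta, params.k_p, params.theta, t)
                             for t in sim.course.times])
        rel_err = np.abs(sim.n_cells - expected) / expected
        assert rel_err.max() < 0.02

    @given(
        conf=st.floats(0.1, 0.8),
        g0=st.floats(0.0, 10.0),
        k_bys=st.floats(0.0, 0.8),
        g_in=st.floats(0.0, 1e-3),
    )
    @settings(max_examples=15, deadline=None)
    def test_trajectory_invariants(self, params, conf, g0, k_bys, g_in):
        well = Well("w", conf, g0, 0.0, initial_dead_confluence=0.02)
        sim = simulate_forward(well, params, k_bys, g_in, rtol=1e-8)
        assert np.all(sim.n_cells >= 0) and np.all(sim.d_cells >= 0) and np.all(sim.g_total >= 0)
        assert np.all(np.diff(sim.d_cells) >= -1e-6)       # dead cells accumulate
        assert np.all(np.diff(sim.g_total) <= 1e-9)        # glucose only consumed
        assert np.all(sim.g_acs <= sim.g_total + 1e-12)

    def test_gin_zero_reduces_to_untreated_model(self, params):
        treated = Well("t", 0.5, 5.0, dose=10.0, initial_dead_confluence=0.02)
        untreated = Well("u", 0.5, 5.0, dose=0.0, initial_dead_confluence=0.02)
        sim_t = simulate_forward(treated, params, 0.3, 0.0)
        sim_u = simulate_forward(untreated, params, 0.3, 0.0)
        assert np.array_equal(sim_t.course.live, sim_u.course.live)
        assert np.array_equal(sim_t.course.dead, sim_u.course.dead)

    def test_monotone_dose_effect_without_depletion(self, params):
        # Stronger inhibition lowers accessible glucose and hence growth.
        # This ordering is only guaranteed while glucose is not depleted:
        # inhibited wells also consume more slowly, so after an untreated
        # well runs out, the treated one can overtake it.  A large glucose
        # reservoir and low seeding keep every arm in the non-depleting
        # regime over the 4-day window.
        well = Well("w", 0.30, 10.0, 0.0, initial_dead_confluence=0.02)
        prev_live, prev_dead = None, None
        for g_in in (0.0, 1e-4, 3e-4, 1e-3):
            sim = simulate_forward(well, params, 0.3, g_in)
            assert sim.g_total[-1] > 1.0  # regime check: no depletion
            if prev_live is not None:
                assert np.all(sim.course.live <= prev_live + 1e-6)
                assert sim.course.dead[-1] >= prev_dead - 1e-6
            prev_live, prev_dead = sim.course.live, sim.course.dead[-1]

    def test_batch_matches_single_well(self, params):
        wells = [Well(f"w{i}", c, g, 0.0, initial_dead_confluence=0.02)
                 for i, (c, g) in enumerate([(0.4, 0.5), (0.65, 5.0), (0.8, 10.0)])]
        kb = np.array([0.5, 0.2, 0.05])
        gin = np.array([0.0, 3e-4, 4.5e-4])
        N, D, G = simulate_batch(
            np.array([w.initial_confluence * params.theta for w in wells]),
            np.array([w.initial_dead_confluence * params.theta for w in wells]),
            np.array([w.G0 for w in wells]), kb, gin, params, rtol=1e-8)
        for i, w in enumerate(wells):
            sim = simulate_forward(w, params, kb[i], gin[i], rtol=1e-8)
            assert np.abs(N[i] - sim.n_cells).max() < 1e-2   # cells; solvers differ
            assert np.abs(D[i] - sim.d_cells).max() < 1e-2


class TestInhibitionParams:
    def test_dose_zero_identity_and_lookup(self):
        inh = InhibitionParams.default()
        assert inh.for_dose(0.0) == 0.0
        assert inh.for_dose(2.0) == pytest.approx(3.02e-4)
        with pytest.raises(KeyError):
            inh.for_dose(7.0)

    def test_dose_zero_must_map_to_zero(self):
        with pytest.raises(ValueError):
            InhibitionParams({0.0: 1e-4})
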
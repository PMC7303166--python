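"""Payoffs, fitness, environment feedback, and the Moran update."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogcontrol.dynamics import (
    Params,
    PopulationState,
    Scenario,
    contact_mean,
    fitness,
    moran_step,
    payoff_automatic,
    payoff_controlled,
    select_teacher,
    teacher_probabilities,
    update_environment,
)
from cogcontrol.topology import make_complete, make_ring

ANCHOR = Params(c=0.5, w=-0.15, s=10.0, u=0.01, tau_p=1.0)


class TestParamsAndScenario:
    @pytest.mark.parametrize("kw", [
        {"u": -0.1}, {"u": 1.5}, {"s": -1.0}, {"tau_p": 0.5}, {"c": float("nan")},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            Params(**kw)

    def test_out_of_range_payoff_parameters_warn(self):
        with pytest.warns(UserWarning):
            Params(c=2.0, w=-0.15)

    def test_eight_distinct_scenarios(self):
        scens = Scenario.all_scenarios()
        assert len(set(scens)) == 8
        assert Scenario.fully_local() in scens
        assert Scenario.fully_global() in scens

    def test_from_string_and_tag(self):
        s = Scenario.from_string("local,global,local")
        assert (s.learning, s.contact, s.environment) == ("local", "global", "local")
        assert s.tag == "LGL"
        with pytest.raises(ValueError):
            Scenario.from_string("local,global")
        with pytest.raises(ValueError):
            Scenario(learning="both")


class TestPayoffs:
    @pytest.mark.parametrize("c, w, xbar, expected", [
        (0.5, -0.15, 1.0, 0.5),
        (0.5, -0.15, 0.0, 0.35),
        (0.0, 0.0, 0.3, 1.0),
    ])
    def test_controlled(self, c, w, xbar, expected):
        assert payoff_controlled(Params(c=c, w=w), xbar) == pytest.approx(expected)

    @pytest.mark.parametrize("p, expected", [(0.0, 1.0), (1.0, 0.0), (0.99, 0.01)])
    def test_automatic(self, p, expected):
        assert payoff_automatic(p) == pytest.approx(expected)


class TestContactMean:
    def test_homogeneous_population_any_scope(self):
        top = make_ring(100, 2)
        for scen in (Scenario(contact="local"), Scenario(contact="global")):
            state = PopulationState.initial(100, scen, x0=0.01)
            assert contact_mean(state, top, scen, 17) == pytest.approx(0.01)

    def test_local_impulse_on_ring(self):
        top = make_ring(100, 2)
        scen = Scenario(contact="local")
        x = np.zeros(100)
        x[0] = 1.0
        state = PopulationState(x=x, p=0.5)
        assert contact_mean(state, top, scen, 0) == pytest.approx(1 / 3)
        assert contact_mean(state, top, scen, 50) == pytest.approx(0.0)

    def test_scopes_coincide_on_complete_graph(self):
        top = make_complete(10)
        rng = np.random.default_rng(1)
        x = rng.random(10)
        s_local = PopulationState(x=x, p=0.5)
        for i in range(10):
            local = contact_mean(s_local, top, Scenario(contact="local"), i)
            glob = contact_mean(s_local, top, Scenario(contact="global"), i)
            assert local == pytest.approx(glob)


class TestFitness:
    def test_fully_controlled_agent(self):
        # x_i = 1 with everyone controlled: f = 1 - c + w*(1-1) = 0.5
        top = make_complete(4)
        scen = Scenario.fully_global()
        state = PopulationState(x=np.ones(4), p=0.2)
        assert fitness(state, top, scen, ANCHOR, 0) == pytest.approx(0.5)

    def test_fully_automatic_in_perfect_environment(self):
        top = make_ring(10, 2)
        state = PopulationState(x=np.zeros(10), p=0.0)
        assert fitness(state, top, Scenario(), ANCHOR, 3) == pytest.approx(1.0)

    def test_mixed_strategy_hand_value(self):
        # x=0.5, c=0.5, w=0, p=0.5 -> 0.5*0.5 + 0.5*0.5 = 0.5
        top = make_complete(2)
        params = Params(c=0.5, w=0.0)
        state = PopulationState(x=np.array([0.5, 0.5]), p=0.5)
        assert fitness(state, top, Scenario.fully_global(), params, 0) == pytest.approx(0.5)

    def test_fitness_bounded_by_the_two_payoffs(self):
        # f is a convex combination of pi_C and pi_A
        top = make_ring(20, 4)
        scen = Scenario()
        rng = np.random.default_rng(2)
        x = rng.random(20)
        state = PopulationState(x=x, p=rng.random(20))
        for i in range(20):
            m = contact_mean(state, top, scen, i)
            pi_c = payoff_controlled(ANCHOR, m)
            pi_a = payoff_automatic(state.p[i])
            f = fitness(state, top, scen, ANCHOR, i)
            assert min(pi_c, pi_a) - 1e-12 <= f <= max(pi_c, pi_a) + 1e-12


class TestEnvironmentUpdate:
    def test_no_lag_recovers_instantaneous_feedback(self):
        top = make_ring(10, 2)
        scen = Scenario(environment="global")
        rng = np.random.default_rng(3)
        state = PopulationState(x=rng.random(10), p=0.37)
        xbar = state.x.mean()
        update_environment(state, top, scen, Params(tau_p=1.0))
        assert state.p == pytest.approx(1.0 - xbar)

    def test_hand_computed_lagged_step(self):
        # p=0.3, <x>=0.2, tau=2 -> 0.3 + (0.8 - 0.3)/2 = 0.55
        top = make_complete(5)
        scen = Scenario(environment="global")
        state = PopulationState(x=np.full(5, 0.2), p=0.3)
        update_environment(state, top, scen, Params(tau_p=2.0))
        assert state.p == pytest.approx(0.55)

    def test_local_update_uses_including_self_neighbourhood(self):
        top = make_ring(4, 2)
        scen = Scenario(environment="local")
        x = np.array([1.0, 0.0, 0.0, 0.0])
        state = PopulationState(x=x, p=np.full(4, 0.5))
        update_environment(state, top, scen, Params(tau_p=1.0))
        # agent 2's neighbourhood {1,2,3} has mean 0 -> p=1; agent 0's {3,0,1} mean 1/3
        assert state.p[2] == pytest.approx(1.0)
        assert state.p[0] == pytest.approx(1.0 - 1 / 3)

    @pytest.mark.parametrize("tau", [1.0, 2.0, 10.0])
    def test_monotone_convergence_to_fixed_point(self, tau):
        top = make_complete(6)
        scen = Scenario(environment="global")
        xbar = 0.3
        state = PopulationState(x=np.full(6, xbar), p=0.05)
        target = 1.0 - xbar
        prev_gap = abs(state.p - target)
        for _ in range(200):
            update_environment(state, top, scen, Params(tau_p=tau))
            gap = abs(state.p - target)
            assert gap <= prev_gap + 1e-12
            prev_gap = gap
        assert state.p == pytest.approx(target, abs=1e-6 if tau < 5 else 1e-3)

    @given(tau=st.floats(1.0, 1e4), p0=st.floats(0, 1), xbar=st.floats(0, 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_environment_stays_in_unit_interval(self, tau, p0, xbar):
        top = make_complete(3)
        scen = Scenario(environment="global")
        state = PopulationState(x=np.full(3, xbar), p=p0)
        for _ in range(5):
            update_environment(state, top, scen, Params(tau_p=tau))
            assert 0.0 <= state.p <= 1.0


class TestTeacherSelection:
    def test_neutral_selection_is_uniform(self):
        probs = teacher_probabilities([0.1, 0.9, 0.5, 0.2], s=0.0)
        assert probs == pytest.approx(np.full(4, 0.25))

    def test_closed_form_two_candidates(self):
        # fitnesses (1.0, 0.5), s=10: P(first) = e^10 / (e^10 + e^5)
        probs = teacher_probabilities([1.0, 0.5], s=10.0)
        expected = np.exp(10) / (np.exp(10) + np.exp(5))
        assert probs[0] == pytest.approx(expected)
        assert probs.sum() == pytest.approx(1.0)

    def test_shift_invariance_and_overflow_safety(self):
        f = np.array([0.2, 0.8, 0.5])
        base = teacher_probabilities(f, s=10.0)
        shifted = teacher_probabilities(f + 1000.0, s=10.0)
        assert shifted == pytest.approx(base)
        assert np.isfinite(teacher_probabilities([1e6, 1e6 - 1], s=10.0)).all()

    def test_single_candidate_always_chosen(self):
        rng = np.random.default_rng(0)
        assert select_teacher([0.3], [7], s=10.0, rng=rng) == 7

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_teacher([], [], s=1.0, rng=np.random.default_rng(0))

    def test_empirical_frequencies_match_softmax(self):
        rng = np.random.default_rng(123)
        cands = np.array([4, 9, 2])
        f = np.array([1.0, 0.8, 0.6])
        draws = [select_teacher(f, cands, s=5.0, rng=rng) for _ in range(20_000)]
        counts = {c: draws.count(c) / len(draws) for c in cands}
        expected = teacher_probabilities(f, s=5.0)
        for c, e in zip(cands, expected):
            assert counts[int(c)] == pytest.approx(e, abs=0.015)


class TestMoranStep:
    def _state(self, n, scen, rng):
        return PopulationState(x=rng.random(n), p=0.5 if scen.environment == "global"
                               else rng.random(n))

    def test_pure_mutation_draws_uniform_strategy(self):
        top = make_ring(10, 2)
        scen = Scenario()
        params = Params(u=1.0)
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(2000):
            state = PopulationState(x=np.zeros(10), p=np.full(10, 0.5))
            moran_step(state, top, scen, params, rng)
            vals.append(state.x.max())  # the single mutated entry
        vals = np.asarray(vals)
        assert vals.mean() == pytest.approx(0.5, abs=0.03)
        assert vals.min() >= 0 and vals.max() <= 1

    def test_homogeneous_population_fixed_without_mutation(self):
        top = make_ring(12, 2)
        params = Params(u=0.0)
        for scen in Scenario.all_scenarios():
            rng = np.random.default_rng(6)
            state = PopulationState.initial(12, scen, x0=0.4)
            for _ in range(50):
                moran_step(state, top, scen, params, rng)
            assert (state.x == 0.4).all()

    def test_at_most_one_entry_changes_and_counter_increments(self):
        top = make_ring(30, 4)
        scen = Scenario.fully_local()
        rng = np.random.default_rng(7)
        state = self._state(30, scen, rng)
        for step in range(100):
            before = state.x.copy()
            moran_step(state, top, scen, ANCHOR, rng)
            assert (state.x != before).sum() <= 1
            assert state.t == step + 1

    def test_neutral_drift_copies_uniform_neighbour(self):
        # s=0, u=0 on a ring: teacher is a uniformly random neighbour
        k = 4
        top = make_ring(20, k)
        scen = Scenario.fully_local()
        params = Params(s=0.0, u=0.0)
        rng = np.random.default_rng(8)
        x0 = np.arange(20, dtype=float) / 20  # unique values identify the teacher
        offsets = []
        for _ in range(8000):
            state = PopulationState(x=x0.copy(), p=np.full(20, 0.5))
            moran_step(state, top, scen, params, rng)
            (changed,) = np.where(state.x != x0)
            if changed.size:  # learner copied a different-valued neighbour
                learner = changed[0]
                teacher = int(state.x[learner] * 20)
                offsets.append((teacher - learner) % 20)
        freqs = {off: offsets.count(off) / len(offsets) for off in (1, 2, 18, 19)}
        for off, f in freqs.items():
            assert f == pytest.approx(1 / k, abs=0.03)
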
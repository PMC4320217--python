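"""State machine, probability models, chains, traversability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antbridge.behavior import (Ant, AntState, Caste,
                                ChainEntryModel, ChainExitModel, LeaveModel,
                                ModelConfigurationError, is_traversable,
                                pheromone_guided_move, prob_enter_chain,
                                prob_leave_chain_lioni,
                                prob_leave_chain_pheromone, rebuild_chains,
                                return_step, search_step)
from antbridge.engine import SimState
from antbridge.environment import (FeedingSpot, GridEnvironment, Rect,
                                   build_default_environment)


def make_world(ants, *, width=20, height=20, bars=None, nest=Rect(0, 3, 0, 19),
               spots=(), seed=7, behavior=None):
    env = GridEnvironment(width, height, bars or {}, nest, list(spots))
    rng = np.random.default_rng(seed)
    return SimState(env, ants, rng, behavior=behavior)


class TestEntryProbability:
    def test_at_zero_chain_size_equals_spontaneous_term(self):
        m = ChainEntryModel(Ce0=0.1, Ce1=0.6, Ce2=4)
        assert prob_enter_chain(m, 0) == pytest.approx(0.1)

    def test_plateau_is_sum_of_terms(self):
        m = ChainEntryModel(Ce0=0.1, Ce1=0.6, Ce2=4)
        assert prob_enter_chain(m, 10 ** 9) == pytest.approx(0.7, rel=1e-6)

    def test_worked_value(self):
        m = ChainEntryModel(Ce0=0.1, Ce1=0.6, Ce2=4)
        assert prob_enter_chain(m, 4) == pytest.approx(0.4)

    def test_plateau_above_one_rejected(self):
        with pytest.raises(ModelConfigurationError):
            ChainEntryModel(Ce0=0.5, Ce1=0.6)


class TestExitProbability:
    def test_limit_is_baseline(self):
        m = ChainExitModel(Cs0=0.05, Cs1=0.9, Cs2=1, nu=2)
        assert prob_leave_chain_lioni(m, 10 ** 6) == pytest.approx(0.05, abs=1e-9)

    def test_worked_value(self):
        m = ChainExitModel(Cs0=0.05, Cs1=0.9, Cs2=1, nu=2)
        assert prob_leave_chain_lioni(m, 3) == pytest.approx(0.14)

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ModelConfigurationError):
            ChainExitModel(Cs0=0.5, Cs1=0.9, Cs2=1.0)


class TestPheromoneLeaveProbability:
    def test_alone_leaves_at_spontaneous_rate(self):
        m = LeaveModel()  # a = 0.4 default
        for level in (0.0, 1.0, 100.0):
            assert prob_leave_chain_pheromone(m, 0, level) == pytest.approx(0.4)

    def test_saturated_coupling_worked_value(self):
        m = LeaveModel(a=0.4, eta=1.0, eps=1.0)  # b saturates at 1
        assert prob_leave_chain_pheromone(m, 1, 0.0) == pytest.approx(0.2)

    def test_coupling_caps_at_one(self):
        m = LeaveModel(a=1.0, eta=5.0, eps=0.0)
        p_huge = prob_leave_chain_pheromone(m, 2, 1e9)
        assert p_huge == pytest.approx(1.0 / (1 + 4))  # b clamped to 1

    def test_monotone_in_pheromone(self):
        m = LeaveModel()
        levels = [0.0, 0.5, 2.0, 10.0, 1e4]
        ps = [prob_leave_chain_pheromone(m, 3, lv) for lv in levels]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


@settings(max_examples=200, deadline=None)
@given(xi=st.integers(0, 10_000),
       ce0=st.floats(0, 0.4), ce1=st.floats(0, 0.6), ce2=st.floats(0.1, 50),
       cs0=st.floats(0, 0.1), cs1=st.floats(0, 0.5), cs2=st.floats(1, 50),
       nu=st.floats(0.1, 4), a=st.floats(0, 1),
       eta=st.floats(0, 2), eps=st.floats(0, 1), level=st.floats(0, 1e6))
def test_probabilities_stay_in_unit_interval_and_are_monotone(
        xi, ce0, ce1, ce2, cs0, cs1, cs2, nu, a, eta, eps, level):
    em = ChainEntryModel(ce0, ce1, ce2)
    xm = ChainExitModel(cs0, cs1, cs2, nu)
    lm = LeaveModel(a, eta, eps)
    pe = prob_enter_chain(em, xi)
    pl = prob_leave_chain_lioni(xm, xi)
    pp = prob_leave_chain_pheromone(lm, xi, level)
    assert 0.0 <= pe <= 1.0 and 0.0 <= pl <= 1.0 and 0.0 <= pp <= 1.0
    assert prob_enter_chain(em, xi + 1) >= pe
    assert prob_leave_chain_lioni(xm, xi + 1) <= pl
    assert prob_leave_chain_pheromone(lm, xi + 1, level) <= pp


class TestGuidedMove:
    def test_single_candidate_always_chosen(self, rng):
        ant = Ant(0, Caste.MINOR, (5, 5))
        assert pheromone_guided_move(ant, [(4, 4)], [0.0], rng) == (4, 4)

    def test_zero_levels_fall_back_to_uniform(self, rng):
        ant = Ant(0, Caste.MINOR, (5, 5))
        cands = [(4, 4), (5, 4), (6, 4)]
        picks = [pheromone_guided_move(ant, cands, [0, 0, 0], rng)
                 for _ in range(3000)]
        freqs = [picks.count(c) / 3000 for c in cands]
        assert all(abs(f - 1 / 3) < 0.05 for f in freqs)

    def test_choice_proportional_to_level(self, rng):
        ant = Ant(0, Caste.MINOR, (5, 5))
        cands = [(4, 4), (5, 4)]
        picks = [pheromone_guided_move(ant, cands, [3.0, 1.0], rng)
                 for _ in range(100_000)]
        f = picks.count((4, 4)) / 100_000
        assert f == pytest.approx(0.75, abs=0.01)


class TestChains:
    def test_no_altruists_no_chains(self):
        ants = [Ant(0, Caste.MINOR, (5, 5))]
        assert rebuild_chains(ants, build_default_environment()) == []

    def test_diagonal_line_is_one_chain(self, default_env):
        ants = [Ant(i, Caste.MINOR, (30 + i, 40 + i), state=AntState.ALTRUISM)
                for i in range(3)]
        chains = rebuild_chains(ants, default_env)
        assert len(chains) == 1 and chains[0].size == 3
        assert all(a.chain_id == chains[0].id for a in ants)

    def test_separated_members_form_separate_chains(self, default_env):
        ants = [Ant(0, Caste.MINOR, (30, 40), state=AntState.ALTRUISM),
                Ant(1, Caste.MINOR, (30, 44), state=AntState.ALTRUISM)]
        chains = rebuild_chains(ants, default_env)
        assert [c.size for c in chains] == [1, 1]

    def test_matches_brute_force_component_labelling(self, rng, default_env):
        cells = [(30 + int(rng.integers(3)), 30 + int(rng.integers(40)))
                 for _ in range(25)]
        cells = list(dict.fromkeys(cells))
        ants = [Ant(i, Caste.MINOR, c, state=AntState.ALTRUISM)
                for i, c in enumerate(cells)]
        chains = rebuild_chains(ants, default_env)
        # oracle: repeated pairwise merging
        groups = [{c} for c in cells]
        merged = True
        while merged:
            merged = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1
                           for a in groups[i] for b in groups[j]):
                        groups[i] |= groups.pop(j)
                        merged = True
                        break
                if merged:
                    break
        assert sorted(c.size for c in chains) == sorted(len(g) for g in groups)


class TestTraversability:
    def _state(self):
        bars = {"d": Rect(8, 10, 0, 19)}
        ants = [Ant(0, Caste.MINOR, (9, 5), state=AntState.ALTRUISM),
                Ant(1, Caste.MINOR, (4, 4))]
        return make_world(ants, bars=bars)

    def test_empty_ditch_cell_blocked(self):
        state = self._state()
        assert not is_traversable(state, (9, 10))

    def test_bridged_ditch_cell_open(self):
        state = self._state()
        assert is_traversable(state, (9, 5))

    def test_occupied_open_cell_blocked(self):
        state = self._state()
        assert not is_traversable(state, (4, 4))
        assert is_traversable(state, (5, 5))

    def test_out_of_bounds_blocked(self):
        state = self._state()
        assert not is_traversable(state, (-1, 0))


class TestSearchState:
    def test_adjacent_food_triggers_pickup_and_return(self, rng):
        spot = FeedingSpot("A", Rect(6, 7, 5, 6), 5)
        ants = [Ant(0, Caste.MINOR, (5, 5))]
        state = make_world(ants, spots=[spot])
        search_step(state, ants[0], state.behavior, state.rng)
        assert ants[0].state is AntState.RETURN
        assert ants[0].carrying and ants[0].cargo_from == "A"
        assert spot.remaining_food == 4

    def test_crowded_ant_next_to_ditch_enters_altruism(self):
        bars = {"d": Rect(8, 10, 0, 19)}
        ants = [Ant(0, Caste.MINOR, (7, 5)), Ant(1, Caste.MINOR, (6, 5))]
        state = make_world(ants, bars=bars)
        search_step(state, ants[0], state.behavior, state.rng)
        assert ants[0].state is AntState.ALTRUISM
        assert state.env.is_ditch[ants[0].pos[1], ants[0].pos[0]]
        assert state.chain_occ[ants[0].pos[1], ants[0].pos[0]] == 0

    def test_lone_ant_never_enters_ditch(self):
        bars = {"d": Rect(8, 10, 0, 19)}
        ants = [Ant(0, Caste.MINOR, (7, 5))]
        state = make_world(ants, bars=bars)
        for _ in range(300):
            search_step(state, ants[0], state.behavior, state.rng)
            assert ants[0].state is AntState.SEARCH
            assert not state.env.is_ditch[ants[0].pos[1], ants[0].pos[0]]

    def test_free_move_lands_on_neighbour(self, rng):
        ants = [Ant(0, Caste.MINOR, (10, 10))]
        state = make_world(ants)
        search_step(state, ants[0], state.behavior, state.rng)
        dx = abs(ants[0].pos[0] - 10)
        dy = abs(ants[0].pos[1] - 10)
        assert max(dx, dy) <= 1


class TestReturnState:
    def test_delivery_in_nest(self):
        ants = [Ant(0, Caste.MINOR, (2, 10), state=AntState.RETURN,
                    carrying=True, cargo_from="A")]
        state = make_world(ants)
        state.delivered = {"A": 0}
        return_step(state, ants[0], state.behavior, state.rng)
        assert ants[0].state is AntState.SEARCH and not ants[0].carrying
        assert state.delivered["A"] == 1

    def test_moves_strictly_closer_to_nest(self):
        ants = [Ant(0, Caste.MINOR, (15, 10), state=AntState.RETURN,
                    carrying=True, cargo_from="A")]
        state = make_world(ants)
        for _ in range(25):
            if state.env.nest.contains(ants[0].pos):
                break
            before = ants[0].pos
            return_step(state, ants[0], state.behavior, state.rng)
            assert ants[0].pos[0] < before[0] or state.env.nest.contains(before)
        assert state.env.nest.contains(ants[0].pos) or ants[0].pos[0] <= 4

    def test_fully_blocked_carrier_waits(self):
        ants = [Ant(0, Caste.MINOR, (10, 0), state=AntState.RETURN,
                    carrying=True, cargo_from="A")]
        blockers = [Ant(i + 1, Caste.MINOR, p) for i, p in
                    enumerate([(9, 0), (11, 0), (9, 1), (10, 1), (11, 1)])]
        state = make_world(ants + blockers)
        return_step(state, ants[0], state.behavior, state.rng)
        assert ants[0].pos == (10, 0)
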
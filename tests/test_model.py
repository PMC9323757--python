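"""Unit tests of the dynamics engine: phases, step composition, run driver."""

import numpy as np
import pytest

from ringmarch import (
    ConfigError,
    ModelConfig,
    RandomDecisions,
    SwarmState,
    apply_conflict_outcomes,
    detect_conflicts,
    front_locust,
    horizontal_phase,
    init_random_configuration,
    run_until_stable,
    step,
    vertical_eligibility,
    vertical_phase,
)

from conftest import seeded_rng, track_state


class TestModelConfig:
    def test_density_resolution_applies_two_per_track_floor(self):
        cfg = ModelConfig(n=30, k=5, density=0.1)
        assert cfg.resolved_m == 15  # max(10, round(0.1 * 150))
        cfg_low = ModelConfig(n=30, k=5, density=0.01)
        assert cfg_low.resolved_m == 10  # floored at 2k

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n=4, k=2, m=9, enforce_two_per_track=False),  # m > n*k
            dict(n=4, k=2, m=3),  # violates the 2-per-track floor
            dict(n=1, k=1, m=1, enforce_two_per_track=False),  # track too short
            dict(n=4, k=1, m=2, density=0.5),  # ambiguous population
            dict(n=4, k=1),  # no population at all
            dict(n=4, k=1, m=2, policy="bernoulli"),  # q missing
            dict(n=4, k=1, m=2, q=0.5),  # q without bernoulli
            dict(n=4, k=1, m=2, p=1.5),  # probability out of range
        ],
    )
    def test_invalid_configurations_are_rejected(self, kw):
        with pytest.raises(ConfigError):
            ModelConfig(**kw)


class TestInitialization:
    def test_sparse_topup_meets_floor_and_nominal_population(self):
        cfg = ModelConfig(n=30, k=5, density=0.1)
        for trial in range(20):
            state = init_random_configuration(cfg, seeded_rng(1, trial))
            assert state.m >= cfg.resolved_m == 15
            for y in range(5):
                assert len(state.track_occupants(y)) >= 2

    def test_full_occupancy_fills_every_cell(self, rng):
        cfg = ModelConfig(n=4, k=2, m=8, enforce_two_per_track=False)
        state = init_random_configuration(cfg, rng)
        assert all(c >= 0 for c in state.grid)

    def test_same_seed_reproduces_the_configuration(self):
        cfg = ModelConfig(n=20, k=3, density=0.3)
        s1 = init_random_configuration(cfg, seeded_rng(7))
        s2 = init_random_configuration(cfg, seeded_rng(7))
        assert s1 == s2

    def test_explicit_m_places_exactly_m(self, rng):
        cfg = ModelConfig(n=10, k=3, m=9)
        state = init_random_configuration(cfg, rng)
        assert state.m == 9
        assert all(len(state.track_occupants(y)) >= 2 for y in range(3))


class TestNeighborhood:
    def test_lone_locust_is_its_own_front_and_back(self):
        state = track_state(8, {3: 1})
        assert front_locust(state, 0, "front") == 0
        assert front_locust(state, 0, "back") == 0

    def test_front_and_back_scan_in_heading_frame(self):
        state = track_state(8, {0: 1, 3: 1})
        assert front_locust(state, 0, "front") == 1
        assert front_locust(state, 0, "back") == 1
        # counterclockwise locust scans against +x for its front
        state2 = track_state(8, {0: -1, 3: 1})
        assert front_locust(state2, 0, "front") == 1

    def test_full_uniform_track_front_is_next_cell(self):
        state = track_state(5, {x: 1 for x in range(5)})
        for x in range(5):
            assert state.xs[front_locust(state, state.occupant(x, 0), "front")] == (x + 1) % 5


class TestConflicts:
    def test_uniform_heading_has_no_conflicts(self):
        assert detect_conflicts(track_state(6, {0: 1, 2: 1, 4: 1})) == []

    def test_facing_adjacent_pair_conflicts(self):
        state = track_state(6, {2: 1, 3: -1})
        assert detect_conflicts(state) == [(0, 1)]

    def test_back_to_back_pair_does_not_conflict(self):
        assert detect_conflicts(track_state(6, {2: -1, 3: 1})) == []

    def test_conflict_pairs_are_disjoint(self, rng):
        from conftest import random_swarm

        for _ in range(50):
            state = random_swarm(rng, 8, 2, int(rng.integers(2, 14)))
            pairs = detect_conflicts(state)
            flat = [i for p in pairs for i in p]
            assert len(flat) == len(set(flat))

    def test_one_of_each_pair_flips(self, decisions):
        state = track_state(6, {2: 1, 3: -1})
        new, report = apply_conflict_outcomes(state, [(0, 1)], decisions)
        assert len(report.flips) == 1
        assert sorted([new.bs[0], new.bs[1]]) in ([-1, -1], [1, 1])

    def test_two_conflicts_yield_independent_uniform_flips(self):
        state = track_state(10, {0: 1, 1: -1, 5: 1, 6: -1})
        rng = seeded_rng(11)
        outcomes = set()
        for _ in range(200):
            new, _ = apply_conflict_outcomes(
                state, [(0, 1), (2, 3)], RandomDecisions(rng)
            )
            outcomes.add((new.bs[0], new.bs[2]))
        assert len(outcomes) == 4  # all four loser combinations occur


class TestHorizontalPhase:
    def test_free_cell_is_taken(self, decisions):
        state = track_state(6, {0: 1})
        new, _ = horizontal_phase(state, [False], decisions)
        assert new.xs[0] == 1

    def test_mutual_block_of_facing_pair(self, decisions):
        state = track_state(6, {0: 1, 1: -1})
        new, report = horizontal_phase(state, [False, False], decisions)
        assert new.xs == [0, 1]
        assert sorted(report.blocked) == [0, 1]

    def test_contested_cell_granted_uniformly(self):
        state = track_state(6, {0: 1, 2: -1})
        rng = seeded_rng(13)
        wins = {0: 0, 1: 0}
        for _ in range(400):
            new, _ = horizontal_phase(state, [False, False], RandomDecisions(rng))
            moved = [i for i in (0, 1) if new.xs[i] == 1]
            assert len(moved) == 1
            wins[moved[0]] += 1
        for i in (0, 1):
            assert 140 <= wins[i] <= 260  # ~Binomial(400, 1/2)

    def test_no_follow_into_vacated_cell(self, decisions):
        state = track_state(6, {0: 1, 1: 1})
        new, _ = horizontal_phase(state, [False, False], decisions)
        assert new.xs[1] == 2  # leader advances
        assert new.xs[0] == 0  # follower refused: cell 1 occupied at step start

    def test_idle_flag_suppresses_movement(self, decisions):
        state = track_state(6, {0: 1})
        new, report = horizontal_phase(state, [True], decisions)
        assert new.xs[0] == 0
        assert report.idled_erratically == [0]


class TestVerticalEligibility:
    def _two_track(self):
        # n=8, k=2: locust 0 at (3,0) cw; its front 1 at (6,0) ccw;
        # target track holds cw locusts at (0,1) and (5,1)
        return SwarmState(8, 2, [3, 6, 0, 5], [0, 0, 1, 1], [1, -1, 1, 1])

    def test_canonical_construction_is_eligible(self):
        state = self._two_track()
        assert vertical_eligibility(state, state, 0, +1)

    def test_adjacent_conflict_fails_condition_one(self):
        state = SwarmState(8, 2, [3, 4, 0, 5], [0, 0, 1, 1], [1, -1, 1, 1])
        assert not vertical_eligibility(state, state, 0, +1)

    def test_same_heading_front_fails_condition_one(self):
        state = SwarmState(8, 2, [3, 6, 0, 5], [0, 0, 1, 1], [1, 1, 1, 1])
        assert not vertical_eligibility(state, state, 0, +1)

    def test_opposite_heading_neighbor_on_target_track_fails_condition_two(self):
        state = SwarmState(8, 2, [3, 6, 0, 5], [0, 0, 1, 1], [1, -1, -1, 1])
        assert not vertical_eligibility(state, state, 0, +1)

    def test_incoming_horizontal_claim_fails_condition_three(self):
        # extra cw locust at (2,1) will attempt to move into E=(3,1)
        state = SwarmState(8, 2, [3, 6, 0, 5, 2], [0, 0, 1, 1, 1], [1, -1, 1, 1, 1])
        assert not vertical_eligibility(state, state, 0, +1)

    def test_edge_track_cannot_leave_the_arena(self):
        state = self._two_track()
        assert not vertical_eligibility(state, state, 0, -1)

    def test_occupied_target_cell_fails(self):
        state = SwarmState(8, 2, [3, 6, 3, 0], [0, 0, 1, 1], [1, -1, 1, 1])
        assert not vertical_eligibility(state, state, 0, +1)


class TestVerticalPhase:
    def test_policy_never_without_erratic_is_inert(self, decisions):
        cfg = ModelConfig(n=8, k=2, m=4, policy="never", enforce_two_per_track=True)
        state = SwarmState(8, 2, [3, 6, 0, 5], [0, 0, 1, 1], [1, -1, 1, 1])
        new, report = vertical_phase(state, state, cfg, [False] * 4, decisions)
        assert new.ys == state.ys and report.switches == []

    def test_eligible_switch_fires_under_policy_always(self, decisions):
        cfg = ModelConfig(n=8, k=2, m=4, policy="always", enforce_two_per_track=True)
        state = SwarmState(8, 2, [3, 6, 0, 5], [0, 0, 1, 1], [1, -1, 1, 1])
        new, report = vertical_phase(state, state, cfg, [False] * 4, decisions)
        assert new.ys[0] == 1
        assert report.switches == [(0, (3, 0), (3, 1), "eligible")]

    def test_erratic_hop_ignores_the_eligibility_conditions(self, decisions):
        cfg = ModelConfig(n=8, k=2, m=2, p=1.0, policy="never", enforce_two_per_track=False)
        state = SwarmState(8, 2, [0, 0], [0, 1], [1, 1])  # uniform: never eligible
        new, report = vertical_phase(state, state, cfg, [True, False], decisions)
        assert report.switches == []  # target cell occupied: hop unavailable
        state2 = SwarmState(8, 2, [0, 4], [0, 1], [1, 1])
        new2, report2 = vertical_phase(state2, state2, cfg, [True, False], decisions)
        assert new2.ys[0] == 1 and report2.switches[0][3] == "erratic"

    def test_erratic_direction_tie_is_uniform(self):
        cfg = ModelConfig(n=4, k=3, m=1, p=1.0, policy="never", enforce_two_per_track=False)
        state = SwarmState(4, 3, [0], [1], [1])
        rng = seeded_rng(17)
        ups = 0
        for _ in range(300):
            new, _ = vertical_phase(state, state, cfg, [True], RandomDecisions(rng))
            assert new.ys[0] in (0, 2)
            ups += new.ys[0] == 2
        assert 100 <= ups <= 200

    def test_single_track_arena_has_no_vertical_moves(self, decisions):
        cfg = ModelConfig(n=6, k=1, m=2, p=1.0, policy="always", enforce_two_per_track=True)
        state = track_state(6, {0: 1, 3: -1})
        new, report = vertical_phase(state, state, cfg, [True, True], decisions)
        assert report.switches == [] and new.ys == [0, 0]


class TestStepAndRun:
    def test_two_cell_opposing_pair_resolves_in_one_step(self):
        cfg = ModelConfig(n=2, k=1, m=2, policy="never", enforce_two_per_track=True)
        state = track_state(2, {0: 1, 1: -1})
        for trial in range(30):
            rec = run_until_stable(
                cfg, seeded_rng(19, trial), stop_mode="local", initial_state=state
            )
            assert rec.tstable == 1 and rec.total_conflicts == 1

    def test_uniform_marching_advances_everyone(self, decisions):
        cfg = ModelConfig(n=8, k=1, m=3, policy="never", enforce_two_per_track=False)
        state = track_state(8, {0: 1, 3: 1, 6: 1})
        new, _ = step(state, cfg, decisions)
        assert sorted(new.xs) == [1, 4, 7]

    def test_full_arena_is_static_but_conflicts_resolve(self, decisions):
        cfg = ModelConfig(n=4, k=1, m=4, policy="never", enforce_two_per_track=False)
        state = track_state(4, {0: 1, 1: -1, 2: 1, 3: -1})
        new, report = step(state, cfg, decisions)
        assert new.xs == state.xs
        assert len(report.conflicts) == 2 and len(report.flips) == 2

    def test_initially_stable_swarm_has_tstable_zero(self):
        cfg = ModelConfig(n=6, k=1, m=2, policy="never", enforce_two_per_track=True)
        rec = run_until_stable(
            cfg, seeded_rng(23), stop_mode="local", initial_state=track_state(6, {0: 1, 3: 1})
        )
        assert rec.tstable == 0 and rec.reached

    def test_opposing_uniform_tracks_never_reach_global_consensus(self):
        cfg = ModelConfig(
            n=6, k=2, m=4, policy="always", enforce_two_per_track=True, max_steps=500
        )
        state = SwarmState(6, 2, [0, 3, 0, 3], [0, 0, 1, 1], [1, 1, -1, -1])
        local = run_until_stable(cfg, seeded_rng(29), stop_mode="local", initial_state=state)
        assert local.tstable == 0
        blocked = run_until_stable(cfg, seeded_rng(29), stop_mode="global", initial_state=state)
        assert not blocked.reached and blocked.tstable == 500

    def test_auto_stop_mode_tracks_the_noise_setting(self):
        quiet = ModelConfig(n=8, k=2, m=4, policy="always")
        noisy = ModelConfig(n=8, k=2, m=4, policy="always", p=0.1)
        state = SwarmState(8, 2, [0, 4, 0, 4], [0, 0, 1, 1], [1, 1, -1, -1])
        rec_quiet = run_until_stable(quiet, seeded_rng(31), stop_mode="auto", initial_state=state)
        assert rec_quiet.reached and rec_quiet.tstable == 0  # local suffices
        rec_noisy = run_until_stable(noisy, seeded_rng(31), stop_mode="auto", initial_state=state)
        assert rec_noisy.tstable > 0  # must go all the way to global consensus
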
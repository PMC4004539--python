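"""Core model: configuration, congruity, payoff, best response, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import (
    all_matrices,
    oracle_best_flips,
    oracle_candidates,
    oracle_payoff,
    random_matrix,
)
from ostrasim.model import (
    AgentParameters,
    ConfigurationError,
    FeelingConfiguration,
    ParameterError,
    Trajectory,
    UpdateSchedule,
    best_response,
    congruity,
    init_random,
    mutual_group,
    payoff,
    run_dynamics,
    step,
)


class TestFeelingConfiguration:
    def test_rejects_non_square(self):
        with pytest.raises(ConfigurationError):
            FeelingConfiguration(np.ones((3, 4)))

    def test_rejects_bad_diagonal(self):
        m = np.ones((3, 3))
        m[1, 1] = -1
        with pytest.raises(ConfigurationError, match=r"\(1, 1\)"):
            FeelingConfiguration(m)

    def test_rejects_non_sign_entries(self):
        m = np.ones((3, 3))
        m[0, 2] = 0
        with pytest.raises(ConfigurationError):
            FeelingConfiguration(m)

    def test_rejects_single_agent(self):
        with pytest.raises(ConfigurationError):
            FeelingConfiguration(np.ones((1, 1)))


class TestInitRandom:
    def test_p_one_gives_unanimity(self):
        config = init_random(5, 1.0, rng_seed=7)
        assert (config.matrix == 1).all()

    def test_p_zero_gives_hostility(self):
        config = init_random(5, 0.0, rng_seed=7)
        off = ~np.eye(5, dtype=bool)
        assert (config.matrix[off] == -1).all()
        assert (np.diagonal(config.matrix) == 1).all()

    def test_seed_determinism(self):
        a = init_random(12, 0.4, rng_seed=3)
        b = init_random(12, 0.4, rng_seed=3)
        assert np.array_equal(a.matrix, b.matrix)

    def test_friendliness_frequency_converges(self):
        # law of large numbers: off-diagonal +1 frequency approaches p
        hits = total = 0
        for seed in range(60):
            m = init_random(30, 0.4, rng_seed=seed).matrix
            off = ~np.eye(30, dtype=bool)
            hits += (m[off] == 1).sum()
            total += off.sum()
        assert hits / total == pytest.approx(0.4, abs=0.01)

    @pytest.mark.parametrize("n,p", [(1, 0.5), (5, -0.1), (5, 1.2)])
    def test_invalid_parameters(self, n, p):
        with pytest.raises(ParameterError):
            init_random(n, p, rng_seed=0)


class TestMutualGroup:
    def test_all_friendly_group_is_everyone(self, all_friendly_30):
        assert mutual_group(all_friendly_30, 4) == frozenset(range(30))

    def test_all_hostile_group_is_self(self, all_hostile_4):
        for i in range(4):
            assert mutual_group(all_hostile_4, i) == {i}

    def test_triangle_groups(self, triangle):
        # agent 1 is mutual with both others; 2 and 3 dislike each other
        assert mutual_group(triangle, 0) == {0, 1, 2}
        assert mutual_group(triangle, 1) == {0, 1}
        assert mutual_group(triangle, 2) == {0, 2}

    def test_index_out_of_range(self, triangle):
        with pytest.raises(IndexError):
            mutual_group(triangle, 3)


class TestCongruity:
    def test_synchronized_group_attains_one(self):
        # identical feeling vectors: two agents liking everyone
        config = FeelingConfiguration(np.ones((6, 6), dtype=np.int8))
        assert congruity(config, 2) == pytest.approx(1.0)

    def test_singleton_convention(self, all_hostile_4):
        assert congruity(all_hostile_4, 0) == 1.0

    def test_triangle_value(self, triangle):
        # agent 1's two peers each disagree on one of three components:
        # c = 1 - mean(sqrt(1/3), sqrt(1/3))
        expected = 1.0 - math.sqrt(1.0 / 3.0)
        assert congruity(triangle, 0) == pytest.approx(expected)

    def test_matches_oracle_on_random_configs(self):
        params = AgentParameters.uniform(6, gamma=1.0)
        for seed in range(30):
            m = random_matrix(6, 0.5, seed)
            config = FeelingConfiguration(m)
            for i in range(6):
                assert payoff(config, i, params) == pytest.approx(
                    oracle_payoff(m.tolist(), i, 1.0, 0.0)
                )


class TestPayoff:
    def test_unified_society(self, all_friendly_30, uniform_params):
        assert payoff(all_friendly_30, 0, uniform_params(30)) == pytest.approx(30.0)

    def test_philanthropist_scores_group_size(self):
        # gamma = 0: payoff equals group size regardless of congruity
        params = AgentParameters.with_philanthropist(5, gamma_others=1.0)
        m = random_matrix(5, 0.5, seed=9)
        config = FeelingConfiguration(m)
        assert payoff(config, 0, params) == pytest.approx(len(mutual_group(config, 0)))

    def test_triangle_value(self, triangle, uniform_params):
        expected = 3.0 * (1.0 - math.sqrt(1.0 / 3.0))
        assert payoff(triangle, 0, uniform_params(3)) == pytest.approx(expected)

    def test_zero_power_zero_is_one(self, all_hostile_4):
        # philanthropist alone: S = n = 1 even though the exponent is 0
        params = AgentParameters.uniform(4, gamma=0.0)
        assert payoff(all_hostile_4, 0, params) == pytest.approx(1.0)

    def test_penalty_term(self, triangle):
        params = AgentParameters.uniform(3, gamma=1.0, penalty_lambda=2.0)
        base = payoff(triangle, 1, AgentParameters.uniform(3, gamma=1.0))
        assert payoff(triangle, 1, params) == pytest.approx(base - 2.0 * 1)

    def test_bounds_with_zero_penalty(self):
        params = AgentParameters.uniform(7, gamma=1.5)
        for seed in range(20):
            config = FeelingConfiguration(random_matrix(7, 0.4, seed))
            for i in range(7):
                assert 0.0 <= payoff(config, i, params) <= 7.0
                assert 0.0 <= congruity(config, i) <= 1.0
                assert 1 <= len(mutual_group(config, i)) <= 7


class TestBestResponse:
    @pytest.mark.parametrize("n", [3, 4])
    def test_exhaustive_oracle_equivalence(self, n):
        """Exact agreement with brute-force enumeration on every configuration."""
        gamma, lam = 1.0, 0.0
        params = AgentParameters.uniform(n, gamma=gamma, penalty_lambda=lam)
        rng = np.random.default_rng(0)
        for m in all_matrices(n):
            config = FeelingConfiguration(m)
            for i in range(n):
                new_row, flipped = best_response(config, i, params, rng)
                allowed = oracle_best_flips(m.tolist(), i, gamma, lam)
                if not allowed:
                    assert flipped is None
                    assert np.array_equal(new_row, m[i])
                else:
                    assert flipped in allowed
                    assert new_row[flipped] == -m[i, flipped]

    @pytest.mark.parametrize("gamma,lam", [(0.0, 0.0), (1.5, 0.0), (1.0, 0.8)])
    def test_sampled_oracle_equivalence_n5(self, gamma, lam):
        params = AgentParameters.uniform(5, gamma=gamma, penalty_lambda=lam)
        rng = np.random.default_rng(1)
        for seed in range(120):
            m = random_matrix(5, 0.5, seed)
            config = FeelingConfiguration(m)
            for i in range(5):
                _, flipped = best_response(config, i, params, rng)
                allowed = oracle_best_flips(m.tolist(), i, gamma, lam)
                if not allowed:
                    assert flipped is None
                else:
                    assert flipped in allowed

    def test_unanimity_never_abandoned(self, all_friendly_30, uniform_params):
        rng = np.random.default_rng(0)
        for gamma in (0.5, 1.0, 2.0):
            _, flipped = best_response(
                all_friendly_30, 3, uniform_params(30, gamma=gamma), rng
            )
            assert flipped is None

    def test_two_agent_reconciliation(self):
        # agent 1 dislikes agent 2 but 2 likes 1: flipping doubles the payoff
        config = FeelingConfiguration(np.array([[1, -1], [1, 1]], dtype=np.int8))
        params = AgentParameters.uniform(2, gamma=1.0)
        new_row, flipped = best_response(config, 0, params, np.random.default_rng(0))
        assert flipped == 1
        assert new_row.tolist() == [1, 1]

    def test_tied_best_flips_selected_uniformly(self):
        # agent 0 dislikes two symmetric reciprocators: both flips tie
        m = np.array(
            [[1, -1, -1], [1, 1, -1], [1, -1, 1]],
            dtype=np.int8,
        )
        config = FeelingConfiguration(m)
        params = AgentParameters.uniform(3, gamma=1.0)
        flips, stay = oracle_candidates(m.tolist(), 0, 1.0, 0.0)
        assert flips[1] == pytest.approx(flips[2])
        assert flips[1] > stay
        counts = {1: 0, 2: 0}
        for seed in range(400):
            _, flipped = best_response(config, 0, params, np.random.default_rng(seed))
            counts[flipped] += 1
        assert counts[1] + counts[2] == 400
        assert 140 <= counts[1] <= 260  # binomial(400, 1/2) within ~4 sigma


class TestStep:
    @pytest.mark.parametrize("rule", ["synchronous", "sequential", "random"])
    def test_all_friendly_is_fixed_point(self, rule, all_friendly_30, uniform_params):
        schedule = UpdateSchedule(rule=rule, rng_seed=5)
        out = step(all_friendly_30, uniform_params(30), schedule)
        assert out == all_friendly_30

    def test_input_not_mutated(self, uniform_params):
        config = FeelingConfiguration(random_matrix(8, 0.3, 2))
        before = config.matrix.copy()
        step(config, uniform_params(8), UpdateSchedule(rng_seed=0))
        assert np.array_equal(config.matrix, before)

    def test_repeated_calls_identical(self, uniform_params):
        config = FeelingConfiguration(random_matrix(10, 0.3, 4))
        schedule = UpdateSchedule(rng_seed=11)
        a = step(config, uniform_params(10), schedule)
        b = step(config, uniform_params(10), schedule)
        assert a == b

    def test_synchronous_matches_per_agent_oracle(self, uniform_params):
        # each row of the synchronous successor must be an oracle-optimal
        # response to the same input configuration
        for seed in range(25):
            m = random_matrix(4, 0.5, seed)
            config = FeelingConfiguration(m)
            out = step(config, uniform_params(4), UpdateSchedule(rng_seed=seed))
            for i in range(4):
                diff = np.flatnonzero(out.matrix[i] != m[i])
                allowed = oracle_best_flips(m.tolist(), i, 1.0, 0.0)
                if not allowed:
                    assert diff.size == 0
                else:
                    assert diff.size == 1 and diff[0] in allowed

    def test_bad_rule_rejected(self):
        with pytest.raises(ParameterError):
            UpdateSchedule(rule="simultaneous")


class TestRunDynamics:
    def test_all_friendly_immediate_fixed_point(self, all_friendly_30, uniform_params):
        traj = run_dynamics(
            all_friendly_30, uniform_params(30), UpdateSchedule(rng_seed=0), horizon=10
        )
        assert traj.terminal_status == "fixed_point"
        assert traj.n_steps == 1
        assert (traj.group_sizes == 30).all()

    def test_group_sizes_consistent_with_configs(self, uniform_params):
        config = init_random(20, 0.4, rng_seed=8)
        traj = run_dynamics(
            config, uniform_params(20), UpdateSchedule(rng_seed=8), horizon=15
        )
        for t, snap in enumerate(traj.configurations):
            assert np.array_equal(traj.group_sizes[t], snap.group_sizes())
            assert ((traj.group_sizes[t] >= 1) & (traj.group_sizes[t] <= 20)).all()

    def test_bit_identical_replays(self, uniform_params):
        config = init_random(15, 1.0 / 3.0, rng_seed=21)
        runs = [
            run_dynamics(
                config, uniform_params(15), UpdateSchedule(rng_seed=21), horizon=40
            )
            for _ in range(2)
        ]
        assert runs[0].terminal_status == runs[1].terminal_status
        assert len(runs[0].configurations) == len(runs[1].configurations)
        for a, b in zip(runs[0].configurations, runs[1].configurations):
            assert a == b

    def test_dominant_penalty_forces_unanimity(self, uniform_params):
        """lambda > N: any start reaches the all-friendly state in < N steps."""
        n = 8
        params = uniform_params(n, gamma=1.0, lam=n + 1.0)
        starts = [random_matrix(n, p, seed) for p in (0.0, 0.2, 0.5) for seed in range(5)]
        for m in starts:
            traj = run_dynamics(
                FeelingConfiguration(m),
                params,
                UpdateSchedule(rng_seed=0),
                horizon=n,
            )
            assert (traj.final.matrix == 1).all()
            assert traj.n_steps <= n - 1 + 1  # + 1 step to certify the fixed point

    def test_horizon_validation(self, all_friendly_30, uniform_params):
        with pytest.raises(ParameterError):
            run_dynamics(
                all_friendly_30, uniform_params(30), UpdateSchedule(), horizon=0
            )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), p=st.sampled_from([0.1, 0.3, 0.5, 0.8]))
def test_dynamics_invariants_hold_along_trajectories(seed, p):
    """Bounds on group sizes and payoffs hold at every step of any run."""
    config = init_random(10, p, rng_seed=seed)
    params = AgentParameters.uniform(10, gamma=1.0)
    traj = run_dynamics(config, params, UpdateSchedule(rng_seed=seed), horizon=12)
    assert traj.group_sizes.min() >= 1
    assert traj.group_sizes.max() <= 10
    final = traj.final
    for i in range(10):
        assert 0.0 <= congruity(final, i) <= 1.0
        assert 0.0 <= payoff(final, i, params) <= 10.0
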
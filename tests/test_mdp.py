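"""MDP estimation, reward reshaping, and Q-learning vs the exact Bellman
solver (closed-form toys plus randomized oracle equivalence)."""

import numpy as np
import pytest

from sepsis_safety.mdp import (DiscreteMDP, MDPError, QTable, RewardSpec,
                               RewardTable, build_reward, estimate_mdp,
                               exact_solve, greedy_policy, make_random_mdp,
                               mdp_from_transitions, q_learning,
                               state_action_flag_fraction, transition_rewards)


def _chain_mdp(gamma=0.5):
    """s0 -a0-> s1 -a0-> survival terminal; deterministic."""
    s = np.array([0, 1])
    a = np.array([0, 0])
    nxt = np.array([1, 2])
    return mdp_from_transitions(s, a, nxt, k=2, n_actions=1, gamma=gamma,
                                min_count=1)


class TestEstimation:
    def test_single_transition_probability_one(self):
        mdp = mdp_from_transitions([0], [0], [1], k=2, n_actions=1, min_count=1)
        assert mdp.transition_probability(0, 0, 1) == 1.0

    def test_counts_2_1_1_give_half_quarter_quarter(self):
        s = [0, 0, 0, 0]
        a = [0, 0, 0, 0]
        nxt = [1, 1, 2, 3]
        mdp = mdp_from_transitions(s, a, nxt, k=4, n_actions=1, min_count=1)
        assert mdp.transition_probability(0, 0, 1) == pytest.approx(0.5)
        assert mdp.transition_probability(0, 0, 2) == pytest.approx(0.25)
        assert mdp.transition_probability(0, 0, 3) == pytest.approx(0.25)

    def test_rows_sum_to_one_on_estimated_cohort(self, prepared_run):
        mdp = prepared_run.mdp
        sums = np.zeros((mdp.k, mdp.n_actions))
        np.add.at(sums, (mdp.u_state, mdp.u_action), mdp.u_prob)
        assert np.allclose(sums[mdp.admissible], 1.0, atol=1e-12)

    def test_last_step_goes_to_outcome_terminal(self, prepared_run):
        mdp = prepared_run.mdp
        cohort = prepared_run.cohort
        deaths = int((~cohort.outcomes()).sum())
        died_seen = int((mdp.t_next == mdp.death_state).sum())
        # admissibility filtering can only drop transitions, never invent them
        assert died_seen <= deaths

    def test_orphan_state_errors_and_relax_recovers(self):
        s = [0, 1]
        a = [0, 0]
        nxt = [1, 2]
        with pytest.raises(MDPError, match=r"\[0, 1\]"):
            mdp_from_transitions(s, a, nxt, k=2, n_actions=1, min_count=5)
        mdp = mdp_from_transitions(s, a, nxt, k=2, n_actions=1, min_count=5,
                                   on_no_admissible="relax")
        assert mdp.admissible.sum() == 2


class TestRewards:
    def test_fully_flagged_action_penalized_thirty_points(self):
        mdp = _chain_mdp()
        r = build_reward(mdp, np.array([1.0, 0.0]), RewardSpec(penalty=30.0),
                         np.array([0, 1]), np.array([0, 0]))
        assert r.r_sa[0, 0] == -30.0
        assert r.r_sa[1, 0] == 0.0

    def test_zero_penalty_means_zero_intermediate_reward(self):
        mdp = _chain_mdp()
        r = build_reward(mdp, np.array([1.0, 1.0]), RewardSpec(penalty=0.0),
                         np.array([0, 1]), np.array([0, 0]))
        assert (r.r_sa == 0.0).all()

    def test_half_flagged_action_penalized_fifteen(self):
        s = np.array([0, 0])
        a = np.array([0, 0])
        mdp = mdp_from_transitions(s, a, [1, 1], k=1, n_actions=1, min_count=1)
        r = build_reward(mdp, np.array([1.0, 0.0]), RewardSpec(penalty=30.0), s, a)
        assert r.r_sa[0, 0] == pytest.approx(-15.0)

    def test_penalized_reward_differs_by_exactly_p_times_f(self, prepared_run):
        pr = prepared_run
        unsafe = pr.human_flags.df["unsafe_human_any"].to_numpy()
        r0 = build_reward(pr.mdp, unsafe, RewardSpec(penalty=0.0),
                          pr.state_ids, pr.action_idx)
        r30 = build_reward(pr.mdp, unsafe, RewardSpec(penalty=30.0),
                           pr.state_ids, pr.action_idx)
        f = state_action_flag_fraction(pr.mdp, pr.state_ids, pr.action_idx, unsafe)
        assert np.allclose(r30.r_sa - r0.r_sa, -30.0 * f, atol=1e-12)

    def test_mismatched_flags_rejected(self):
        mdp = _chain_mdp()
        with pytest.raises(MDPError, match="match"):
            build_reward(mdp, np.zeros(5), RewardSpec(), np.array([0, 1]),
                         np.array([0, 0]))


class TestSolvers:
    def test_single_step_episode_converges_to_terminal_reward(self):
        mdp = mdp_from_transitions([0], [0], [1], k=1, n_actions=1, gamma=0.99,
                                   min_count=1)
        r = RewardTable(r_sa=np.zeros((1, 1)), terminal_magnitude=100.0)
        qt = q_learning(mdp, r, seed=0)
        assert qt.q[0, 0] == pytest.approx(100.0, abs=1e-3)
        ex = exact_solve(mdp, r)
        assert ex.q[0, 0] == pytest.approx(100.0, abs=1e-9)

    def test_two_state_chain_matches_hand_bellman_solution(self):
        """gamma=0.5, terminal +100 after s1: Q(s1)=100, Q(s0)=50."""
        mdp = _chain_mdp(gamma=0.5)
        r = RewardTable(r_sa=np.zeros((2, 1)), terminal_magnitude=100.0)
        for qt in (q_learning(mdp, r, seed=1), exact_solve(mdp, r)):
            assert qt.q[1, 0] == pytest.approx(100.0, abs=1e-3)
            assert qt.q[0, 0] == pytest.approx(50.0, abs=1e-3)

    def test_gamma_zero_is_myopic(self):
        mdp = _chain_mdp(gamma=0.0)
        r = RewardTable(r_sa=np.array([[3.0], [1.0]]), terminal_magnitude=100.0)
        ex = exact_solve(mdp, r)
        assert ex.q[0, 0] == pytest.approx(3.0)
        assert ex.q[1, 0] == pytest.approx(101.0)   # immediate terminal bonus

    def test_zero_rewards_give_zero_q(self):
        mdp = _chain_mdp()
        r = RewardTable(r_sa=np.zeros((2, 1)), terminal_magnitude=0.0)
        assert (exact_solve(mdp, r).q[mdp.admissible] == 0.0).all()
        assert np.allclose(q_learning(mdp, r, seed=2).q[mdp.admissible], 0.0,
                           atol=1e-6)

    def test_q_learning_matches_exact_solver_on_random_mdps(self):
        rng = np.random.default_rng(99)
        for trial in range(12):
            nS = int(rng.integers(3, 15))
            nA = int(rng.integers(2, 5))
            mdp, rewards = make_random_mdp(nS, nA, seed=trial, n_episodes=400)
            ql = q_learning(mdp, rewards, seed=trial)
            ex = exact_solve(mdp, rewards)
            assert np.array_equal(greedy_policy(ql), greedy_policy(ex))

    def test_q_learning_deterministic_under_seed(self):
        mdp, rewards = make_random_mdp(6, 3, seed=4, n_episodes=300)
        q1 = q_learning(mdp, rewards, seed=9).q
        q2 = q_learning(mdp, rewards, seed=9).q
        assert np.array_equal(q1, q2)

    def test_nonconvergence_raises_with_diagnostic(self):
        mdp, rewards = make_random_mdp(8, 3, seed=2, n_episodes=300)
        with pytest.raises(MDPError, match="converge"):
            q_learning(mdp, rewards, max_sweeps=1, tol=1e-12)


class TestGreedy:
    def test_unique_maximizer_selected(self):
        qt = QTable(q=np.array([[1.0, 5.0, 2.0]]),
                    admissible=np.ones((1, 3), bool))
        assert greedy_policy(qt)[0] == 1

    def test_exact_tie_breaks_to_lower_action_index(self):
        q = np.full((1, 8), -np.inf)
        q[0, 3] = q[0, 7] = 4.0
        adm = np.zeros((1, 8), bool)
        adm[0, [3, 7]] = True
        assert greedy_policy(QTable(q=q, admissible=adm))[0] == 3

    def test_state_without_admissible_action_gets_minus_one(self):
        q = np.full((2, 2), -np.inf)
        q[0, 0] = 1.0
        adm = np.zeros((2, 2), bool)
        adm[0, 0] = True
        policy = greedy_policy(QTable(q=q, admissible=adm))
        assert policy[0] == 0 and policy[1] == -1


class TestRewardReshapingToy:
    """3-state MDP: a flagged shortcut action vs a safe detour worth 10 less.

    s0 --a0--> survival (+100), a0 fully flagged (f = 1)
    s0 --a1--> s1 --a0--> survival (+100, discounted once), f = 0
    With gamma=0.9 the value deficit of the detour is 10 < 30, so penalty 0
    picks the shortcut and penalty 30 avoids it.
    """

    def _toy(self, penalty):
        s = np.array([0, 0, 1] * 6)
        a = np.array([0, 1, 0] * 6)
        nxt = np.array([2, 1, 2] * 6)
        mdp = mdp_from_transitions(s, a, nxt, k=2, n_actions=2, gamma=0.9,
                                   min_count=1)
        unsafe = np.array([1.0, 0.0, 0.0] * 6)
        return mdp, build_reward(mdp, unsafe, RewardSpec(penalty=penalty),
                                 s, a)

    def test_zero_penalty_selects_flagged_shortcut(self):
        mdp, r = self._toy(0.0)
        for solver in (exact_solve, lambda m, rw: q_learning(m, rw, seed=3)):
            assert greedy_policy(solver(mdp, r))[0] == 0

    def test_penalty_thirty_avoids_flagged_shortcut(self):
        mdp, r = self._toy(30.0)
        ex = exact_solve(mdp, r)
        assert ex.q[0, 0] == pytest.approx(70.0, abs=1e-6)
        assert ex.q[0, 1] == pytest.approx(90.0, abs=1e-6)
        for solver in (exact_solve, lambda m, rw: q_learning(m, rw, seed=3)):
            assert greedy_policy(solver(mdp, r))[0] == 1

    def test_zero_penalty_path_bit_identical_to_original(self, prepared_run):
        pr = prepared_run
        unsafe = pr.human_flags.df["unsafe_human_any"].to_numpy()
        spec_orig = RewardSpec(penalty=0.0)
        r_a = build_reward(pr.mdp, unsafe, spec_orig, pr.state_ids, pr.action_idx)
        r_b = build_reward(pr.mdp, np.zeros_like(unsafe), spec_orig,
                           pr.state_ids, pr.action_idx)
        q_a = q_learning(pr.mdp, r_a, seed=5)
        q_b = q_learning(pr.mdp, r_b, seed=5)
        assert np.array_equal(q_a.q, q_b.q)

    def test_large_penalty_avoids_fully_flagged_actions(self):
        mdp, _ = self._toy(0.0)
        gamma = mdp.gamma
        big = 2 * 100.0 / (1 - gamma) + 1
        _, r = self._toy(big)
        policy = greedy_policy(exact_solve(mdp, r))
        f = r.flagged_fraction
        for s in range(mdp.k):
            if policy[s] >= 0 and (f[s][mdp.admissible[s]] == 0).any():
                assert f[s, policy[s]] < 1.0
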
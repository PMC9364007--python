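"""Bellman updates, value mixture, noise, convergence and the exact oracle."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from swapdance import (
    ACTIONS,
    Action,
    Agent,
    CompiledGame,
    GameConfig,
    HoldVariant,
    LearnerConfig,
    QTables,
    add_q_noise,
    bellman_residual,
    bellman_update,
    encode_state,
    enumerate_states,
    greedy_action,
    init_tables,
    legal_actions,
    run_learning,
    transition,
    value_update,
)


class TestInit:
    def test_zero_sd_gives_zero_tables(self, compiled_default):
        cfg = LearnerConfig(init_sd=0.0, seed=0)
        q, v = init_tables(compiled_default, cfg)
        assert np.nanmax(np.abs(q.q)) == 0.0
        assert np.abs(v.v).max() == 0.0

    def test_same_seed_is_bit_identical(self, compiled_default):
        cfg = LearnerConfig(init_sd=0.05, seed=42)
        q1, v1 = init_tables(compiled_default, cfg)
        q2, v2 = init_tables(compiled_default, cfg)
        np.testing.assert_array_equal(q1.q, q2.q)
        np.testing.assert_array_equal(v1.v, v2.v)

    def test_sample_mean_within_standard_error(self, compiled_default):
        cfg = LearnerConfig(init_sd=0.05, seed=7)
        q, _ = init_tables(compiled_default, cfg)
        vals = q.q[~np.isnan(q.q)]
        assert vals.size > 1000
        assert abs(vals.mean()) < 4 * 0.05 / np.sqrt(vals.size)

    def test_illegal_entries_marked_impossible(self, compiled_default):
        cfg = LearnerConfig(seed=0)
        q, _ = init_tables(compiled_default, cfg)
        assert np.isnan(q.q[:, 0][~compiled_default.legal]).all()
        assert np.isnan(q.q[:, 1][~compiled_default.legal]).all()


class TestBellman:
    def test_gamma_zero_collapses_to_immediate_reward(self, default_game,
                                                      compiled_default):
        cfg = LearnerConfig(gamma=1e-12, init_sd=0.0, seed=0)
        q, v = init_tables(compiled_default, cfg)
        q = bellman_update(q, v, compiled_default, cfg)
        for actor, s_label, action in [
            (Agent.A, "100:001", Action.EXIT),
            (Agent.B, "000:000", Action.TOGGLE_OBJECT_A),
            (Agent.A, "101:001", Action.PASS),
        ]:
            t = transition(encode_state(s_label), actor, action, default_game)
            i = compiled_default.index[encode_state(s_label).bits]
            for y in Agent:
                expected = sum(o.probability * o.reward_to(y) for o in t.outcomes)
                assert q.q[actor, y, i, action] == pytest.approx(expected, abs=1e-9)

    def test_deterministic_toggle_is_single_term(self, default_game,
                                                 compiled_default):
        cfg = LearnerConfig(gamma=0.9, init_sd=0.0, seed=0)
        q, v = init_tables(compiled_default, cfg)
        rng = np.random.default_rng(1)
        v.v[:, :-1] = rng.normal(size=(2, compiled_default.n_states))
        q = bellman_update(q, v, compiled_default, cfg)
        s = encode_state("100:001")
        i = compiled_default.index[s.bits]
        t = transition(s, Agent.A, Action.TOGGLE_OBJECT_A, default_game)
        (o,) = t.outcomes
        j = compiled_default.index[o.state.bits]
        assert q.q[Agent.A, Agent.A, i, Action.TOGGLE_OBJECT_A] == pytest.approx(
            o.reward_to_A + 0.9 * v.v[Agent.A, j]
        )

    def test_slow_exit_hand_expansion(self):
        # two-outcome expectation for EXIT from the goal state, by hand
        game_cfg = GameConfig(p_exit=0.5)
        game = CompiledGame(game_cfg)
        cfg = LearnerConfig(gamma=0.9, init_sd=0.0, seed=0)
        q, v = init_tables(game, cfg)
        rng = np.random.default_rng(2)
        v.v[:, :-1] = rng.normal(size=(2, game.n_states))
        q = bellman_update(q, v, game, cfg)
        s = encode_state("001:100")
        i = game.index[s.bits]
        per_step = -game_cfg.cost_step - game_cfg.cost_maintain
        succeed = 4.0 + per_step  # A leaves with b
        fail = per_step + 0.9 * v.v[Agent.A, i]
        assert q.q[Agent.A, Agent.A, i, Action.EXIT] == pytest.approx(
            0.5 * succeed + 0.5 * fail
        )

    def test_terminal_successor_contributes_zero_value(self):
        game_cfg = GameConfig()
        game = CompiledGame(game_cfg)
        cfg = LearnerConfig(gamma=0.9, init_sd=0.0, seed=0)
        q, v = init_tables(game, cfg)
        v.v[:, :-1] = 123.0  # only non-terminal values are large
        q = bellman_update(q, v, game, cfg)
        i = game.index[encode_state("001:100").bits]
        # EXIT leads to the terminal state only: no 123 leaks through gamma*V
        assert q.q[Agent.A, Agent.A, i, Action.EXIT] == pytest.approx(
            4.0 - game_cfg.cost_step - game_cfg.cost_maintain
        )


class TestValueUpdate:
    @pytest.fixture()
    def toy(self, compiled_default):
        cfg = LearnerConfig(init_sd=0.0, seed=0)
        q, _ = init_tables(compiled_default, cfg)
        rng = np.random.default_rng(3)
        q.q[~np.isnan(q.q)] = rng.normal(size=int((~np.isnan(q.q)).sum()))
        return q

    def test_beta_one_limit_is_own_max(self, toy):
        cfg = LearnerConfig(beta=1 - 1e-12, seed=0)
        v = value_update(toy, cfg)
        np.testing.assert_allclose(
            v.v[Agent.A, :-1], np.nanmax(toy.q[Agent.A, Agent.A], axis=1), atol=1e-9
        )

    def test_beta_zero_limit_is_opponent_best_response(self, toy):
        cfg = LearnerConfig(beta=1e-12, seed=0)
        v = value_update(toy, cfg)
        e_star = np.nanargmax(
            np.where(np.isnan(toy.q[Agent.B, Agent.B]), -np.inf, toy.q[Agent.B, Agent.B]),
            axis=1,
        )
        rows = np.arange(toy.game.n_states)
        np.testing.assert_allclose(
            v.v[Agent.A, :-1], toy.q[Agent.B, Agent.A][rows, e_star], atol=1e-9
        )

    def test_balanced_beta_is_the_mean_of_both_branches(self, toy):
        cfg = LearnerConfig(beta=0.5, seed=0)
        v = value_update(toy, cfg)
        own = np.nanmax(toy.q[Agent.A, Agent.A], axis=1)
        e_star = np.nanargmax(
            np.where(np.isnan(toy.q[Agent.B, Agent.B]), -np.inf, toy.q[Agent.B, Agent.B]),
            axis=1,
        )
        rows = np.arange(toy.game.n_states)
        response = toy.q[Agent.B, Agent.A][rows, e_star]
        np.testing.assert_allclose(v.v[Agent.A, :-1], 0.5 * (own + response), atol=1e-9)

    def test_terminal_value_is_pinned_to_zero(self, toy):
        v = value_update(toy, LearnerConfig(seed=0))
        assert v.v[:, -1].tolist() == [0.0, 0.0]


class TestNoise:
    def test_zero_sd_is_identity(self, converged_default):
        cfg = LearnerConfig(q_noise_sd=0.0, seed=0)
        q2 = add_q_noise(converged_default.q, cfg)
        np.testing.assert_array_equal(q2.q, converged_default.q.q)

    def test_fixed_seed_reproducible(self, converged_default):
        cfg = LearnerConfig(q_noise_sd=0.25, seed=9)
        a = add_q_noise(converged_default.q, cfg, np.random.default_rng(9))
        b = add_q_noise(converged_default.q, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(a.q, b.q)

    def test_perturbation_scale_matches_sd(self, converged_default):
        cfg = LearnerConfig(q_noise_sd=0.25, seed=10)
        noisy = add_q_noise(converged_default.q, cfg, np.random.default_rng(10))
        diff = (noisy.q - converged_default.q.q)[~np.isnan(converged_default.q.q)]
        # sample variance of ~1000 draws should sit near 0.0625
        assert diff.var() == pytest.approx(0.0625, rel=0.2)
        assert np.isnan(noisy.q).sum() == np.isnan(converged_default.q.q).sum()


class TestGreedyAction:
    def test_unique_maximiser_always_chosen(self, converged_default, default_game):
        s = encode_state("001:100")
        rng = np.random.default_rng(0)
        picks = {
            greedy_action(converged_default.q, s, Agent.A, 0.0, rng) for _ in range(50)
        }
        assert len(picks) == 1

    def test_full_noise_is_uniform_over_legal(self, converged_default, default_game):
        s = encode_state("100:001")
        legal = legal_actions(s, Agent.A, default_game)
        rng = np.random.default_rng(1)
        n = 10_000
        counts = {a: 0 for a in legal}
        for _ in range(n):
            counts[greedy_action(converged_default.q, s, Agent.A, 1.0, rng)] += 1
        expected = n / len(legal)
        for a in legal:
            # 5-sigma binomial band
            assert abs(counts[a] - expected) < 5 * np.sqrt(expected)

    def test_exact_ties_split_evenly(self, compiled_default):
        cfg = LearnerConfig(init_sd=0.0, seed=0)
        q, _ = init_tables(compiled_default, cfg)  # all-zero: every action ties
        s = encode_state("000:000")
        rng = np.random.default_rng(2)
        counts = {}
        for _ in range(5000):
            a = greedy_action(q, s, Agent.A, 0.0, rng)
            counts[a] = counts.get(a, 0) + 1
        freqs = np.array(list(counts.values())) / 5000
        assert len(counts) == 5
        assert np.all(np.abs(freqs - 0.2) < 0.05)

    def test_terminal_or_empty_raises(self, converged_default):
        from swapdance import JointState

        with pytest.raises(ValueError):
            greedy_action(
                converged_default.q,
                JointState((False,) * 6, terminal=True, exiter=Agent.A),
                Agent.A,
            )


class TestRunLearning:
    def test_seed_determinism_with_noise(self, default_game):
        cfg = LearnerConfig(seed=5)
        a = run_learning(default_game, cfg)
        b = run_learning(default_game, cfg)
        np.testing.assert_array_equal(a.q.q, b.q.q)
        np.testing.assert_array_equal(a.v.v, b.v.v)
        assert a.iterations_to_convergence == b.iterations_to_convergence

    def test_noise_free_converges_quickly(self, converged_default):
        assert converged_default.converged
        assert converged_default.iterations_to_convergence < 100

    def test_noise_free_fixed_point_residual(self, default_game, compiled_default,
                                             noise_free_learner, converged_default):
        res = converged_default
        assert (
            bellman_residual(res.q, res.v, compiled_default, noise_free_learner)
            <= 1e-9
        )

    def test_nonconvergence_returns_tables(self, default_game):
        cfg = LearnerConfig(max_iterations=3, seed=0)
        res = run_learning(default_game, cfg)
        assert not res.converged
        assert res.q.q.shape[2] == 64

    def test_terminal_value_zero_throughout(self, converged_default):
        assert converged_default.v.v[:, -1].tolist() == [0.0, 0.0]

    def test_strong_discounting_gives_up_on_exchange(self):
        # with gamma far below the exchange threshold the agents just leave
        from swapdance import DanceLabel, extract_dance

        game_cfg = GameConfig()
        res = run_learning(game_cfg, LearnerConfig(gamma=0.5, seed=0))
        dance = extract_dance(res.q, game_cfg, seed=0)
        assert dance.label is DanceLabel.EXIT_NO_SWAP


def _oracle_fixed_point(game_cfg: GameConfig, gamma: float, beta: float = 0.5,
                        tol: float = 1e-13, max_iter: int = 20000):
    """Independent exact solver: dict-based iteration of the expectation and
    mixture equations from zero tables to a machine-precision fixed point,
    with deterministic first-index tie-breaking."""
    states = enumerate_states(game_cfg.variant)
    v = {ag: {s.bits: 0.0 for s in states} for ag in Agent}
    q = {}
    for _ in range(max_iter):
        new_q = {}
        for x in Agent:
            for y in Agent:
                for s in states:
                    for d in legal_actions(s, x, game_cfg):
                        total = 0.0
                        for o in transition(s, x, d, game_cfg).outcomes:
                            cont = 0.0 if o.state.terminal else v[y][o.state.bits]
                            total += o.probability * (o.reward_to(y) + gamma * cont)
                        new_q[x, y, s.bits, d] = total
        new_v = {ag: {} for ag in Agent}
        for s in states:
            best = {}
            for x in Agent:
                acts = legal_actions(s, x, game_cfg)
                best[x] = max(acts, key=lambda d: new_q[x, x, s.bits, d])
            for y in Agent:
                own_w = beta if y is Agent.A else 1.0 - beta
                other = Agent.B if y is Agent.A else Agent.A
                new_v[y][s.bits] = own_w * new_q[y, y, s.bits, best[y]] + (
                    1.0 - own_w
                ) * new_q[other, y, s.bits, best[other]]
        delta = max(
            abs(new_v[ag][s.bits] - v[ag][s.bits]) for ag in Agent for s in states
        )
        q, v = new_q, new_v
        if delta < tol:
            break
    return q, v


class TestOracleEquivalence:
    def test_sixteen_state_variant_matches_exact_solver(self):
        """On the 16-state no-agent-holds variant with certain exit and no
        noise, the learner's converged V must agree with an independent
        dict-based fixed-point solver."""
        game_cfg = GameConfig(variant=HoldVariant.NO_AGENT_HOLDS, p_exit=1.0)
        gamma = 0.9
        learner = LearnerConfig(
            gamma=gamma, q_noise_sd=0.0, init_sd=0.0, seed=0,
            max_iterations=5000, residual_tol=1e-12,
        )
        res = run_learning(game_cfg, learner)
        assert res.converged
        _, v_oracle = _oracle_fixed_point(game_cfg, gamma)
        game = res.q.game
        for y in Agent:
            for i, s in enumerate(game.states):
                assert res.v.v[y, i] == pytest.approx(
                    v_oracle[y][s.bits], abs=1e-6
                ), f"V^{y.name}({s.label})"


class TestConvergedSymmetry:
    def test_symmetric_config_learns_symmetric_tables(self, converged_default):
        """Swapping agent roles and object identities maps the converged
        tables onto themselves (up to the run's noise tolerance)."""
        game = converged_default.q.game
        perm = np.empty(game.n_states, dtype=int)
        for i, s in enumerate(game.states):
            mirrored = (s.bits[5], s.bits[4], s.bits[3], s.bits[2], s.bits[1], s.bits[0])
            perm[i] = game.index[mirrored]
        act_perm = [Action.TOGGLE_OBJECT_B, Action.TOGGLE_AGENT,
                    Action.TOGGLE_OBJECT_A, Action.PASS, Action.EXIT]
        va = converged_default.v.v[Agent.A, :-1]
        vb = converged_default.v.v[Agent.B, :-1]
        np.testing.assert_allclose(va, vb[perm], atol=1e-6)
        qa = converged_default.q.q[Agent.A, Agent.A]
        qb = converged_default.q.q[Agent.B, Agent.B]
        np.testing.assert_allclose(qa, qb[perm][:, act_perm], atol=1e-6)


class TestSerialization:
    def test_json_round_trip(self, converged_default, compiled_default):
        payload = converged_default.q.to_json()
        restored = QTables.from_json(compiled_default, payload)
        np.testing.assert_allclose(restored.q, converged_default.q.q, atol=1e-12)
        assert '"impossible"' in payload

    def test_csv_matrix_layout(self, converged_default):
        text = converged_default.q.to_csv(Agent.A, Agent.A)
        lines = text.strip().splitlines()
        assert lines[0].split(",")[1:] == [a.name for a in ACTIONS]
        assert len(lines) == 65  # header + 64 states
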
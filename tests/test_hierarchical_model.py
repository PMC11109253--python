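"""Hierarchical model: elementary updates, replay, entropies, oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tigermaze as tm
from tigermaze.hierarchical_model import (Belief, grid_update_listen,
                                          tiger_from_grid,
                                          tiger_update_from_roar)
from tigermaze.maze_env import BACK, F, L, N, R, Pose

from conftest import random_belief
from _oracles import (oracle_exact_grid_filter, oracle_listen_grid,
                      oracle_move_grid, oracle_tiger_dir,
                      oracle_tiger_marginal)


class TestTigerUpdate:
    def test_uniform_prior_returns_normalized_likelihood(self):
        post = tiger_update_from_roar(np.full(3, 1 / 3), L, 1.0, 0.85)
        assert np.allclose(post, [0.85, 0.075, 0.075], atol=1e-15)

    def test_zero_sensitivity_leaves_prior_unchanged(self):
        prior = np.array([0.2, 0.5, 0.3])
        post = tiger_update_from_roar(prior, F, 0.0, 0.85)
        assert np.allclose(post, prior)

    def test_squared_sensitivity_hand_value(self):
        # prior (0.85, 0.075, 0.075), same-direction roar, delta = 2:
        # posterior entry = 0.85^3 / (0.85^3 + 2 * 0.075^3)
        prior = np.array([0.85, 0.075, 0.075])
        post = tiger_update_from_roar(prior, L, 2.0, 0.85)
        z = 0.85 ** 3 + 2 * 0.075 ** 3
        assert np.allclose(post, [0.85 ** 3 / z, 0.075 ** 3 / z, 0.075 ** 3 / z],
                           rtol=1e-12)
        assert post[0] == pytest.approx(0.9986280, abs=1e-7)


class TestGridListenUpdate:
    def test_beta_to_one_limit_excludes_inconsistent_rooms(self, maze):
        params = tm.ModelParams(beta=0.999, gamma=0.0)
        b = Belief(np.array([0.9, 0.05, 0.05]), np.full(16, 1 / 16),
                   np.full(16, 1 / 16))
        new_grid, mode = grid_update_listen(
            b, L, N, params, maze, pre_roar_tiger=np.array([0.9, 0.05, 0.05]))
        assert mode == "update"
        rel = maze.td_rel[N]
        assert np.all(new_grid[rel == BACK] == 0.0)
        assert np.all(new_grid[rel != L] < 1e-2)
        assert new_grid.sum() == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_one_reduces_to_pure_update(self, maze, rng):
        for _ in range(20):
            b = random_belief(rng, maze)
            pre = rng.dirichlet(np.ones(3))
            v = int(rng.integers(3))
            d = int(rng.integers(4))
            p1 = tm.ModelParams(epsilon=1.0, beta=0.9, gamma=0.1)
            out_eps1, _ = grid_update_listen(b, v, d, p1, maze,
                                             pre_roar_tiger=pre)
            out_update, _ = grid_update_listen(
                b, v, d, p1, maze, pre_roar_tiger=np.eye(3)[v])  # force update
            assert np.allclose(out_eps1, out_update, atol=1e-12)

    def test_matches_enumeration_oracle(self, maze, rng):
        params = tm.ModelParams(beta=0.9, gamma=0.1, epsilon=0.3)
        for _ in range(50):
            b = random_belief(rng, maze)
            pre = rng.dirichlet(np.ones(3))
            v = int(rng.integers(3))
            d = int(rng.integers(4))
            got, mode = grid_update_listen(b, v, d, params, maze,
                                           pre_roar_tiger=pre)
            post_tiger = b.p_tiger
            reest = v != int(np.argmax(pre))
            want = oracle_listen_grid(
                b.p_grid, b.anchor_prior, v, int(np.argmax(post_tiger)), d,
                params.beta, params.gamma, params.epsilon, reest, maze)
            assert mode == ("re_estimate" if reest else "update")
            assert np.allclose(got, want, atol=1e-12)


class TestMoveUpdate:
    def test_point_mass_grid_gives_point_mass_tiger(self, maze):
        params = tm.ModelParams(gamma=0.0)
        for c in range(16):
            for d in range(4):
                grid = np.zeros(16)
                grid[c] = 1.0
                b = Belief(np.full(3, 1 / 3), grid, grid.copy())
                out = tm.move_update(b, F, d, params, maze)
                dest = tm.transition(Pose(c, d), F, maze)
                td = tm.true_tiger_direction(dest, maze)
                if td != BACK:
                    assert out.p_tiger[td] == pytest.approx(1.0)
                assert out.p_grid[dest.grid] == 1.0

    def test_push_forward_preserves_grid_entropy(self, maze, rng):
        params = tm.ModelParams()
        for _ in range(30):
            b = random_belief(rng, maze)
            d = int(rng.integers(4))
            a = int(rng.integers(3))
            out = tm.move_update(b, a, d, params, maze)
            assert tm.entropy(out.p_grid) == pytest.approx(
                tm.entropy(b.p_grid), abs=1e-12)

    def test_uniform_grid_tiger_marginal_counts_directions(self, maze):
        params = tm.ModelParams(gamma=0.0)
        grid = np.full(16, 1 / 16)
        b = Belief(np.full(3, 1 / 3), grid, grid.copy())
        out = tm.move_update(b, F, N, params, maze)
        d_next = N
        counts = np.array([
            sum(oracle_tiger_dir(c, d_next, maze) == s for c in range(16))
            for s in range(3)], dtype=float)
        # push-forward of uniform is uniform; marginal is direction counts
        assert np.allclose(out.p_tiger, counts / counts.sum(), atol=1e-12)

    def test_anchor_reset_on_move(self, maze, rng):
        b = random_belief(rng, maze)
        out = tm.move_update(b, R, N, tm.ModelParams(), maze, trial_index=5)
        assert np.array_equal(out.anchor_prior, out.p_grid)
        assert out.anchor_trial == 5

    def test_gamma_zero_is_exact_marginal(self, maze, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(16))
            d = int(rng.integers(4))
            got = tiger_from_grid(p, d, 0.0, maze)
            want = oracle_tiger_marginal(p, d, 0.0, maze)
            assert np.allclose(got, want, atol=1e-12)


class TestReadouts:
    def test_entropy_extremes_and_hand_value(self):
        assert tm.entropy(np.full(3, 1 / 3)) == pytest.approx(math.log(3))
        point = np.zeros(16)
        point[4] = 1.0
        assert tm.entropy(point) == 0.0
        # -(0.85 ln 0.85 + 2 * 0.075 ln 0.075)
        assert tm.entropy(np.array([0.85, 0.075, 0.075])) == pytest.approx(
            0.5266812, abs=1e-7)

    def test_map_predict_unique_and_tied(self, rng):
        b = Belief(np.array([0.6, 0.3, 0.1]), np.full(16, 1 / 16),
                   np.full(16, 1 / 16))
        assert tm.map_predict(b, rng)[0] == L
        b2 = Belief(np.array([0.5, 0.5, 0.0]), np.full(16, 1 / 16),
                    np.full(16, 1 / 16))
        draws = np.array([tm.map_predict(b2, rng)[0] for _ in range(4000)])
        assert abs((draws == L).mean() - 0.5) < 0.05
        cells = np.array([tm.map_predict(b2, rng)[1] for _ in range(8000)])
        freqs = np.bincount(cells, minlength=16) / 8000
        assert np.all(np.abs(freqs - 1 / 16) < 0.02)


class TestReplay:
    def test_one_listen_composes_elementary_updates(self, maze):
        params = tm.ModelParams()
        model = tm.HierarchicalModel()
        pose = Pose(0, N)
        assert tm.true_tiger_direction(pose, maze) != BACK
        game = tm.GameRecord(
            trials=[tm.TrialRecord(pose=pose, action=tm.LISTEN, roar=L)],
            termination="trial_limit", trial_limit=10)
        trace = model.replay_game(game, params, maze)
        b0 = model.init_belief(maze, N, params)
        expect_tiger = tiger_update_from_roar(b0.p_tiger, L, params.delta,
                                              maze.alpha)
        staged = Belief(expect_tiger, b0.p_grid, b0.anchor_prior)
        expect_grid, _ = grid_update_listen(staged, L, N, params, maze,
                                            pre_roar_tiger=b0.p_tiger)
        assert np.allclose(trace.post_td[0], expect_tiger, atol=1e-12)
        assert np.allclose(trace.post_gr[0], expect_grid, atol=1e-12)

    def test_replay_reproduces_generator_beliefs_exactly(self, maze,
                                                         one_participant):
        traces = tm.run_model_on_session(one_participant.sessions,
                                         tm.ModelParams(), maze)
        for got, stored in zip(traces, one_participant.traces):
            assert np.array_equal(got.post_td, stored.post_td)
            assert np.array_equal(got.post_gr, stored.post_gr)
            assert got.mode == stored.mode

    def test_inconsistent_logs_raise(self, maze):
        pose = Pose(0, N)
        game = tm.GameRecord(trials=[tm.TrialRecord(pose=pose, action=tm.LISTEN)],
                             termination="trial_limit")
        with pytest.raises(ValueError, match="without a roar"):
            tm.HierarchicalModel().replay_game(game, tm.ModelParams(), maze)
        game2 = tm.GameRecord(
            trials=[tm.TrialRecord(pose=pose, action=tm.move(L), roar=F)],
            termination="trial_limit")
        with pytest.raises(ValueError, match="carries a roar"):
            tm.HierarchicalModel().replay_game(game2, tm.ModelParams(), maze)

    def test_noise_free_repeated_listening_shrinks_support(self):
        """With perfect observations and memory, listening repeatedly in one
        room can only exclude candidate rooms, never revive them."""
        maze = tm.reference_maze(alpha=1.0)
        params = tm.ModelParams(delta=1.0, beta=0.999, epsilon=0.0, gamma=0.0)
        model = tm.HierarchicalModel()
        pose = next(Pose(c, d) for c in range(16) for d in range(4)
                    if tm.true_tiger_direction(Pose(c, d), maze) == L)
        belief = model.init_belief(maze, pose.orientation, params)
        prev_support = 16
        for _ in range(4):
            belief, _ = model.listen_step(belief, L, pose.orientation,
                                          params, maze)
            support = int((belief.p_grid > 1e-9).sum())
            assert support <= prev_support
            prev_support = support
        assert prev_support < 16

    def test_exact_filter_agreement_and_map_conditioning_gap(self, maze):
        """Noise-free listen-only sessions coincide with the exact Bayes
        filter over rooms; with noisy roars and a contradicting history the
        model's MAP-conditioned grid update genuinely departs from it."""
        pose = next(Pose(c, d) for c in range(16) for d in range(4)
                    if tm.true_tiger_direction(Pose(c, d), maze) == L)
        d = pose.orientation

        noise_free = tm.reference_maze(alpha=1.0)
        params = tm.ModelParams(delta=1.0, beta=0.999, epsilon=0.0, gamma=0.0)
        model = tm.HierarchicalModel()
        belief = model.init_belief(noise_free, d, params)
        for v in [L, L]:
            belief, _ = model.listen_step(belief, v, d, params, noise_free)
        exact = oracle_exact_grid_filter(np.full(16, 1 / 16), [L, L], d,
                                         1.0, noise_free)
        # with alpha = 1 and beta -> 1 both put all mass on consistent rooms
        assert set(np.flatnonzero(belief.p_grid > 1e-6)) == set(
            np.flatnonzero(exact > 1e-6))

        belief = model.init_belief(maze, d, params)
        roars = [L, L, F]
        for v in roars:
            belief, _ = model.listen_step(belief, v, d, params, maze)
        exact = oracle_exact_grid_filter(np.full(16, 1 / 16), roars, d,
                                         maze.alpha, maze)
        # the model conditions on the MAP tiger state, not the full tiger
        # posterior: after a contradicting roar the two must differ
        assert np.abs(belief.p_grid - exact).max() > 0.01


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_all_updates_preserve_normalization(seed):
    maze = tm.reference_maze()
    rng = np.random.default_rng(seed)
    b = random_belief(rng, maze)
    params = tm.ModelParams(
        delta=float(rng.uniform(1, 3)), beta=float(rng.uniform(0.5, 0.999)),
        epsilon=float(rng.uniform(0, 1)), gamma=float(rng.uniform(0, 0.3)))
    model = tm.HierarchicalModel()
    v = int(rng.integers(3))
    d = int(rng.integers(4))
    out, _ = model.listen_step(b, v, d, params, maze)
    assert abs(out.p_tiger.sum() - 1) < 1e-9 and abs(out.p_grid.sum() - 1) < 1e-9
    out2 = model.move_step(b, int(rng.integers(3)), d, params, maze, 1)
    assert abs(out2.p_tiger.sum() - 1) < 1e-9 and abs(out2.p_grid.sum() - 1) < 1e-9
    assert np.all(out.p_grid >= 0) and np.all(out2.p_grid >= 0)
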
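"""Network models: gradients against finite differences, initialization
contracts, determinism, checkpoint replay, and small learning problems."""

import numpy as np
import pytest

from predrep.envs import build_card_world, generate_card_trajectory
from predrep.models import FeedforwardPredictor, RecurrentPredictor, train_feedforward
from predrep.models.rnn import collect_representations


def _numeric_grad(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        hi = f()
        arr[idx] = orig - eps
        lo = f()
        arr[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g


class TestFeedforwardGradients:
    @pytest.mark.parametrize("include_actions", [True, False])
    def test_analytic_matches_central_differences(self, include_actions, rng):
        net = FeedforwardPredictor(n_hidden=5, include_actions=include_actions, seed=0)
        net.include_actions = include_actions
        obs = rng.random((7, 4))
        act = rng.random((7, 3))
        target = (rng.random((7, 4)) > 0.5).astype(float)
        w = {
            "W_o": rng.normal(0, 0.5, (5, 4)),
            "W_a": rng.normal(0, 0.5, (5, 3)),
            "b1": rng.normal(0, 0.1, 5),
            "W2": rng.normal(0, 0.5, (5, 5)),
            "b2": rng.normal(0, 0.1, 5),
            "W3": rng.normal(0, 0.5, (4, 5)),
            "b3": rng.normal(0, 0.1, 4),
        }
        grads, _ = net._grads(obs, act, target, w)
        for key, g in grads.items():
            num = _numeric_grad(
                lambda: net._loss(net._forward(obs, act, w)[2], target), w[key]
            )
            denom = max(np.abs(num).max(), 1e-8)
            assert np.abs(g - num).max() / denom < 1e-4, key


class TestRNNGradients:
    def test_bptt_matches_central_differences(self, rng):
        n, d_obs, d_act, T, B = 5, 3, 2, 4, 2
        w = {
            "W": np.eye(n) + rng.normal(0, 0.1, (n, n)),
            "W_o": rng.normal(0, 0.3, (n, d_obs)),
            "W_a": rng.normal(0, 0.3, (n, d_act)),
            "W_out": rng.normal(0, 0.3, (d_obs, n)),
        }
        obs = rng.random((T, B, d_obs))
        act = rng.random((T, B, d_act))
        tgt = rng.random((T, B, d_obs))
        r0 = rng.normal(0, 0.1, (B, n))

        def loss():
            _, y = RecurrentPredictor.forward_window(w, obs, act, r0)
            return float(np.sum((y - tgt) ** 2) / (T * B))

        r, y = RecurrentPredictor.forward_window(w, obs, act, r0)
        grads, analytic_loss = RecurrentPredictor.backward_window(w, obs, act, r0, r, y, tgt)
        assert analytic_loss == pytest.approx(loss())
        for key, g in grads.items():
            num = _numeric_grad(loss, w[key])
            denom = max(np.abs(num).max(), 1e-8)
            assert np.abs(g - num).max() / denom < 1e-4, key


class TestRecurrentPredictor:
    def test_initialization_contract(self, arm_traj):
        net = RecurrentPredictor(n_units=16, max_epochs=1, seed=0).fit(arm_traj)
        epoch0, w0 = net.checkpoints_[0]
        assert epoch0 == 0
        assert np.array_equal(w0["W"], np.eye(16))
        for key in ("W_o", "W_a", "W_out"):
            assert w0[key].std() == pytest.approx(0.02, rel=0.3)

    def test_seed_determinism(self, arm_traj):
        h1 = RecurrentPredictor(n_units=8, max_epochs=2, seed=5).fit(arm_traj).loss_history_
        h2 = RecurrentPredictor(n_units=8, max_epochs=2, seed=5).fit(arm_traj).loss_history_
        assert h1 == h2

    def test_checkpoint_replay_reproduces_final_rollout(self, arm_traj):
        net = RecurrentPredictor(n_units=8, max_epochs=2, seed=1).fit(arm_traj)
        r_final, y_final = net.rollout(arm_traj)
        _, w_last = net.checkpoints_[-1]
        r_ckpt, y_ckpt = net.rollout(arm_traj, weights=w_last)
        assert np.array_equal(r_final, r_ckpt)
        assert np.array_equal(y_final, y_ckpt)

    def test_nonpredictive_beats_mean_predictor(self, arm_traj):
        net = RecurrentPredictor(
            n_units=32, mode="non_predictive", max_epochs=15, batch_size=16, seed=0
        ).fit(arm_traj)
        # autoencoding must do better than predicting the observation mean
        z = net._to_internal(arm_traj.observations)
        var_floor = float(np.sum(z.var(0)))
        assert net.loss_history_[-1][2] < var_floor

    def test_representation_shapes_and_determinism(self, arm_traj):
        net = RecurrentPredictor(n_units=8, max_epochs=1, seed=2).fit(arm_traj)
        r1 = collect_representations(net, arm_traj)
        r2 = collect_representations(net, arm_traj)
        assert r1.shape == (len(arm_traj), 8)
        assert np.array_equal(r1, r2)

    def test_outputs_in_observation_units(self, arm_traj):
        net = RecurrentPredictor(n_units=8, max_epochs=1, seed=2).fit(arm_traj)
        y = net.predict(arm_traj)
        assert y.shape == arm_traj.observations.shape
        lo, hi = arm_traj.observations.min(), arm_traj.observations.max()
        margin = 0.5 * (hi - lo)
        assert y.min() > lo - margin and y.max() < hi + margin


class TestFeedforwardTraining:
    def test_single_state_world_reaches_trivial_optimum(self):
        world = build_card_world(grid_shape=(1, 1), seed=0)
        traj = generate_card_trajectory(world, 2000, seed=0)
        net = FeedforwardPredictor(
            n_hidden=10, max_epochs=2, learning_rate=0.05, seed=0
        ).fit(traj)
        assert net.loss_history_[-1][2] < 1e-2

    def test_card_net_learns_deterministic_transitions(self, card_world):
        traj = generate_card_trajectory(card_world, 30_000, seed=3)
        net = FeedforwardPredictor(
            max_epochs=12, n_hidden=60, learning_rate=1e-3, seed=1
        ).fit(traj)
        obs, act = traj.observations, traj.actions_onehot()
        pred = net.predict(obs[:-1][-5000:], act[:-1][-5000:])
        acc = (pred.argmax(1) == traj.observations[1:][-5000:].argmax(1)).mean()
        assert acc > 0.95

    def test_actionless_net_bounded_by_kernel_entropy_floor(self):
        # without the action input the next observation is stochastic; the
        # optimum is the transition-kernel average, whose MSE floor follows
        # in closed form from the explicit chain
        from predrep.envs.cards import transition_matrix

        world = build_card_world(grid_shape=(3, 3), seed=0)
        traj = generate_card_trajectory(world, 30_000, seed=1)
        P = transition_matrix(world)
        pi = np.full(9, 1 / 9)
        for _ in range(2000):
            pi = pi @ P
        floor = float(np.sum(pi[:, None] * P * (1 - P)) / 9)
        net = FeedforwardPredictor(
            include_actions=False, n_hidden=40, learning_rate=1e-3,
            max_epochs=30, seed=0,
        ).fit(traj)
        val = net.loss_history_[-1][2]
        assert val >= floor - 1e-3
        assert val <= 1.2 * floor

    def test_training_failure_is_reported(self, card_world):
        traj = generate_card_trajectory(card_world, 2000, seed=3)
        with pytest.raises(RuntimeError):
            # zero learning rate: loss cannot decrease
            train_feedforward(traj, max_epochs=2, learning_rate=0.0, seed=0)

    def test_representation_probe_shape(self, card_world, card_traj):
        net = FeedforwardPredictor(n_hidden=20, max_epochs=1, seed=0).fit(card_traj)
        from predrep.experiments import card_probe

        obs, act, _ = card_probe(card_world)
        rep = net.representations(obs, act)
        assert rep.shape == (125, 20)
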
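"""Vanilla recurrent network for predictive / autoencoding training.

Dynamics and readout:

    r_t = tanh(W r_{t-1} + W_o o_t + W_a a_t)
    y_t = tanh(W_out r_t)

trained by truncated backpropagation through time under either the
predictive cost (target o_{t+1}) or the non-predictive/autoencoding cost
(target o_t), both mean-squared.  W starts at the identity; the input,
action and readout matrices start as small random normal matrices.

Observations are affinely mapped into the open interval of the tanh
readout before training (a single global offset/gain per trajectory);
predictions are mapped back to observation units, so all downstream error
curves live in the original observation space.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from predrep.models._optim import EarlyStopping, PlateauScheduler, RMSprop
from predrep.trajectory import Trajectory

__all__ = ["RecurrentPredictor", "train_rnn", "collect_representations"]


class RecurrentPredictor(BaseEstimator):
    """Sklearn-style estimator wrapping the vanilla RNN of the task suite.

    Parameters
    ----------
    n_units : recurrent width (500 at full scale; 100 for ensembles).
    mode : "predictive" (target o_{t+1}) or "non_predictive" (target o_t).
    include_actions : feed the action vector alongside the observation.
    truncation : BPTT window length.
    batch_size : number of parallel contiguous subsequences.
    max_epochs : passes over the training portion of the trajectory.
    obs_margin : observations are mapped into [-obs_margin, obs_margin].
    seed : controls weight initialization.

    Attributes (after fit)
    ----------------------
    weights_ : dict with W, W_o, W_a, W_out.
    loss_history_ : list of (epoch, train_loss, val_loss, learning_rate),
        losses in normalized observation units.
    checkpoints_ : list of (epoch, weight dict) snapshots, epoch 0 included.
    """

    def __init__(
        self,
        n_units: int = 500,
        mode: str = "predictive",
        include_actions: bool = True,
        truncation: int = 20,
        batch_size: int = 64,
        learning_rate: float = 1e-4,
        rms_alpha: float = 0.95,
        rms_eps: float = 1e-7,
        max_epochs: int = 30,
        val_fraction: float = 0.2,
        plateau_factor: float = 0.5,
        plateau_patience: int = 8,
        early_stop_patience: int = 25,
        early_stop_min_delta: float = 5e-5,
        checkpoint_every: int = 1,
        init_std: float = 0.02,
        obs_margin: float = 0.8,
        seed: int = 0,
    ):
        self.n_units = n_units
        self.mode = mode
        self.include_actions = include_actions
        self.truncation = truncation
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.rms_alpha = rms_alpha
        self.rms_eps = rms_eps
        self.max_epochs = max_epochs
        self.val_fraction = val_fraction
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.early_stop_min_delta = early_stop_min_delta
        self.checkpoint_every = checkpoint_every
        self.init_std = init_std
        self.obs_margin = obs_margin
        self.seed = seed

    # -- observation normalization ---------------------------------------

    def _fit_obs_transform(self, obs: np.ndarray) -> None:
        lo, hi = float(obs.min()), float(obs.max())
        center = 0.5 * (hi + lo)
        halfwidth = max(0.5 * (hi - lo), 1e-12)
        self.obs_center_ = center
        self.obs_gain_ = self.obs_margin / halfwidth

    def _to_internal(self, obs: np.ndarray) -> np.ndarray:
        return (obs - self.obs_center_) * self.obs_gain_

    def _to_obs_units(self, y: np.ndarray) -> np.ndarray:
        return y / self.obs_gain_ + self.obs_center_

    # -- forward / backward ----------------------------------------------

    @staticmethod
    def forward_window(
        w: dict, obs: np.ndarray, act: np.ndarray, r0: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Roll the RNN over a (T, B, ...) window from hidden state r0.

        Returns hidden states r (T, B, n) and outputs y (T, B, D)."""
        T, B = obs.shape[0], obs.shape[1]
        n = r0.shape[1]
        r = np.empty((T, B, n))
        y = np.empty((T, B, w["W_out"].shape[0]))
        prev = r0
        for t in range(T):
            pre = prev @ w["W"].T + obs[t] @ w["W_o"].T + act[t] @ w["W_a"].T
            prev = np.tanh(pre)
            r[t] = prev
            y[t] = np.tanh(r[t] @ w["W_out"].T)
        return r, y

    @staticmethod
    def backward_window(
        w: dict,
        obs: np.ndarray,
        act: np.ndarray,
        r0: np.ndarray,
        r: np.ndarray,
        y: np.ndarray,
        targets: np.ndarray,
    ) -> tuple[dict, float]:
        """Gradients of the window's mean-over-(time, batch) summed-over-dim
        squared error, truncated at the window start."""
        T, B, _ = y.shape
        norm = T * B
        loss = float(np.sum((y - targets) ** 2) / norm)
        g = {k: np.zeros_like(v) for k, v in w.items()}
        dr_next = np.zeros_like(r0)
        for t in range(T - 1, -1, -1):
            dy = 2.0 * (y[t] - targets[t]) / norm
            dz_out = dy * (1.0 - y[t] ** 2)
            g["W_out"] += dz_out.T @ r[t]
            dr = dz_out @ w["W_out"] + dr_next
            dz = dr * (1.0 - r[t] ** 2)
            rprev = r[t - 1] if t > 0 else r0
            g["W"] += dz.T @ rprev
            g["W_o"] += dz.T @ obs[t]
            g["W_a"] += dz.T @ act[t]
            dr_next = dz @ w["W"]
        return g, loss

    # -- data plumbing ----------------------------------------------------

    def _targets(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        """Input range and aligned targets; predictive mode drops the last
        step (no next observation)."""
        if self.mode == "predictive":
            return obs[:-1], obs[1:], len(obs) - 1
        if self.mode == "non_predictive":
            return obs, obs, len(obs)
        raise ValueError(f"unknown mode {self.mode!r}")

    @staticmethod
    def _chunk(x: np.ndarray, n_chunks: int) -> np.ndarray:
        """Split the leading axis into n_chunks contiguous sequences,
        arranged as (L, n_chunks, ...)."""
        L = len(x) // n_chunks
        return np.stack([x[b * L : (b + 1) * L] for b in range(n_chunks)], axis=1)

    # -- estimator API ----------------------------------------------------

    def fit(self, trajectory: Trajectory) -> "RecurrentPredictor":
        rng = np.random.default_rng(self.seed)
        obs_all = trajectory.observations
        act_all = trajectory.action_inputs()
        if not self.include_actions:
            act_all = np.zeros((len(obs_all), 1))
        self._fit_obs_transform(obs_all)
        z = self._to_internal(obs_all)
        d_obs, d_act = z.shape[1], act_all.shape[1]
        n = self.n_units
        w = {
            "W": np.eye(n),
            "W_o": rng.normal(0, self.init_std, (n, d_obs)),
            "W_a": rng.normal(0, self.init_std, (n, d_act)),
            "W_out": rng.normal(0, self.init_std, (d_obs, n)),
        }
        x, tgt, usable = self._targets(z)
        a = act_all[:usable]
        n_train = int(round((1 - self.val_fraction) * usable))
        xtr = self._chunk(x[:n_train], self.batch_size)
        atr = self._chunk(a[:n_train], self.batch_size)
        ttr = self._chunk(tgt[:n_train], self.batch_size)
        n_val_chunks = min(self.batch_size, max(1, (usable - n_train) // max(self.truncation, 1)))
        xva = self._chunk(x[n_train:], n_val_chunks)
        ava = self._chunk(a[n_train:], n_val_chunks)
        tva = self._chunk(tgt[n_train:], n_val_chunks)

        opt = RMSprop(self.learning_rate, self.rms_alpha, self.rms_eps)
        sched = PlateauScheduler(opt, self.plateau_factor, self.plateau_patience)
        stopper = EarlyStopping(self.early_stop_patience, self.early_stop_min_delta)
        self.loss_history_ = []
        self.checkpoints_ = [(0, {k: v.copy() for k, v in w.items()})]
        L = xtr.shape[0]
        for epoch in range(1, self.max_epochs + 1):
            hidden = np.zeros((self.batch_size, n))
            train_loss, n_windows = 0.0, 0
            for start in range(0, L, self.truncation):
                ow = xtr[start : start + self.truncation]
                aw = atr[start : start + self.truncation]
                tw = ttr[start : start + self.truncation]
                r, y = self.forward_window(w, ow, aw, hidden)
                grads, loss = self.backward_window(w, ow, aw, hidden, r, y, tw)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training loss diverged at epoch {epoch}")
                opt.step(w, grads)
                hidden = r[-1]  # carried, gradient-truncated
                train_loss += loss
                n_windows += 1
            train_loss /= n_windows
            _, yv = self.forward_window(w, xva, ava, np.zeros((xva.shape[1], n)))
            val_loss = float(np.sum((yv - tva) ** 2) / (yv.shape[0] * yv.shape[1]))
            self.loss_history_.append((epoch, train_loss, val_loss, opt.learning_rate))
            if epoch % self.checkpoint_every == 0:
                self.checkpoints_.append((epoch, {k: v.copy() for k, v in w.items()}))
            sched.update(val_loss)
            if stopper.should_stop(val_loss):
                break
        self.weights_ = w
        self.n_obs_dims_ = d_obs
        self.n_action_dims_ = d_act
        return self

    def rollout(
        self, trajectory: Trajectory, weights: dict | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Frozen-weight rollout on a probe trajectory.

        Returns (R, Y): hidden activations (T, n_units) and outputs mapped
        back to observation units (T, D).  Deterministic.
        """
        w = self.weights_ if weights is None else weights
        z = self._to_internal(trajectory.observations)
        act = trajectory.action_inputs()
        if not self.include_actions:
            act = np.zeros((len(z), 1))
        r, y = self.forward_window(
            w, z[:, None, :], act[:, None, :], np.zeros((1, w["W"].shape[0]))
        )
        return r[:, 0, :], self._to_obs_units(y[:, 0, :])

    def predict(self, trajectory: Trajectory) -> np.ndarray:
        """Network outputs along a trajectory, in observation units."""
        return self.rollout(trajectory)[1]


def train_rnn(trajectory: Trajectory, **config) -> tuple:
    """Functional wrapper: returns (fitted net, loss history, checkpoints)."""
    net = RecurrentPredictor(**config).fit(trajectory)
    return net, net.loss_history_, net.checkpoints_


def collect_representations(net, probe, actions: np.ndarray | None = None) -> np.ndarray:
    """Unit-activation matrix of a trained network on a probe input.

    For a :class:`RecurrentPredictor`, `probe` is a held-out trajectory and
    the result is the (T, n_units) frozen rollout.  For a
    :class:`FeedforwardPredictor`, `probe` is an (n_conditions, D) array of
    observation encodings with aligned one-hot `actions`, and the result is
    the first-layer activation per condition.
    """
    if isinstance(net, RecurrentPredictor):
        return net.rollout(probe)[0]
    if actions is None:
        raise ValueError("feedforward probing needs aligned action encodings")
    return net.representations(probe, actions)
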
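"""Two-layer feedforward predictor for the card-game task.

The network maps the current one-hot observation (and, optionally, the
one-hot action) to a prediction of the next observation:

    h1 = sigmoid(W_o o + W_a a + b1)      (the analyzed representation)
    h2 = tanh(W2 h1 + b2)
    p  = sigmoid(W3 h2 + b3)              (BCE loss, action-conditioned)

Without actions the next observation is stochastic, so the readout becomes
linear from the tanh layer and the loss mean-squared error — the optimum is
then the transition-kernel average rather than a hard classification.

The columns of W_o play the role of per-state weight vectors w_s and the
columns of W_a the per-action vectors w_a; their additive structure after
learning is what the translation-invariance analysis quantifies.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from predrep.models._optim import SGD, EarlyStopping, PlateauScheduler, RMSprop
from predrep.trajectory import Trajectory

__all__ = ["FeedforwardPredictor", "train_feedforward"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class FeedforwardPredictor(BaseEstimator):
    """Sklearn-style estimator for next-observation prediction on a lattice.

    Parameters
    ----------
    n_hidden : width of both hidden layers (default 100).
    include_actions : feed the one-hot action alongside the observation.
    optimizer : "rmsprop" or "sgd".  Plain SGD's implicit bias produces a
        markedly more translation-invariant first layer on the lattice task
        than RMSprop does at the same final loss; see the methods note.
    learning_rate : step size (scale depends on the optimizer).
    rms_alpha, rms_eps : RMSprop constants.
    max_epochs : training budget; early stopping may end sooner.
    batch_size : minibatch size for stochastic training.
    val_fraction : contiguous tail fraction held out for validation.
    checkpoint_every : epochs between stored first-layer snapshots.
    init_std : std of the normal weight initialization.
    seed : controls initialization and shuffling.

    Attributes (after fit)
    ----------------------
    weights_ : dict of weight arrays (W_o, W_a, b1, W2, b2, W3, b3).
    loss_history_ : list of (epoch, train_loss, val_loss, learning_rate).
    checkpoints_ : list of (epoch, {"W_o", "W_a", "b1"}) snapshots.
    converged_ : False if the training loss never decreased.
    """

    def __init__(
        self,
        n_hidden: int = 100,
        include_actions: bool = True,
        optimizer: str = "rmsprop",
        learning_rate: float = 1e-4,
        rms_alpha: float = 0.95,
        rms_eps: float = 1e-7,
        max_epochs: int = 60,
        batch_size: int = 64,
        val_fraction: float = 0.2,
        plateau_factor: float = 0.5,
        plateau_patience: int = 8,
        early_stop_patience: int = 25,
        early_stop_min_delta: float = 5e-5,
        checkpoint_every: int = 1,
        init_std: float = 0.1,
        seed: int = 0,
    ):
        self.n_hidden = n_hidden
        self.include_actions = include_actions
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.rms_alpha = rms_alpha
        self.rms_eps = rms_eps
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.plateau_factor = plateau_factor
        self.plateau_patience = plateau_patience
        self.early_stop_patience = early_stop_patience
        self.early_stop_min_delta = early_stop_min_delta
        self.checkpoint_every = checkpoint_every
        self.init_std = init_std
        self.seed = seed

    # -- core network -----------------------------------------------------

    def _forward(self, obs: np.ndarray, act: np.ndarray, w: dict) -> tuple:
        pre1 = obs @ w["W_o"].T + w["b1"]
        if self.include_actions:
            pre1 = pre1 + act @ w["W_a"].T
        h1 = _sigmoid(pre1)
        h2 = np.tanh(h1 @ w["W2"].T + w["b2"])
        z = h2 @ w["W3"].T + w["b3"]
        out = _sigmoid(z) if self.include_actions else z
        return h1, h2, out

    def _loss(self, out: np.ndarray, target: np.ndarray) -> float:
        if self.include_actions:  # mean binary cross-entropy
            p = np.clip(out, 1e-12, 1 - 1e-12)
            return float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
        return float(np.mean((out - target) ** 2))

    def _grads(self, obs, act, target, w) -> tuple[dict, float]:
        n = len(obs)
        h1, h2, out = self._forward(obs, act, w)
        loss = self._loss(out, target)
        d = out.shape[1]
        if self.include_actions:
            # d(BCE)/dz with sigmoid output collapses to (p - t)
            dz = (out - target) / (n * d)
        else:
            dz = 2.0 * (out - target) / (n * d)
        g = {"W3": dz.T @ h2, "b3": dz.sum(0)}
        dh2 = dz @ w["W3"]
        dz2 = dh2 * (1 - h2**2)
        g["W2"] = dz2.T @ h1
        g["b2"] = dz2.sum(0)
        dh1 = dz2 @ w["W2"]
        dz1 = dh1 * h1 * (1 - h1)
        g["W_o"] = dz1.T @ obs
        g["b1"] = dz1.sum(0)
        if self.include_actions:
            g["W_a"] = dz1.T @ act
        return g, loss

    # -- estimator API ----------------------------------------------------

    def fit(self, trajectory: Trajectory) -> "FeedforwardPredictor":
        """Train on next-observation prediction over the trajectory."""
        rng = np.random.default_rng(self.seed)
        obs = trajectory.observations
        act = trajectory.actions_onehot()
        d_obs, d_act = obs.shape[1], act.shape[1]
        w = {
            "W_o": rng.normal(0, self.init_std, (self.n_hidden, d_obs)),
            "W_a": rng.normal(0, self.init_std, (self.n_hidden, d_act)),
            "b1": np.zeros(self.n_hidden),
            "W2": rng.normal(0, self.init_std, (self.n_hidden, self.n_hidden)),
            "b2": np.zeros(self.n_hidden),
            "W3": rng.normal(0, self.init_std, (d_obs, self.n_hidden)),
            "b3": np.zeros(d_obs),
        }
        # inputs at t, targets at t+1; contiguous tail validation split
        x_obs, x_act, target = obs[:-1], act[:-1], obs[1:]
        n_train = int(round((1 - self.val_fraction) * len(x_obs)))
        if self.optimizer == "rmsprop":
            opt = RMSprop(self.learning_rate, self.rms_alpha, self.rms_eps)
        elif self.optimizer == "sgd":
            opt = SGD(self.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        sched = PlateauScheduler(opt, self.plateau_factor, self.plateau_patience)
        stopper = EarlyStopping(self.early_stop_patience, self.early_stop_min_delta)

        self.loss_history_ = []
        self.checkpoints_ = [(0, {k: w[k].copy() for k in ("W_o", "W_a", "b1")})]
        first_loss, best_train = None, np.inf
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n_train)
            train_loss = 0.0
            for i in range(0, n_train, self.batch_size):
                idx = order[i : i + self.batch_size]
                grads, loss = self._grads(x_obs[idx], x_act[idx], target[idx], w)
                opt.step(w, grads)
                train_loss += loss * len(idx)
            train_loss /= n_train
            _, _, val_out = self._forward(x_obs[n_train:], x_act[n_train:], w)
            val_loss = self._loss(val_out, target[n_train:])
            self.loss_history_.append((epoch, train_loss, val_loss, opt.learning_rate))
            if first_loss is None:
                first_loss = train_loss
            best_train = min(best_train, train_loss)
            if epoch % self.checkpoint_every == 0:
                self.checkpoints_.append(
                    (epoch, {k: w[k].copy() for k in ("W_o", "W_a", "b1")})
                )
            sched.update(val_loss)
            if stopper.should_stop(val_loss):
                break
        self.weights_ = w
        self.n_obs_dims_ = d_obs
        self.n_action_dims_ = d_act
        self.converged_ = bool(best_train < first_loss) if first_loss is not None else False
        return self

    def predict(self, obs: np.ndarray, act: np.ndarray | None = None) -> np.ndarray:
        """Predicted next-observation vector for given (obs, action) inputs."""
        if act is None:
            act = np.zeros((len(obs), self.n_action_dims_))
        return self._forward(obs, act, self.weights_)[2]

    def representations(
        self, obs: np.ndarray, act: np.ndarray, weights: dict | None = None
    ) -> np.ndarray:
        """First-layer activations (the analyzed representation)."""
        w = dict(self.weights_ if weights is None else {**self.weights_, **weights})
        return self._forward(obs, act, w)[0]


def train_feedforward(trajectory: Trajectory, **config) -> tuple:
    """Functional wrapper: returns (fitted net, loss history, checkpoints).

    Raises RuntimeError if the training loss never decreased over the
    budget, rather than silently returning an untrained model.
    """
    net = FeedforwardPredictor(**config).fit(trajectory)
    if not net.converged_:
        raise RuntimeError("feedforward training failed: loss never decreased")
    return net, net.loss_history_, net.checkpoints_
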
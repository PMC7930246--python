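"""Two-joint, six-muscle planar arm driven by correlated binary pulses.

A deliberately simple kinematic arm: six binary muscle channels (two
antagonists per joint plus two biarticular muscles) are low-pass filtered
into activations, mapped through a signed moment-arm matrix to torques at
the shoulder (alpha) and elbow (beta), and integrated with viscous damping
by explicit Euler.  The latent space is the two joint angles; observations
are the (x, y) positions of the elbow and wrist relative to the shoulder,
a smooth trigonometric function of the angles.  The muscle pulse trains are
independent two-state Markov chains, giving temporally correlated actions
analogous to the coherent walk of the spatial task.

Convention: alpha is the angle between the upper arm and the shoulder
line; beta is the interior elbow angle, so beta = pi is a straight arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from predrep.trajectory import Trajectory

__all__ = [
    "ArmParams",
    "ArmState",
    "generate_muscle_pulses",
    "arm_dynamics_step",
    "forward_kinematics",
    "generate_arm_trajectory",
]


def _default_moment_arms() -> np.ndarray:
    # columns: shoulder flexor/extensor, elbow flexor/extensor,
    # biarticular flexor/extensor (acting on both joints)
    return np.array(
        [
            [0.01, -0.01, 0.0, 0.0, 0.005, -0.005],
            [0.0, 0.0, 0.01, -0.01, 0.005, -0.005],
        ]
    )


@dataclass
class ArmParams:
    """Geometry, muscle filter, and integration constants of the arm."""

    upperarm_length: float = 0.3
    forearm_length: float = 0.33
    moment_arm_matrix: np.ndarray = field(default_factory=_default_moment_arms)
    muscle_time_constant: float = 10.0  # steps
    damping: float = 0.2  # per step
    alpha_limits: tuple[float, float] = (0.2, 2.9)
    beta_limits: tuple[float, float] = (0.3, 2.9)
    dt: float = 1.0  # one simulation step

    def __post_init__(self) -> None:
        self.moment_arm_matrix = np.asarray(self.moment_arm_matrix, dtype=float)
        if self.upperarm_length <= 0 or self.forearm_length <= 0:
            raise ValueError("segment lengths must be positive")
        if self.moment_arm_matrix.shape != (2, 6):
            raise ValueError("moment_arm_matrix must be 2x6")
        if np.any(np.all(self.moment_arm_matrix == 0, axis=0)):
            raise ValueError("every muscle column must be nonzero")
        for j in range(2):
            row = self.moment_arm_matrix[j]
            if not (np.any(row > 0) and np.any(row < 0)):
                raise ValueError(f"joint {j} needs antagonist torque directions")


@dataclass
class ArmState:
    """Joint angles, angular velocities, and filtered muscle activations."""

    alpha: float
    beta: float
    alpha_vel: float = 0.0
    beta_vel: float = 0.0
    activations: np.ndarray = field(default_factory=lambda: np.zeros(6))


def generate_muscle_pulses(
    n_steps: int, flip_probability: float = 0.05, seed: int = 0
) -> np.ndarray:
    """Six independent binary Markov chains, shape (6, n_steps).

    Each channel flips state with the given symmetric probability per step,
    so on/off runs have geometric length 1 / flip_probability on average.
    """
    if not 0.0 < flip_probability < 1.0:
        raise ValueError("flip_probability must be in (0, 1)")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    flips = rng.random((6, n_steps)) < flip_probability
    start = rng.integers(0, 2, size=(6, 1))
    # cumulative parity of flips determines the state at each step
    return ((start + np.cumsum(flips, axis=1)) % 2).astype(np.int64)


def arm_dynamics_step(state: ArmState, pulses_t: np.ndarray, params: ArmParams) -> ArmState:
    """Advance the arm one step: filter pulses, apply torques, integrate.

    Activations follow a first-order low pass of the binary pulses; joint
    torques are moment_arm_matrix @ activations minus viscous damping;
    angles are clipped to the joint limits with velocity zeroed there.
    """
    if not np.all(np.isfinite([state.alpha, state.beta, state.alpha_vel, state.beta_vel])):
        raise FloatingPointError("non-finite arm state")
    act = state.activations + (np.asarray(pulses_t, float) - state.activations) / params.muscle_time_constant
    torque = params.moment_arm_matrix @ act
    vel = np.array([state.alpha_vel, state.beta_vel])
    vel = vel + params.dt * (torque - params.damping * vel)
    ang = np.array([state.alpha, state.beta]) + params.dt * vel
    for j, lim in enumerate((params.alpha_limits, params.beta_limits)):
        if ang[j] <= lim[0]:
            ang[j], vel[j] = lim[0], 0.0
        elif ang[j] >= lim[1]:
            ang[j], vel[j] = lim[1], 0.0
    return ArmState(ang[0], ang[1], vel[0], vel[1], act)


def forward_kinematics(alpha: float, beta: float, params: ArmParams) -> np.ndarray:
    """Elbow and wrist (x, y) relative to the shoulder, flattened length 4."""
    l1, l2 = params.upperarm_length, params.forearm_length
    elbow = l1 * np.array([np.cos(alpha), np.sin(alpha)])
    wrist = elbow + l2 * np.array([np.cos(alpha + beta - np.pi), np.sin(alpha + beta - np.pi)])
    return np.concatenate([elbow, wrist])


def generate_arm_trajectory(
    params: ArmParams | None = None,
    n_steps: int = 100_000,
    seed: int = 0,
    flip_probability: float = 0.05,
) -> Trajectory:
    """Simulate exploratory arm movement under random muscle pulses.

    Latents are (alpha, beta); actions are the 6-dim binary pulse vectors
    (stored as integer codes 0..63 plus the raw pulse matrix in the
    observation pipeline via :meth:`Trajectory.actions_onehot` override);
    observations are the 4 limb coordinates normalized by the arm length.
    """
    params = params or ArmParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    pulses = generate_muscle_pulses(n_steps, flip_probability, seed)
    rng = np.random.default_rng(seed + 1)
    state = ArmState(
        alpha=float(rng.uniform(*params.alpha_limits)),
        beta=float(rng.uniform(*params.beta_limits)),
    )
    latents = np.empty((n_steps, 2))
    observations = np.empty((n_steps, 4))
    scale = params.upperarm_length + params.forearm_length
    for t in range(n_steps):
        latents[t] = (state.alpha, state.beta)
        observations[t] = forward_kinematics(state.alpha, state.beta, params) / scale
        try:
            state = arm_dynamics_step(state, pulses[:, t], params)
        except FloatingPointError as err:
            raise FloatingPointError(f"arm dynamics diverged at step {t}") from err
    codes = np.einsum("ct,c->t", pulses, 2 ** np.arange(6)).astype(np.int64)
    return Trajectory(
        states=latents.copy(),
        actions=codes,
        observations=observations,
        n_action_classes=64,
        latents=latents,
        # networks take the 6 raw pulse channels as the action input,
        # not a 64-way one-hot
        action_vectors=pulses.T.astype(np.float64),
        meta={
            "env": "arm",
            "seed": seed,
            "flip_probability": flip_probability,
            "upperarm_length": params.upperarm_length,
            "forearm_length": params.forearm_length,
            "normalization": scale,
            "action_encoding": "muscle_pulses",
        },
    )
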
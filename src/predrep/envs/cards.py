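"""Card-game lattice world.

States live on a small d-dimensional lattice (default 5x5).  Each state is
assigned a random hand of cards from a fixed deck; that hand is the state's
observation and carries no information at all about where the state sits on
the lattice.  Actions, by contrast, are defined on the lattice: unit moves
along each axis plus a null action.  A network that learns to predict the
next observation from (observation, action) can therefore only exploit the
lattice through the action structure — which is exactly the effect the
representation analyses measure.

Action encoding: code 0 is the null action; codes ``1 + 2*axis`` and
``2 + 2*axis`` are +1 / -1 moves along ``axis``.  On a 2-D grid with the
x-east / y-north convention this gives 0=stay, 1=E, 2=W, 3=N, 4=S and
``N_a = 5``; a 3-D grid has ``N_a = 7``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from predrep.trajectory import Trajectory

__all__ = [
    "CardWorld",
    "ACTION_NAMES_2D",
    "build_card_world",
    "lattice_step",
    "valid_actions",
    "generate_card_trajectory",
    "encode_card_observation",
]

ACTION_NAMES_2D = {"0": 0, "E": 1, "W": 2, "N": 3, "S": 4}


class InvalidMoveError(ValueError):
    """Raised when an action would carry the agent off the lattice."""


@dataclass
class CardWorld:
    """Lattice of states, each holding a fixed random hand of cards."""

    grid_shape: tuple[int, ...]
    deck_size: int
    cards_per_state: int
    card_sets: dict[tuple[int, ...], tuple[int, ...]]
    seed: int
    # class index of each state's card set among the distinct sets
    set_classes: dict[tuple[int, ...], int] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def n_actions(self) -> int:
        return 1 + 2 * len(self.grid_shape)

    @property
    def n_set_classes(self) -> int:
        return len(set(self.set_classes.values()))

    def all_states(self) -> list[tuple[int, ...]]:
        return [tuple(idx) for idx in np.ndindex(*self.grid_shape)]

    def state_index(self, state: tuple[int, ...]) -> int:
        return int(np.ravel_multi_index(state, self.grid_shape))


def build_card_world(
    grid_shape: tuple[int, ...] = (5, 5),
    deck_size: int = 40,
    cards_per_state: int = 5,
    seed: int = 0,
) -> CardWorld:
    """Assign each lattice state an independent random hand of cards.

    Hands are drawn without replacement within a state (``cards_per_state``
    distinct card ids out of ``deck_size``) and independently across states.
    Deterministic given ``seed``.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g < 1 for g in grid_shape):
        raise ValueError("all grid extents must be >= 1")
    if cards_per_state > deck_size:
        raise ValueError("cards_per_state cannot exceed deck_size")
    rng = np.random.default_rng(seed)
    card_sets: dict[tuple[int, ...], tuple[int, ...]] = {}
    for state in np.ndindex(*grid_shape):
        hand = rng.choice(deck_size, size=cards_per_state, replace=False)
        card_sets[tuple(state)] = tuple(int(c) for c in hand)
    # distinct-set class labels (hands could collide, though it is unlikely)
    classes: dict[tuple[int, ...], int] = {}
    set_classes = {}
    for state, hand in card_sets.items():
        key = tuple(sorted(hand))
        if key not in classes:
            classes[key] = len(classes)
        set_classes[state] = classes[key]
    return CardWorld(grid_shape, deck_size, cards_per_state, card_sets, seed, set_classes)


def _action_displacement(action: int, ndim: int) -> np.ndarray:
    disp = np.zeros(ndim, dtype=np.int64)
    if action == 0:
        return disp
    axis, sign = divmod(action - 1, 2)
    if axis >= ndim:
        raise ValueError(f"action {action} invalid for a {ndim}-D grid")
    disp[axis] = 1 if sign == 0 else -1
    return disp


def lattice_step(
    state: tuple[int, ...], action: int | str, grid_shape: tuple[int, ...]
) -> tuple[int, ...]:
    """Apply a unit lattice move; the null action returns the same state.

    Raises :class:`InvalidMoveError` if the move leaves the grid — callers
    must never sample such an action.
    """
    if isinstance(action, str):
        action = ACTION_NAMES_2D[action]
    disp = _action_displacement(int(action), len(grid_shape))
    new = tuple(int(c + d) for c, d in zip(state, disp))
    for c, extent in zip(new, grid_shape):
        if not 0 <= c < extent:
            raise InvalidMoveError(f"action {action} leaves the grid from {state}")
    return new


def valid_actions(state: tuple[int, ...], grid_shape: tuple[int, ...]) -> list[int]:
    """Actions that keep the agent on the lattice (null action always valid)."""
    out = [0]
    for axis, extent in enumerate(grid_shape):
        if state[axis] + 1 < extent:
            out.append(1 + 2 * axis)
        if state[axis] - 1 >= 0:
            out.append(2 + 2 * axis)
    return out


def encode_card_observation(
    world: CardWorld, state: tuple[int, ...], scheme: str = "one_hot_state_class"
) -> np.ndarray:
    """Encode a state's hand of cards as a binary observation vector.

    ``one_hot_state_class``
        One 1 at the index of the state's distinct-card-set class; length is
        the number of distinct sets (normally ``n_states``).
    ``multi_hot_cards``
        Length ``deck_size`` with a 1 per card in the hand.
    """
    if scheme == "one_hot_state_class":
        vec = np.zeros(world.n_set_classes)
        vec[world.set_classes[tuple(state)]] = 1.0
        return vec
    if scheme == "multi_hot_cards":
        vec = np.zeros(world.deck_size)
        vec[list(world.card_sets[tuple(state)])] = 1.0
        return vec
    raise ValueError(f"unknown observation scheme: {scheme!r}")


def generate_card_trajectory(
    world: CardWorld,
    n_steps: int,
    seed: int = 0,
    scheme: str = "one_hot_state_class",
    start: tuple[int, ...] | None = None,
) -> Trajectory:
    """Random walk on the lattice with uniformly sampled valid actions.

    At each step the action is drawn uniformly from the actions that do not
    leave the grid (boundary-excluded sampling), so every emitted
    (state, action) pair is legal.  Observations are the card-hand encodings
    of the visited states.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    ndim = len(world.grid_shape)
    state = tuple([0] * ndim) if start is None else tuple(start)

    obs_table = {s: encode_card_observation(world, s, scheme) for s in world.all_states()}
    valid_table = {s: np.array(valid_actions(s, world.grid_shape)) for s in world.all_states()}

    states = np.empty((n_steps, ndim), dtype=np.int64)
    actions = np.empty(n_steps, dtype=np.int64)
    observations = np.empty((n_steps, len(next(iter(obs_table.values())))))
    for t in range(n_steps):
        states[t] = state
        observations[t] = obs_table[state]
        acts = valid_table[state]
        a = int(acts[rng.integers(len(acts))])
        actions[t] = a
        state = lattice_step(state, a, world.grid_shape)
    return Trajectory(
        states=states,
        actions=actions,
        observations=observations,
        n_action_classes=world.n_actions,
        latents=states.astype(np.float64),
        meta={
            "env": "cards",
            "seed": seed,
            "scheme": scheme,
            "grid_shape": list(world.grid_shape),
            "deck_size": world.deck_size,
            "cards_per_state": world.cards_per_state,
            "world_seed": world.seed,
        },
    )


def transition_matrix(world: CardWorld) -> np.ndarray:
    """Explicit state-transition matrix of the boundary-excluded walk.

    Row s gives the distribution of the next state when the action is drawn
    uniformly from the valid actions at s.  Used as a small-chain oracle for
    occupancy and loss-floor computations.
    """
    n = world.n_states
    P = np.zeros((n, n))
    for s in world.all_states():
        i = world.state_index(s)
        acts = valid_actions(s, world.grid_shape)
        for a in acts:
            j = world.state_index(lattice_step(s, a, world.grid_shape))
            P[i, j] += 1.0 / len(acts)
    return P
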
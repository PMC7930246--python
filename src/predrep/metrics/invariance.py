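"""Translation-invariance score of the card-network first layer.

After learning, the lattice action a should act on the first-layer state
vectors additively: w_{s'} - w_s is (approximately) the same vector for
every state pair (s, s') linked by a.  The score measures, per action, the
mean pairwise dispersion of these difference vectors relative to their
mean norm, averaged over the four move actions.  Exact translational
invariance gives 0; independent random weight columns give about sqrt(2).
"""

from __future__ import annotations

import numpy as np

from predrep.envs.cards import CardWorld, InvalidMoveError, lattice_step

__all__ = ["translation_invariance_score", "random_weight_baseline"]


def _linked_deltas(weights: np.ndarray, world: CardWorld, action: int) -> np.ndarray:
    """Difference vectors w_{s'} - w_s over all pairs linked by `action`.

    `weights` has one column per state-class; states map to columns through
    the world's card-set class index.
    """
    deltas = []
    for s in world.all_states():
        try:
            s2 = lattice_step(s, action, world.grid_shape)
        except InvalidMoveError:
            continue
        deltas.append(weights[:, world.set_classes[s2]] - weights[:, world.set_classes[s]])
    return np.array(deltas)


def translation_invariance_score(first_layer_weights: np.ndarray, world: CardWorld) -> float:
    """0 for exact additive action structure; ~sqrt(2) for random weights.

    `first_layer_weights` is the observation block of the first layer
    (n_hidden, n_state_classes), one column per one-hot observation class.
    """
    w = np.asarray(first_layer_weights, float)
    move_actions = range(1, world.n_actions)
    ratios = []
    for a in move_actions:
        deltas = _linked_deltas(w, world, a)
        if len(deltas) == 0:
            continue
        scale = np.mean(np.linalg.norm(deltas, axis=1))
        if scale == 0:
            ratios.append(0.0)
            continue
        diff = deltas[:, None, :] - deltas[None, :, :]
        iu = np.triu_indices(len(deltas), k=1)
        dispersion = np.mean(np.linalg.norm(diff[iu], axis=1))
        ratios.append(dispersion / scale)
    if not ratios:
        raise ValueError("world has no linked state pairs")
    return float(np.mean(ratios))


def random_weight_baseline(
    world: CardWorld, n_hidden: int = 100, n_draws: int = 20, seed: int = 0
) -> float:
    """Monte-Carlo score of i.i.d. normal weight columns (untrained regime)."""
    rng = np.random.default_rng(seed)
    scores = [
        translation_invariance_score(
            rng.normal(size=(n_hidden, world.n_set_classes)), world
        )
        for _ in range(n_draws)
    ]
    return float(np.mean(scores))
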
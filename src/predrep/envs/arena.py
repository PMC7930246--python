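"""Colored-wall square arena with a coherent heading-diffusion random walk.

The environment is a ``size x size`` grid of tiles.  Every boundary tile is
a wall carrying an RGB color; colors are drawn i.i.d. uniform per channel
and then smoothed along the unrolled wall perimeter with a wrap-around
Gaussian kernel, giving nearby wall tiles correlated colors.  All interior
tiles are free.

The agent carries a continuous heading angle theta.  At every step theta
diffuses by a Gaussian increment; the agent then moves to whichever of the
eight neighboring tiles is best aligned with the new heading, or stays put
if that tile is a wall (in which case the next heading increment is drawn
with doubled variance).  A coherence rule keeps heading increments turning
toward the direction of the last executed move.  Actions are allocentric:
a 9-way code (8 compass moves + stay) reporting the move actually executed.

Observations come from 5 sensors spanning a 90-degree cone centered on the
heading; each reports the distance to the wall along its ray and the RGB
color of the wall tile hit, for a 20-dimensional observation vector.
Because walls exist only on the boundary, ray hits are computed in closed
form (exact first crossing of the interior box), not by sampled marching.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from predrep.trajectory import Trajectory

__all__ = [
    "Arena",
    "AgentState",
    "WalkConfig",
    "build_arena",
    "random_walk_step",
    "sense",
    "sense_batch",
    "generate_spatial_trajectory",
]

# compass angles of the 8 neighbor moves, code k -> angle k*45 deg, 0 = East
COMPASS = np.arange(8) * (np.pi / 4)
STAY_CODE = 8
N_ACTIONS = 9
SENSOR_OFFSETS = np.deg2rad([-45.0, -22.5, 0.0, 22.5, 45.0])
_MOVES = np.stack([np.rint(np.cos(COMPASS)), np.rint(np.sin(COMPASS))], 1).astype(int)


@dataclass
class Arena:
    """Square tile grid whose boundary tiles are colored walls."""

    size: int
    colors: np.ndarray  # (size, size, 3); defined on wall tiles
    smoothing_variance: float
    seed: int
    n_sensors: int = 5
    cone_width_deg: float = 90.0

    def is_wall(self, cell: tuple[int, int]) -> bool:
        i, j = cell
        return i == 0 or j == 0 or i == self.size - 1 or j == self.size - 1

    @property
    def diagonal(self) -> float:
        return self.size * np.sqrt(2.0)

    def free_cells(self) -> list[tuple[int, int]]:
        return [
            (i, j)
            for i in range(1, self.size - 1)
            for j in range(1, self.size - 1)
        ]


@dataclass
class AgentState:
    """Agent pose: occupied cell, heading, and walk bookkeeping."""

    cell: tuple[int, int]
    heading: float
    last_move_dir: float | None = None  # compass angle of last executed move
    blocked: bool = False  # last step hit a wall -> next dtheta doubled


@dataclass
class WalkConfig:
    """Heading-diffusion parameters of the coherent random walk (rad^2)."""

    heading_variance: float = 0.5
    blocked_variance: float = 1.0
    enforce_coherence: bool = True

    def __post_init__(self) -> None:
        if self.heading_variance <= 0 or self.blocked_variance <= 0:
            raise ValueError("variances must be positive")


def _perimeter_cells(size: int) -> list[tuple[int, int]]:
    """Boundary tiles in contiguous order around the perimeter."""
    cells = []
    cells += [(i, 0) for i in range(size - 1)]  # south edge, W->E
    cells += [(size - 1, j) for j in range(size - 1)]  # east edge, S->N
    cells += [(i, size - 1) for i in range(size - 1, 0, -1)]  # north edge, E->W
    cells += [(0, j) for j in range(size - 1, 0, -1)]  # west edge, N->S
    return cells


def build_arena(size: int = 64, smoothing_variance: float = 2.0, seed: int = 0) -> Arena:
    """Color the wall perimeter with smoothed random RGB values.

    Each perimeter tile gets an i.i.d. uniform [0, 1] color per channel;
    each channel is then convolved along the unrolled perimeter (with
    wrap-around) with a Gaussian kernel of the given variance (tiles^2).
    """
    if size < 4:
        raise ValueError("arena size must be >= 4")
    rng = np.random.default_rng(seed)
    perim = _perimeter_cells(size)
    raw = rng.uniform(0.0, 1.0, size=(len(perim), 3))
    sigma = float(np.sqrt(smoothing_variance))
    smoothed = gaussian_filter1d(raw, sigma=sigma, axis=0, mode="wrap") if sigma > 0 else raw
    colors = np.full((size, size, 3), np.nan)
    for (i, j), c in zip(perim, smoothed):
        colors[i, j] = c
    return Arena(size=size, colors=colors, smoothing_variance=smoothing_variance, seed=seed)


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def random_walk_step(
    arena: Arena, state: AgentState, config: WalkConfig, rng: np.random.Generator
) -> tuple[AgentState, int]:
    """One step of the coherent heading-diffusion walk.

    Returns the new agent state and the executed action code (0-7 compass,
    8 = stay).  If the best-aligned neighbor is a wall the agent stays and
    the *next* heading increment uses the doubled (blocked) variance.
    """
    if arena.is_wall(state.cell):
        raise ValueError("agent is on a wall cell")
    var = config.blocked_variance if state.blocked else config.heading_variance
    dtheta = rng.normal(0.0, np.sqrt(var))
    if config.enforce_coherence and state.last_move_dir is not None:
        # turn toward the last executed move: flip the increment when
        # dtheta * wrap(theta - d_a) is negative
        if dtheta * wrap_angle(state.heading - state.last_move_dir) < 0:
            dtheta = -dtheta
    heading = float(wrap_angle(state.heading + dtheta)) % (2 * np.pi)
    code = int(np.rint(heading / (np.pi / 4))) % 8
    target = (state.cell[0] + _MOVES[code, 0], state.cell[1] + _MOVES[code, 1])
    if arena.is_wall(target):
        new = replace(state, heading=heading, blocked=True)
        return new, STAY_CODE
    new = AgentState(
        cell=target, heading=heading, last_move_dir=float(COMPASS[code]), blocked=False
    )
    return new, code


def _ray_hits(
    arena: Arena, px: np.ndarray, py: np.ndarray, angles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact first wall crossing for rays from interior points.

    Walls occupy exactly the tiles outside the interior box
    [1, size-1] x [1, size-1], so the hit is the first crossing of that box.
    Returns (entry distance, wall cell index array (..., 2)).
    """
    n = arena.size
    dx, dy = np.cos(angles), np.sin(angles)
    with np.errstate(divide="ignore"):
        tx = np.where(dx > 0, (n - 1 - px) / dx, np.where(dx < 0, (1 - px) / dx, np.inf))
        ty = np.where(dy > 0, (n - 1 - py) / dy, np.where(dy < 0, (1 - py) / dy, np.inf))
    t = np.minimum(tx, ty)
    eps = 1e-9
    hx = np.clip(np.floor(px + (t + eps) * dx).astype(int), 0, n - 1)
    hy = np.clip(np.floor(py + (t + eps) * dy).astype(int), 0, n - 1)
    return t, np.stack([hx, hy], axis=-1)


def sense_batch(arena: Arena, cells: np.ndarray, headings: np.ndarray) -> np.ndarray:
    """Vectorized sensing: (T, 2) cells + (T,) headings -> (T, 20) observations.

    Per sensor: normalized distance (raw distance / arena diagonal) followed
    by the RGB color of the wall tile hit.  Raw distance is the ray's entry
    distance into the wall tile plus half a tile, i.e. the center-to-center
    distance for a squarely faced wall.
    """
    cells = np.asarray(cells)
    px = cells[:, 0] + 0.5
    py = cells[:, 1] + 0.5
    angles = headings[:, None] + SENSOR_OFFSETS[None, :]
    t, hit = _ray_hits(arena, px[:, None], py[:, None], angles)
    raw = t + 0.5
    rgb = arena.colors[hit[..., 0], hit[..., 1]]  # (T, 5, 3)
    obs = np.concatenate([(raw / arena.diagonal)[..., None], rgb], axis=-1)
    return obs.reshape(len(cells), arena.n_sensors * 4)


def sense(arena: Arena, state: AgentState) -> np.ndarray:
    """20-dimensional observation from the agent's current pose."""
    if arena.is_wall(state.cell):
        raise ValueError("agent is on a wall cell")
    return sense_batch(arena, np.array([state.cell]), np.array([state.heading]))[0]


def generate_spatial_trajectory(
    arena: Arena,
    walk_config: WalkConfig | None = None,
    n_steps: int = 100_000,
    seed: int = 0,
) -> Trajectory:
    """Simulate the coherent walk and the 5-sensor observation stream.

    Latents are (x, y, theta) with x, y the occupied cell indices; actions
    are the executed 9-way codes; observations the 20-dim sensor vectors.
    Deterministic given (arena, config, seed).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    config = walk_config or WalkConfig()
    rng = np.random.default_rng(seed)
    c = arena.size // 2
    state = AgentState(cell=(c, c), heading=float(rng.uniform(0, 2 * np.pi)))
    cells = np.empty((n_steps, 2), dtype=np.int64)
    headings = np.empty(n_steps)
    actions = np.empty(n_steps, dtype=np.int64)
    for tstep in range(n_steps):
        cells[tstep] = state.cell
        headings[tstep] = state.heading
        state, actions[tstep] = random_walk_step(arena, state, config, rng)
    observations = sense_batch(arena, cells, headings)
    latents = np.column_stack([cells.astype(float), headings])
    return Trajectory(
        states=np.column_stack([cells, headings]),
        actions=actions,
        observations=observations,
        n_action_classes=N_ACTIONS,
        latents=latents,
        meta={
            "env": "arena",
            "seed": seed,
            "size": arena.size,
            "arena_seed": arena.seed,
            "smoothing_variance": arena.smoothing_variance,
            "heading_variance": config.heading_variance,
            "blocked_variance": config.blocked_variance,
            "distance_normalization": arena.diagonal,
        },
    )


def save_wall_image(arena: Arena, path: str) -> None:
    """Dump the wall coloring as a plain PPM image for visual inspection."""
    img = np.nan_to_num(arena.colors, nan=1.0)
    data = (img.transpose(1, 0, 2)[::-1] * 255).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(f"P6 {arena.size} {arena.size} 255\n".encode())
        fh.write(data.tobytes())
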
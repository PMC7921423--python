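"""Rejection kinetic Monte Carlo (rKMC) simulator of protein clustering
under macromolecular crowding.

The model places two species on a bounded 2D square lattice with single
occupancy: *ASK3 units*, which diffuse freely (rate ``k1``) but pay an
exponential penalty ``k3 = A * exp(-n_lost * dE/theta)`` for moves that break
ASK3-ASK3 nearest-neighbour contacts, and inert *obstacles* representing
virtually integrated crowder macromolecules, which diffuse slowly (rate
``k5``) and form no attractive contacts.

One iteration picks a molecule uniformly at random, picks one of its four
von Neumann neighbour squares uniformly, classifies the move, and accepts it
iff its rate constant ``k`` exceeds a fresh uniform draw ``r`` in [0, 1).
Moves off the grid edge and moves onto an occupied square (reflection,
exchange/vibration) leave the molecule in place and consume no acceptance
draw. Hard walls, not periodic boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "EMPTY",
    "ASK3",
    "OBSTACLE",
    "LatticeConfig",
    "LatticeState",
    "MoveProposal",
    "RateModel",
    "KmcRandom",
    "initialize",
    "count_contacts",
    "classify_move",
    "rate_for",
    "step",
    "run",
    "expand_grid",
]

EMPTY, ASK3, OBSTACLE = 0, 1, 2

# von Neumann neighbourhood, fixed order: +x, -x, +y, -y
_DX = (1, -1, 0, 0)
_DY = (0, 0, 1, -1)


@dataclass(frozen=True)
class LatticeConfig:
    """Simulation parameters.

    Defaults are the study conditions: 500 ASK3 units with 1500 obstacles on
    a 120x120 grid, k1 = 1 (free ASK3 diffusion always accepted), k5 = 0.01
    (slow obstacle diffusion), contact-loss penalty prefactor A = 1 and
    energy per contact dE/theta = 1 so that k3 = 1 when no contact is lost.
    """

    width: int = 120
    height: int = 120
    n_ask3: int = 500
    n_obstacles: int = 1500
    A: float = 1.0
    dE_over_theta: float = 1.0
    k1: float = 1.0
    k5: float = 0.01
    seed: int = 0
    record_every: int = 100_000

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_ask3 < 0 or self.n_obstacles < 0:
            raise ValueError("molecule counts must be >= 0")
        if self.n_ask3 + self.n_obstacles > self.width * self.height:
            raise ValueError(
                f"{self.n_ask3} + {self.n_obstacles} molecules exceed "
                f"{self.width * self.height} grid squares"
            )
        for name in ("k1", "k5"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.A <= 0.0:
            raise ValueError("A must be > 0")
        if self.dE_over_theta < 0.0:
            raise ValueError("dE_over_theta must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass
class RateModel:
    """Maps a classified move to its acceptance rate.

    ``k2`` (exchange/vibration) and ``k4``, ``k6``, ``k7`` (reflections) are
    dummy constants: those move classes deterministically keep the molecule
    in place, so their rates are never compared with a random draw.
    """

    k1: float = 1.0
    k5: float = 0.01
    A: float = 1.0
    dE_over_theta: float = 1.0

    @classmethod
    def from_config(cls, config: LatticeConfig) -> "RateModel":
        return cls(
            k1=config.k1,
            k5=config.k5,
            A=config.A,
            dE_over_theta=config.dE_over_theta,
        )

    def k3(self, n_lost: int) -> float:
        """Penalty rate for an ASK3 move losing ``n_lost`` contacts."""
        if n_lost < 0:
            raise ValueError("n_lost must be >= 0")
        return self.A * math.exp(-n_lost * self.dE_over_theta)


@dataclass(frozen=True)
class MoveProposal:
    """A classified candidate move of one molecule to a neighbour square."""

    molecule: int
    origin: tuple[int, int]
    destination: tuple[int, int]
    move_class: str  # ask3_free | ask3_penalized | ask3_exchange |
    #                  obstacle_free | reflect_out_of_bounds | reflect_occupied
    n_lost: int = 0


class LatticeState:
    """Occupancy grid plus molecule registry.

    The grid and the per-molecule position arrays are kept mutually
    consistent; species counts never change during a run. Coordinates are
    0-based with ``x`` the column and ``y`` the row.
    """

    __slots__ = ("width", "height", "_grid", "xs", "ys", "kinds", "step")

    def __init__(
        self,
        width: int,
        height: int,
        xs: list[int],
        ys: list[int],
        kinds: list[int],
        step: int = 0,
    ):
        self.width = width
        self.height = height
        self.xs = list(xs)
        self.ys = list(ys)
        self.kinds = list(kinds)
        self.step = step
        self._grid = [[EMPTY] * width for _ in range(height)]
        for i, (x, y, kind) in enumerate(zip(self.xs, self.ys, self.kinds)):
            if not (0 <= x < width and 0 <= y < height):
                raise ValueError(f"molecule {i} at ({x}, {y}) is out of bounds")
            if self._grid[y][x] != EMPTY:
                raise ValueError(f"square ({x}, {y}) occupied twice")
            self._grid[y][x] = kind

    @property
    def n_molecules(self) -> int:
        return len(self.kinds)

    @property
    def n_ask3(self) -> int:
        return sum(1 for k in self.kinds if k == ASK3)

    @property
    def n_obstacles(self) -> int:
        return sum(1 for k in self.kinds if k == OBSTACLE)

    def occupancy(self) -> np.ndarray:
        """Occupancy grid as an (height, width) int8 array."""
        return np.array(self._grid, dtype=np.int8)

    def ask3_mask(self) -> np.ndarray:
        """Boolean (height, width) mask of squares holding an ASK3 unit."""
        return self.occupancy() == ASK3

    def kind_at(self, x: int, y: int) -> int:
        if not (0 <= x < self.width and 0 <= y < self.height):
            raise IndexError(f"({x}, {y}) outside {self.width}x{self.height} grid")
        return self._grid[y][x]

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.width, self.height, self.xs, self.ys, self.kinds, self.step
        )

    def validate(self) -> None:
        """Assert grid/registry consistency (single occupancy)."""
        seen = set()
        for x, y, kind in zip(self.xs, self.ys, self.kinds):
            if (x, y) in seen:
                raise AssertionError(f"double occupancy at ({x}, {y})")
            seen.add((x, y))
            if self._grid[y][x] != kind:
                raise AssertionError(f"grid/registry mismatch at ({x}, {y})")
        n_occupied = sum(1 for row in self._grid for v in row if v != EMPTY)
        if n_occupied != len(self.kinds):
            raise AssertionError("grid holds squares not in the registry")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LatticeState):
            return NotImplemented
        return (
            self.width == other.width
            and self.height == other.height
            and self.step == other.step
            and self.xs == other.xs
            and self.ys == other.ys
            and self.kinds == other.kinds
        )


class KmcRandom:
    """Buffered uniform streams for the rKMC draw discipline.

    Three independent child streams (target choice, direction choice,
    acceptance draw) plus one for initial placement, all derived from a
    single seed. One target draw and one direction draw are consumed per
    iteration; an acceptance draw is consumed only when the move class
    requires a rate comparison.
    """

    _BUF = 1 << 14

    def __init__(self, seed: int):
        ss = np.random.SeedSequence(seed)
        s_init, s_target, s_dir, s_accept = ss.spawn(4)
        self.init_rng = np.random.default_rng(s_init)
        self._target_rng = np.random.default_rng(s_target)
        self._dir_rng = np.random.default_rng(s_dir)
        self._accept_rng = np.random.default_rng(s_accept)
        self._target_buf: list[float] = []
        self._dir_buf: list[float] = []
        self._accept_buf: list[float] = []

    def target(self, n: int) -> int:
        """Uniform molecule index in [0, n)."""
        buf = self._target_buf
        if not buf:
            buf.extend(self._target_rng.random(self._BUF).tolist())
            buf.reverse()
        return int(buf.pop() * n)

    def direction(self) -> int:
        """Uniform direction index in [0, 4)."""
        buf = self._dir_buf
        if not buf:
            buf.extend(self._dir_rng.random(self._BUF).tolist())
            buf.reverse()
        return int(buf.pop() * 4.0)

    def accept(self, k: float) -> bool:
        """Draw r ~ U[0, 1); accept iff k > r."""
        buf = self._accept_buf
        if not buf:
            buf.extend(self._accept_rng.random(self._BUF).tolist())
            buf.reverse()
        return k > buf.pop()


def initialize(config: LatticeConfig, rng: KmcRandom | None = None) -> LatticeState:
    """Place all molecules uniformly at random on distinct squares.

    Parameters
    ----------
    config
        Validated simulation parameters.
    rng
        Random state; defaults to ``KmcRandom(config.seed)``.
    """
    if rng is None:
        rng = KmcRandom(config.seed)
    n_total = config.n_ask3 + config.n_obstacles
    cells = rng.init_rng.choice(
        config.width * config.height, size=n_total, replace=False
    )
    xs = (cells % config.width).tolist()
    ys = (cells // config.width).tolist()
    kinds = [ASK3] * config.n_ask3 + [OBSTACLE] * config.n_obstacles
    return LatticeState(config.width, config.height, xs, ys, kinds, step=0)


def count_contacts(state: LatticeState, pos: tuple[int, int]) -> int:
    """Number of ASK3 units among the von Neumann neighbours of ``pos``."""
    x, y = pos
    if not (0 <= x < state.width and 0 <= y < state.height):
        raise IndexError(f"({x}, {y}) outside the grid")
    grid = state._grid
    n = 0
    for dx, dy in zip(_DX, _DY):
        nx, ny = x + dx, y + dy
        if 0 <= nx < state.width and 0 <= ny < state.height:
            if grid[ny][nx] == ASK3:
                n += 1
    return n


def classify_move(
    state: LatticeState, molecule: int, destination: tuple[int, int]
) -> MoveProposal:
    """Classify a candidate move of ``molecule`` to ``destination``.

    ``n_lost`` is the net number of ASK3-ASK3 contacts broken:
    ``max(0, contacts(origin) - contacts(destination, mover excluded))``.
    Moves that gain contacts count as free diffusion.
    """
    x, y = state.xs[molecule], state.ys[molecule]
    kind = state.kinds[molecule]
    nx, ny = destination
    if abs(nx - x) + abs(ny - y) != 1:
        raise ValueError("destination must be a von Neumann neighbour of origin")
    origin = (x, y)
    if not (0 <= nx < state.width and 0 <= ny < state.height):
        return MoveProposal(molecule, origin, destination, "reflect_out_of_bounds")
    dest_kind = state._grid[ny][nx]
    if dest_kind == OBSTACLE:
        return MoveProposal(molecule, origin, destination, "reflect_occupied")
    if dest_kind == ASK3:
        if kind == ASK3:
            return MoveProposal(molecule, origin, destination, "ask3_exchange")
        return MoveProposal(molecule, origin, destination, "reflect_occupied")
    # empty destination
    if kind == OBSTACLE:
        return MoveProposal(molecule, origin, destination, "obstacle_free")
    c_origin = count_contacts(state, origin)
    # the mover is always adjacent to its own destination square and must
    # not count as a contact there
    c_dest = count_contacts(state, destination) - (1 if kind == ASK3 else 0)
    n_lost = max(0, c_origin - c_dest)
    if n_lost == 0:
        return MoveProposal(molecule, origin, destination, "ask3_free")
    return MoveProposal(molecule, origin, destination, "ask3_penalized", n_lost)


_STAY_CLASSES = frozenset(
    {"ask3_exchange", "reflect_out_of_bounds", "reflect_occupied"}
)


def rate_for(model: RateModel, proposal: MoveProposal) -> float:
    """Acceptance rate in [0, 1] for a classified proposal.

    Stay-in-place classes (exchange, reflections) report rate 0; the caller
    must not consume an acceptance draw for them.
    """
    mc = proposal.move_class
    if mc == "ask3_free":
        return model.k1
    if mc == "ask3_penalized":
        return model.k3(proposal.n_lost)
    if mc == "obstacle_free":
        return model.k5
    if mc in _STAY_CLASSES:
        return 0.0
    raise ValueError(f"unknown move class {mc!r}")


def step(state: LatticeState, model: RateModel, rng: KmcRandom) -> LatticeState:
    """Advance the state by one rKMC iteration, in place.

    Draw discipline: one uniform for the target molecule, one for the
    direction, and one acceptance draw only for the classes that compare a
    rate against r (ask3_free, ask3_penalized, obstacle_free).
    """
    i = rng.target(state.n_molecules)
    d = rng.direction()
    x, y = state.xs[i], state.ys[i]
    proposal = classify_move(state, i, (x + _DX[d], y + _DY[d]))
    if proposal.move_class not in _STAY_CLASSES:
        k = rate_for(model, proposal)
        if rng.accept(k):
            nx, ny = proposal.destination
            state._grid[y][x] = EMPTY
            state._grid[ny][nx] = state.kinds[i]
            state.xs[i] = nx
            state.ys[i] = ny
    state.step += 1
    return state


def _advance(
    state: LatticeState, model: RateModel, rng: KmcRandom, n_steps: int
) -> None:
    """Tight inner loop; semantically identical to ``n_steps`` calls of
    :func:`step` (asserted by the test suite)."""
    grid = state._grid
    xs, ys, kinds = state.xs, state.ys, state.kinds
    W, H = state.width, state.height
    n = len(kinds)
    k1, k5 = model.k1, model.k5
    A, dE = model.A, model.dE_over_theta
    exp = math.exp
    t_buf, d_buf, a_buf = rng._target_buf, rng._dir_buf, rng._accept_buf
    t_rng, d_rng, a_rng = rng._target_rng, rng._dir_rng, rng._accept_rng
    BUF = rng._BUF
    dxy = tuple(zip(_DX, _DY))
    for _ in range(n_steps):
        if not t_buf:
            t_buf.extend(t_rng.random(BUF).tolist())
            t_buf.reverse()
        i = int(t_buf.pop() * n)
        if not d_buf:
            d_buf.extend(d_rng.random(BUF).tolist())
            d_buf.reverse()
        d = int(d_buf.pop() * 4.0)
        x = xs[i]
        y = ys[i]
        nx = x + _DX[d]
        ny = y + _DY[d]
        if 0 <= nx < W and 0 <= ny < H and grid[ny][nx] == EMPTY:
            kind = kinds[i]
            if kind == OBSTACLE:
                k = k5
            else:
                c = 0
                for dx, dy in dxy:
                    ax, ay = x + dx, y + dy
                    if 0 <= ax < W and 0 <= ay < H and grid[ay][ax] == ASK3:
                        c += 1
                if c:
                    for dx, dy in dxy:
                        ax, ay = nx + dx, ny + dy
                        if (
                            0 <= ax < W
                            and 0 <= ay < H
                            and grid[ay][ax] == ASK3
                            and not (ax == x and ay == y)
                        ):
                            c -= 1
                    k = k1 if c <= 0 else A * exp(-c * dE)
                else:
                    k = k1
            if not a_buf:
                a_buf.extend(a_rng.random(BUF).tolist())
                a_buf.reverse()
            if k > a_buf.pop():
                grid[y][x] = EMPTY
                grid[ny][nx] = kinds[i]
                xs[i] = nx
                ys[i] = ny
    state.step += n_steps


def run(
    state: LatticeState,
    model: RateModel,
    n_steps: int,
    rng: KmcRandom,
    record_every: int = 100_000,
    recorder=None,
) -> list:
    """Run ``n_steps`` iterations, emitting a record every ``record_every``
    steps and at the final step (plus the starting state).

    ``recorder(state) -> record`` defaults to :meth:`LatticeState.copy`, so
    the return value is a trajectory of snapshots; pass e.g. a cluster
    summariser to record statistics instead.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if recorder is None:
        recorder = LatticeState.copy
    records = [recorder(state)]
    done = 0
    while done < n_steps:
        chunk = min(record_every, n_steps - done)
        _advance(state, model, rng, chunk)
        done += chunk
        records.append(recorder(state))
    return records


def expand_grid(state: LatticeState, new_width: int, new_height: int) -> LatticeState:
    """Grow the grid; molecules keep their coordinates, new squares empty.

    Shrinking is rejected: the relocation of molecules outside a smaller
    grid is undefined in this model.
    """
    if new_width < state.width or new_height < state.height:
        raise ValueError(
            f"cannot shrink {state.width}x{state.height} to {new_width}x{new_height}"
        )
    return LatticeState(new_width, new_height, state.xs, state.ys, state.kinds, state.step)
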
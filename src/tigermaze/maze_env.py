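"""Generative Tiger-maze environment.

A 4x4 (by default) grid of rooms with torus topology: every room has four
doors (N/E/S/W with wraparound) and exactly one of them is a tiger door,
shared with the neighbouring room as an undirected edge.  The agent observes
its body orientation but not its room.  Listening yields a probabilistic
roar from one of the three visible doors (left/front/right): the true tiger
door roars with probability ``alpha`` and each normal door with probability
``(1 - alpha) / 2``.  Opening the tiger door ends the game with score 0.

Conventions
-----------
* Cells are indexed row-major, 0-based, row 0 at the top.  File formats use
  the task's 1-based top-to-bottom convention; :mod:`tigermaze.session_io`
  converts.
* Absolute directions: ``N=0, E=1, S=2, W=3``.  Facing north in the top row
  and moving forward wraps to the bottom row.
* Relative directions: ``L=0, F=1, R=2, BACK=3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# -- direction constants ----------------------------------------------------

N, E, S, W = 0, 1, 2, 3
L, F, R, BACK = 0, 1, 2, 3

ABS_NAMES = "NESW"
REL_NAMES = "LFRB"

#: relative code of an absolute direction x seen from orientation d,
#: indexed by (x - d) % 4
_REL_OF_DELTA = np.array([F, R, BACK, L], dtype=np.int8)


def rel_direction(abs_dir: int, orientation: int) -> int:
    """Relative position (L/F/R/BACK) of absolute direction ``abs_dir``
    for an agent facing ``orientation``."""
    return int(_REL_OF_DELTA[(abs_dir - orientation) % 4])


def abs_direction(rel_dir: int, orientation: int) -> int:
    """Inverse of :func:`rel_direction`."""
    # L,F,R,BACK -> offsets -1,0,+1,+2 relative to the facing direction
    return (orientation + rel_dir - 1) % 4


def turn(orientation: int, move_dir: int) -> int:
    """Orientation after moving L/F/R: the agent ends up facing the
    direction of travel."""
    if move_dir not in (L, F, R):
        raise ValueError("move direction must be L, F or R")
    return abs_direction(move_dir, orientation)


# -- poses, actions, observations -------------------------------------------


@dataclass(frozen=True)
class Pose:
    """Room index plus observable body orientation."""

    grid: int
    orientation: int

    def __post_init__(self) -> None:
        if self.orientation not in (N, E, S, W):
            raise ValueError(f"invalid orientation {self.orientation}")


@dataclass(frozen=True)
class Action:
    kind: str  # "listen" | "move"
    direction: Optional[int] = None  # L/F/R for moves, None for listen

    def __post_init__(self) -> None:
        if self.kind == "listen":
            if self.direction is not None:
                raise ValueError("listen carries no direction")
        elif self.kind == "move":
            if self.direction not in (L, F, R):
                raise ValueError("move requires a direction in {L, F, R}")
        else:
            raise ValueError(f"unknown action kind {self.kind!r}")


LISTEN = Action("listen")


def move(direction: int) -> Action:
    return Action("move", direction)


# -- maze configuration ------------------------------------------------------


@dataclass
class MazeConfig:
    """Torus grid topology, tiger-door edges and roar accuracy.

    ``tiger_edges`` is a set of undirected edges (frozensets of two adjacent
    cell indices) forming a perfect matching: every cell is incident to
    exactly one tiger edge.
    """

    n_rows: int = 4
    n_cols: int = 4
    tiger_edges: frozenset = frozenset()
    alpha: float = 0.85

    # derived lookup tables (built in __post_init__)
    nbr: np.ndarray = field(init=False, repr=False, compare=False)
    tiger_abs: np.ndarray = field(init=False, repr=False, compare=False)
    td_rel: np.ndarray = field(init=False, repr=False, compare=False)
    trans_cell: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_rows < 3 or self.n_cols < 3:
            raise ValueError("maze dimensions must be at least 3x3")
        if not (1.0 / 3.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (1/3, 1]")
        self.tiger_edges = frozenset(frozenset(e) for e in self.tiger_edges)
        nc = self.n_cells
        rows, cols = np.divmod(np.arange(nc), self.n_cols)
        self.nbr = np.empty((nc, 4), dtype=np.int64)
        self.nbr[:, N] = (rows - 1) % self.n_rows * self.n_cols + cols
        self.nbr[:, S] = (rows + 1) % self.n_rows * self.n_cols + cols
        self.nbr[:, E] = rows * self.n_cols + (cols + 1) % self.n_cols
        self.nbr[:, W] = rows * self.n_cols + (cols - 1) % self.n_cols

        self.tiger_abs = np.full(nc, -1, dtype=np.int64)
        for edge in self.tiger_edges:
            cells = tuple(edge)
            if len(cells) != 2:
                raise ValueError(f"tiger edge {cells} is not a cell pair")
            a, b = cells
            hits = [d for d in range(4) if self.nbr[a, d] == b]
            if not hits:
                raise ValueError(f"tiger edge {cells} joins non-adjacent cells")
            if len(hits) > 1:
                raise ValueError(f"ambiguous tiger edge {cells}")
            for c, other in ((a, b), (b, a)):
                d = next(d for d in range(4) if self.nbr[c, d] == other)
                if self.tiger_abs[c] != -1:
                    raise ValueError(f"cell {c} has more than one tiger edge")
                self.tiger_abs[c] = d
        if np.any(self.tiger_abs < 0):
            missing = np.flatnonzero(self.tiger_abs < 0).tolist()
            raise ValueError(f"cells without a tiger edge: {missing}")

        # tiger door's relative direction per (orientation, cell)
        self.td_rel = _REL_OF_DELTA[(self.tiger_abs[None, :] - np.arange(4)[:, None]) % 4]
        self.td_rel = self.td_rel.astype(np.int64)

        # transition table: trans_cell[d, a, c] = destination cell when the
        # agent at cell c facing d opens door a in {L, F, R}
        self.trans_cell = np.empty((4, 3, nc), dtype=np.int64)
        for d in range(4):
            for a in (L, F, R):
                self.trans_cell[d, a] = self.nbr[:, abs_direction(a, d)]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "alpha": self.alpha,
            "tiger_edges": sorted(sorted(e) for e in self.tiger_edges),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MazeConfig":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            alpha=float(d["alpha"]),
            tiger_edges=frozenset(frozenset(map(int, e)) for e in d["tiger_edges"]),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MazeConfig):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.alpha == other.alpha
            and self.tiger_edges == other.tiger_edges
        )


def generate_maze(n_rows: int = 4, n_cols: int = 4, alpha: float = 0.85,
                  seed: int = 0, max_tries: int = 1000) -> MazeConfig:
    """Draw a random tiger-door layout: a uniform-ish random perfect matching
    on the torus grid graph, via randomised greedy matching with retries.

    Deterministic given ``seed``.  Raises if no perfect matching is found
    within ``max_tries`` attempts (e.g. for an odd number of cells).
    """
    nc = n_rows * n_cols
    if nc % 2:
        raise ValueError("no perfect matching exists on an odd number of cells")
    rows, cols = np.divmod(np.arange(nc), n_cols)
    nbr = np.empty((nc, 4), dtype=np.int64)
    nbr[:, N] = (rows - 1) % n_rows * n_cols + cols
    nbr[:, S] = (rows + 1) % n_rows * n_cols + cols
    nbr[:, E] = rows * n_cols + (cols + 1) % n_cols
    nbr[:, W] = rows * n_cols + (cols - 1) % n_cols

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        order = rng.permutation(nc)
        matched = np.zeros(nc, dtype=bool)
        edges = []
        ok = True
        for c in order:
            if matched[c]:
                continue
            cands = [n for n in nbr[c] if not matched[n] and n != c]
            if not cands:
                ok = False
                break
            other = int(cands[rng.integers(len(cands))])
            matched[c] = matched[other] = True
            edges.append(frozenset((int(c), other)))
        if ok and matched.all():
            return MazeConfig(n_rows=n_rows, n_cols=n_cols, alpha=alpha,
                              tiger_edges=frozenset(edges))
    raise RuntimeError(
        f"no perfect matching found on the {n_rows}x{n_cols} torus after "
        f"{max_tries} attempts")


def reference_maze(alpha: float = 0.85) -> MazeConfig:
    """A fixed 4x4 layout used as the package's common default maze.

    The published task used a single hand-designed maze whose exact edge
    list is not available in machine-readable form; this synthetic stand-in
    is a fixed perfect matching on the 4x4 torus with tiger doors spread
    over rows and columns, and plays the same role (one shared maze for all
    simulated participants).
    """
    edges = [(0, 1), (2, 3), (4, 8), (5, 6), (7, 11), (9, 13), (10, 14), (12, 15)]
    return MazeConfig(n_rows=4, n_cols=4, alpha=alpha,
                      tiger_edges=frozenset(frozenset(e) for e in edges))


# -- kinematics & observation ------------------------------------------------


def transition(pose: Pose, direction: int, maze: MazeConfig) -> Pose:
    """Pose after opening the L/F/R door: the agent steps through it and
    ends up facing the direction of travel (torus wraparound applied)."""
    d_new = turn(pose.orientation, direction)
    return Pose(int(maze.nbr[pose.grid, d_new]), d_new)


def true_tiger_direction(pose: Pose, maze: MazeConfig) -> int:
    """Relative direction (L/F/R/BACK) of the room's unique tiger door."""
    return int(maze.td_rel[pose.orientation, pose.grid])


def sample_roar(pose: Pose, maze: MazeConfig, rng: np.random.Generator) -> int:
    """Draw the roar direction on a Listen trial.

    The true tiger door roars with probability ``alpha``; each of the two
    other visible doors with probability ``(1 - alpha) / 2``.  Raises if the
    tiger door is behind the agent (listening is undefined there; legal
    trajectories never reach such a state, see :func:`new_game`).
    """
    td = true_tiger_direction(pose, maze)
    if td == BACK:
        raise ValueError("cannot listen with the tiger door behind the agent")
    p = np.full(3, (1.0 - maze.alpha) / 2.0)
    p[td] = maze.alpha
    return int(rng.choice(3, p=p))


# -- game lifecycle ----------------------------------------------------------


@dataclass
class TrialRecord:
    """One trial: true pose, the action-phase outcome and the prediction-
    phase reports (all prediction fields are None on the final trial and on
    missed reports)."""

    pose: Pose
    action: Optional[Action] = None      # None when the action was missed
    roar: Optional[int] = None           # L/F/R, Listen trials only
    report_td: Optional[int] = None      # predicted tiger direction (L/F/R)
    report_grid: Optional[int] = None    # predicted upcoming cell index
    conf_td: Optional[bool] = None       # True = high confidence
    conf_grid: Optional[bool] = None
    missed_action: bool = False
    missed_report_td: bool = False
    missed_report_gr: bool = False


@dataclass
class GameRecord:
    """One game's trials plus its termination bookkeeping."""

    trials: list
    termination: Optional[str] = None    # "explored" | "trial_limit" | "eaten"
    trial_limit: int = 14
    n_explored: int = 0
    n_listen: int = 0
    score: Optional[int] = None
    game_index: int = 0
    half: str = "behavioural"            # "behavioural" | "scanning"

    @property
    def true_poses(self) -> list:
        return [t.pose for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


class Game:
    """A Tiger-maze game in progress (mutable state driven by step_game)."""

    def __init__(self, maze: MazeConfig, pose: Pose, trial_limit: int):
        self.maze = maze
        self.pose = pose
        self.trial_limit = int(trial_limit)
        self.record = GameRecord(trials=[], trial_limit=self.trial_limit)
        self.visited = {pose.grid}

    @property
    def terminated(self) -> bool:
        return self.record.termination is not None


def new_game(maze: MazeConfig, rng: np.random.Generator,
             trial_limit: Optional[int] = None) -> Game:
    """Start a game from an unknown initial state.

    The initial (cell, orientation) pair is sampled uniformly over states
    whose tiger door is not behind the agent, so listening is always
    defined; the per-game trial limit is drawn uniformly from 10-14 unless
    given explicitly.
    """
    if trial_limit is None:
        trial_limit = int(rng.integers(10, 15))
    while True:
        cell = int(rng.integers(maze.n_cells))
        d = int(rng.integers(4))
        if maze.td_rel[d, cell] != BACK:
            return Game(maze, Pose(cell, d), trial_limit)


def step_game(game: Game, action: Optional[Action],
              rng: np.random.Generator) -> TrialRecord:
    """Apply one action-phase choice and append the trial record.

    ``action=None`` records a missed (no-response) trial: the state stays
    the same until the next trial.  Listening leaves the pose unchanged and
    samples a roar; moving through the tiger edge terminates the game as
    "eaten" with score 0.  The game also terminates once more than eight
    distinct rooms have been visited ("explored") or at the per-game trial
    limit ("trial_limit").
    """
    if game.terminated:
        raise RuntimeError("cannot act in a terminated game")
    maze = game.maze
    trial = TrialRecord(pose=game.pose, action=action,
                        missed_action=action is None)
    if action is not None and action.kind == "listen":
        trial.roar = sample_roar(game.pose, maze, rng)
        game.record.n_listen += 1
    elif action is not None:
        dest = transition(game.pose, action.direction, maze)
        if frozenset((game.pose.grid, dest.grid)) in maze.tiger_edges:
            game.record.termination = "eaten"
        else:
            game.pose = dest
            game.visited.add(dest.grid)
            if len(game.visited) >= 9:
                game.record.termination = "explored"
    game.record.trials.append(trial)
    if game.record.termination is None and len(game.record.trials) >= game.trial_limit:
        game.record.termination = "trial_limit"
    if game.terminated:
        game.record.n_explored = len(game.visited)
    return trial


# -- scoring -----------------------------------------------------------------


def _default_prediction_rewards() -> dict:
    # (prediction correct?, high confidence?) -> points
    return {(True, True): 3, (True, False): 2, (False, True): 0, (False, False): 0}


@dataclass
class RewardTable:
    """Score components: per-room exploration reward, per-listen cost, and
    prediction rewards keyed by (correct?, high-confidence?) separately for
    the tiger-door and grid predictions.

    The published score table's exact prediction rewards were not released;
    the defaults (correct/high=3, correct/low=2, incorrect=0) respect the
    stated ordering and are fully configurable.
    """

    explore_reward: int = 5
    listen_cost: int = 1
    td_rewards: dict = field(default_factory=_default_prediction_rewards)
    gr_rewards: dict = field(default_factory=_default_prediction_rewards)

    def __post_init__(self) -> None:
        for table in (self.td_rewards, self.gr_rewards):
            if table[(True, True)] < table[(True, False)]:
                raise ValueError("correct/high reward must be >= correct/low")


def game_score(game: GameRecord, maze: MazeConfig,
               rewards: Optional[RewardTable] = None) -> int:
    """Total game score.

    ``N_exp * explore_reward - N_lis * listen_cost`` plus prediction rewards
    summed over trials 1..T-1 (the final trial has no prediction phase);
    zero overall if the game ended eaten.  A prediction is correct when it
    matches the true upcoming state (the pose of the next trial).
    """
    if game.termination is None:
        raise ValueError("game not terminated")
    if game.termination == "eaten":
        return 0
    if rewards is None:
        rewards = RewardTable()
    total = game.n_explored * rewards.explore_reward - game.n_listen * rewards.listen_cost
    for t in range(len(game.trials) - 1):
        trial = game.trials[t]
        upcoming = game.trials[t + 1].pose
        if trial.report_td is not None and trial.conf_td is not None:
            correct = trial.report_td == true_tiger_direction(upcoming, maze)
            total += rewards.td_rewards[(bool(correct), bool(trial.conf_td))]
        if trial.report_grid is not None and trial.conf_grid is not None:
            correct = trial.report_grid == upcoming.grid
            total += rewards.gr_rewards[(bool(correct), bool(trial.conf_grid))]
    return int(total)
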
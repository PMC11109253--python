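"""Hierarchical belief inference over tiger-door direction and grid location.

The model tracks two coupled discrete posteriors: a 3-state belief over the
relative direction of the upcoming tiger door (left/front/right) and a
16-state belief over the room in the maze.  The direction of information
flow depends on the action:

* On a **Listen** trial the tiger belief is updated first, Bayes-fashion,
  from the roar direction with a sensitivity exponent ``delta`` on the
  likelihood.  The grid belief is then reweighted three ways according to
  whether each room's true tiger direction (given the observable body
  orientation) matches the roar, differs from it, or lies behind the agent
  — with weights built from the tiger-dependence parameter ``beta`` and the
  maze-memory error rate ``gamma``.  If the roar contradicts the predicted
  tiger direction the model enters *re-estimation mode*: the same weighting
  is applied to the *anchor prior* (the grid belief held on first entering
  the current room), conditioned on the maximum-a-posteriori tiger
  direction, and mixed with the ordinary update with weight ``epsilon`` on
  the latter.

* On a **Move** trial the grid belief is pushed forward through the maze's
  (bijective) transition map and the tiger belief is rebuilt by
  marginalising the room belief through a ``gamma``-noised memory of each
  room's true tiger direction, restricted to the three visible doors.

Posterior Shannon entropies of the two beliefs (natural log) serve as the
model's uncertainty read-outs, mirrored by the task's binary confidence
reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .maze_env import (BACK, GameRecord, MazeConfig, turn)

_NORM_TOL = 1e-9


# -- parameters and belief state --------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """The four free parameters of the hierarchical model.

    delta
        Sensitivity exponent on the roar likelihood; values above 1 weight
        new observations more heavily than ideal Bayes.  Fitting box [1, 3].
    beta
        Dependence of the grid update on the tiger-door comparison; at
        beta -> 1 rooms inconsistent with the roar are excluded outright.
        Box [0.5, 0.999].
    epsilon
        Probability of continuing the ordinary update while in
        re-estimation mode (epsilon = 1 disables re-estimation).  Box [0, 1].
    gamma
        Maze-memory error rate; softens every comparison against the
        memorised maze structure.  Box [0, 0.3].
    """

    delta: float = 1.8
    beta: float = 0.97
    epsilon: float = 0.14
    gamma: float = 0.074

    BOUNDS = {
        "delta": (1.0, 3.0),
        "beta": (0.5, 0.999),
        "epsilon": (0.0, 1.0),
        "gamma": (0.0, 0.3),
    }

    def validate(self) -> "ModelParams":
        for name, (lo, hi) in self.BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside its box [{lo}, {hi}]")
        return self


@dataclass
class Belief:
    """Paired posteriors plus the re-estimation anchor.

    ``anchor_prior`` is the grid belief at the first trial after entering
    the current room; it is refreshed exactly when a Move is applied."""

    p_tiger: np.ndarray
    p_grid: np.ndarray
    anchor_prior: np.ndarray
    anchor_trial: int = 0

    def copy(self) -> "Belief":
        return Belief(self.p_tiger.copy(), self.p_grid.copy(),
                      self.anchor_prior.copy(), self.anchor_trial)

    def check_normalized(self, tol: float = _NORM_TOL) -> None:
        for v in (self.p_tiger, self.p_grid, self.anchor_prior):
            if np.any(v < -tol) or abs(v.sum() - 1.0) > tol:
                raise ValueError("belief vector not a normalized distribution")


# -- elementary updates ------------------------------------------------------


def tiger_update_from_roar(p_tiger: np.ndarray, v: int, delta: float,
                           alpha: float) -> np.ndarray:
    """Bayes update of the 3-state tiger belief from a roar at direction v,
    with the likelihood raised to the power delta (delta = 0 leaves the
    prior unchanged; delta = 1 is ideal Bayes)."""
    lik = np.full(3, (1.0 - alpha) / 2.0)
    lik[v] = alpha
    post = np.asarray(p_tiger, dtype=float) * lik ** delta
    z = post.sum()
    if z <= 0.0:
        raise ZeroDivisionError("tiger update annihilated all belief mass")
    return post / z


def _three_way_weights(cells_rel: np.ndarray, target: int, w_match: float,
                       w_mismatch: float, w_back: float) -> np.ndarray:
    w = np.where(cells_rel == target, w_match, w_mismatch)
    return np.where(cells_rel == BACK, w_back, w)


def _reweight_grid(p_grid: np.ndarray, cells_rel: np.ndarray, target: int,
                   beta: float, gamma: float) -> np.ndarray:
    """Three-case grid reweighting against a target direction: rooms whose
    memorised tiger direction matches the target keep weight
    (1-g)b + g(1-b), mismatching rooms g*b + (1-g)(1-b), and rooms with the
    tiger behind get the bare memory-error weight g.  Unnormalized."""
    w = _three_way_weights(cells_rel, target,
                           (1.0 - gamma) * beta + gamma * (1.0 - beta),
                           gamma * beta + (1.0 - gamma) * (1.0 - beta),
                           gamma)
    return p_grid * w


def _safe_normalize(q: np.ndarray, anchor: np.ndarray,
                    context: str) -> np.ndarray:
    z = q.sum()
    if z > 0.0:
        return q / z
    # Total annihilation is only reachable in gamma = 0 corner cases; the
    # filter must stay total, so restart from the anchor prior.
    warnings.warn(f"{context}: grid update annihilated all mass; "
                  "falling back to the anchor prior", RuntimeWarning)
    za = anchor.sum()
    if za > 0.0:
        return anchor / za
    return np.full_like(q, 1.0 / q.size)


def grid_update_listen(belief: Belief, v: int, d: int, params: ModelParams,
                       maze: MazeConfig, *,
                       pre_roar_tiger: Optional[np.ndarray] = None,
                       gate: str = "pre_roar",
                       reest_condition: str = "post_roar"):
    """Listen-trial grid update (the tiger update must already be applied,
    so ``belief.p_tiger`` holds the post-roar posterior).

    Returns ``(new_grid, mode)`` with ``mode`` in {"update", "re_estimate"}.
    The mode gate compares the roar ``v`` against the MAP tiger direction:
    by default the *pre-roar* posterior (the prediction actually reported on
    the previous trial, supplied as ``pre_roar_tiger``); ``gate='post_roar'``
    uses the freshly updated posterior instead.  In re-estimation mode the
    anchor prior is reweighted against the MAP tiger direction — post-roar
    by default, ``reest_condition='pre_roar'`` for the other reading — and
    mixed with the ordinary update with weight epsilon on the latter.
    """
    cells_rel = maze.td_rel[d]
    p_ud = _reweight_grid(belief.p_grid, cells_rel, v, params.beta, params.gamma)
    p_ud = _safe_normalize(p_ud, belief.anchor_prior, "update mode")

    if gate == "pre_roar":
        if pre_roar_tiger is None:
            raise ValueError("gate='pre_roar' requires the pre-roar tiger posterior")
        gate_map = int(np.argmax(pre_roar_tiger))
    elif gate == "post_roar":
        gate_map = int(np.argmax(belief.p_tiger))
    else:
        raise ValueError(f"unknown gate {gate!r}")

    if v == gate_map:
        return p_ud, "update"

    if reest_condition == "post_roar":
        cond_map = int(np.argmax(belief.p_tiger))
    elif reest_condition == "pre_roar":
        if pre_roar_tiger is None:
            raise ValueError("reest_condition='pre_roar' requires the pre-roar posterior")
        cond_map = int(np.argmax(pre_roar_tiger))
    else:
        raise ValueError(f"unknown reest_condition {reest_condition!r}")

    p_re = _reweight_grid(belief.anchor_prior, cells_rel, cond_map,
                          params.beta, params.gamma)
    p_re = _safe_normalize(p_re, belief.anchor_prior, "re-estimation mode")
    mixed = (1.0 - params.epsilon) * p_re + params.epsilon * p_ud
    return mixed, "re_estimate"


def tiger_from_grid(p_grid: np.ndarray, d: int, gamma: float,
                    maze: MazeConfig) -> np.ndarray:
    """Rebuild the tiger belief as a memory-noised marginal of the grid
    belief: each room puts mass 1 - gamma on its true tiger direction and
    gamma/3 on each of the other three relative directions (Back included),
    after which the result is restricted to the three visible doors and
    renormalized.  gamma = 0 gives the exact renormalized marginal."""
    m = np.bincount(maze.td_rel[d], weights=p_grid, minlength=4)
    p4 = (1.0 - gamma) * m + (gamma / 3.0) * (1.0 - m)
    p3 = p4[:3]
    z = p3.sum()
    if z <= 0.0:
        # all grid mass on tiger-behind rooms with gamma = 0
        warnings.warn("tiger marginal had no mass on visible doors; "
                      "falling back to uniform", RuntimeWarning)
        return np.full(3, 1.0 / 3.0)
    return p3 / z


def move_update(belief: Belief, direction: int, d: int, params: ModelParams,
                maze: MazeConfig, trial_index: int = 0) -> Belief:
    """Move-trial update: push the grid belief through the (bijective)
    transition map for a move in ``direction`` from orientation ``d``,
    rebuild the tiger belief by marginalisation at the new orientation, and
    reset the re-estimation anchor to the new grid posterior."""
    perm = maze.trans_cell[d, direction]
    new_grid = np.empty_like(belief.p_grid)
    new_grid[perm] = belief.p_grid
    d_next = turn(d, direction)
    new_tiger = tiger_from_grid(new_grid, d_next, params.gamma, maze)
    return Belief(new_tiger, new_grid, new_grid.copy(), trial_index)


# -- read-outs ---------------------------------------------------------------


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0.0]
    return float(-(nz * np.log(nz)).sum())


def entropies(belief: Belief) -> tuple:
    """(tiger entropy, grid entropy) of the paired posteriors, in nats."""
    return entropy(belief.p_tiger), entropy(belief.p_grid)


def map_predict(belief: Belief, rng: np.random.Generator) -> tuple:
    """MAP prediction of (tiger direction, grid cell); exact posterior ties
    are broken uniformly at random with the supplied generator."""
    return (_random_argmax(belief.p_tiger, rng),
            _random_argmax(belief.p_grid, rng))


def _random_argmax(p: np.ndarray, rng: np.random.Generator,
                   tol: float = 1e-12) -> int:
    top = np.flatnonzero(p >= p.max() - tol)
    return int(top[rng.integers(top.size)]) if top.size > 1 else int(top[0])


# -- session replay ----------------------------------------------------------


@dataclass
class GameTrace:
    """Per-trial model quantities for one game (row t = state after trial
    t's action, i.e. the posterior that generates trial t's predictions)."""

    prior_td: np.ndarray      # (T, 3) belief before the trial's action
    prior_gr: np.ndarray      # (T, n_cells)
    post_td: np.ndarray       # (T, 3) belief after the trial's action
    post_gr: np.ndarray       # (T, n_cells)
    mode: list                # "update" | "re_estimate" | None per trial
    map_td: Optional[np.ndarray] = None
    map_gr: Optional[np.ndarray] = None

    @property
    def post_entropy_td(self) -> np.ndarray:
        return _row_entropies(self.post_td)

    @property
    def post_entropy_gr(self) -> np.ndarray:
        return _row_entropies(self.post_gr)

    @property
    def prior_entropy_td(self) -> np.ndarray:
        return _row_entropies(self.prior_td)

    @property
    def prior_entropy_gr(self) -> np.ndarray:
        return _row_entropies(self.prior_gr)


def _row_entropies(mat: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(mat > 0.0, np.log(np.where(mat > 0.0, mat, 1.0)), 0.0)
    return -(mat * lp).sum(axis=1)


class BeliefModel:
    """Common replay contract for all four behavioural models.

    Subclasses implement :meth:`listen_step` and :meth:`move_step`; the base
    class owns initialization and the trial loop shared by generation,
    likelihood evaluation and analysis.
    """

    name = "base"
    free_parameters: tuple = ()

    def init_belief(self, maze: MazeConfig, orientation: int,
                    params: ModelParams) -> Belief:
        """Uniform room prior; the initial tiger belief is its
        memory-noised marginal at the observed starting orientation."""
        p_grid = np.full(maze.n_cells, 1.0 / maze.n_cells)
        p_tiger = tiger_from_grid(p_grid, orientation, params.gamma, maze)
        return Belief(p_tiger, p_grid, p_grid.copy(), 0)

    def listen_step(self, belief: Belief, v: int, d: int,
                    params: ModelParams, maze: MazeConfig):
        raise NotImplementedError

    def move_step(self, belief: Belief, direction: int, d: int,
                  params: ModelParams, maze: MazeConfig,
                  trial_index: int) -> Belief:
        raise NotImplementedError

    def replay_game(self, game: GameRecord, params: ModelParams,
                    maze: MazeConfig,
                    rng: Optional[np.random.Generator] = None) -> GameTrace:
        """Replay one game's action/observation sequence and return the
        belief trajectory.  Raises on logs whose structure is inconsistent
        (Listen without roar, Move with roar, orientation breaks)."""
        T = len(game.trials)
        nc = maze.n_cells
        prior_td = np.empty((T, 3)); prior_gr = np.empty((T, nc))
        post_td = np.empty((T, 3)); post_gr = np.empty((T, nc))
        modes: list = []
        map_td = np.full(T, -1, dtype=np.int64) if rng is not None else None
        map_gr = np.full(T, -1, dtype=np.int64) if rng is not None else None

        belief = self.init_belief(maze, game.trials[0].pose.orientation, params)
        expected_d = game.trials[0].pose.orientation
        for t, trial in enumerate(game.trials):
            d = trial.pose.orientation
            if d != expected_d:
                raise ValueError(
                    f"trial {t}: orientation {d} inconsistent with action "
                    f"history (expected {expected_d})")
            prior_td[t] = belief.p_tiger; prior_gr[t] = belief.p_grid
            action = trial.action
            if trial.missed_action or action is None:
                modes.append(None)
            elif action.kind == "listen":
                if trial.roar is None:
                    raise ValueError(f"trial {t}: Listen trial without a roar")
                belief, mode = self.listen_step(belief, trial.roar, d, params, maze)
                modes.append(mode)
            else:
                if trial.roar is not None:
                    raise ValueError(f"trial {t}: Move trial carries a roar")
                belief = self.move_step(belief, action.direction, d, params,
                                        maze, t + 1)
                modes.append(None)
                expected_d = turn(d, action.direction)
            post_td[t] = belief.p_tiger; post_gr[t] = belief.p_grid
            if rng is not None:
                map_td[t], map_gr[t] = map_predict(belief, rng)
        return GameTrace(prior_td, prior_gr, post_td, post_gr, modes,
                         map_td, map_gr)

    def run_session(self, sessions: list, params: ModelParams,
                    maze: MazeConfig,
                    rng: Optional[np.random.Generator] = None) -> list:
        """Replay a list of games; returns one :class:`GameTrace` each.
        Deterministic given the generator's seed (MAP tie-breaks are its
        only random element)."""
        return [self.replay_game(g, params, maze, rng) for g in sessions]


class HierarchicalModel(BeliefModel):
    """The full bidirectional model (free parameters delta, beta, epsilon,
    gamma); see the module docstring for the update rules."""

    name = "hierarchical"
    free_parameters = ("delta", "beta", "epsilon", "gamma")

    def __init__(self, gate: str = "pre_roar",
                 reest_condition: str = "post_roar"):
        self.gate = gate
        self.reest_condition = reest_condition

    def listen_step(self, belief, v, d, params, maze):
        pre = belief.p_tiger
        post_tiger = tiger_update_from_roar(pre, v, params.delta, maze.alpha)
        stage = Belief(post_tiger, belief.p_grid, belief.anchor_prior,
                       belief.anchor_trial)
        new_grid, mode = grid_update_listen(
            stage, v, d, params, maze, pre_roar_tiger=pre,
            gate=self.gate, reest_condition=self.reest_condition)
        return Belief(post_tiger, new_grid, belief.anchor_prior,
                      belief.anchor_trial), mode

    def move_step(self, belief, direction, d, params, maze, trial_index):
        return move_update(belief, direction, d, params, maze, trial_index)


def run_model_on_session(sessions: list, params: ModelParams,
                         maze: MazeConfig,
                         rng: Optional[np.random.Generator] = None,
                         model: Optional[BeliefModel] = None) -> list:
    """Replay a participant's games under the hierarchical model (or any
    model passed explicitly); returns per-game :class:`GameTrace` objects
    carrying beliefs, modes, MAP predictions and entropies."""
    if model is None:
        model = HierarchicalModel()
    return model.run_session(sessions, params, maze, rng)
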
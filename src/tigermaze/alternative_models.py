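"""Competitor models behind the common replay interface.

Three alternatives to the hierarchical model, differing in how (or whether)
the two belief chains talk to each other:

* **top-down** — only the room belief is inferred; on Listen trials it is
  reweighted directly against the roar (accuracy ``alpha`` blended with the
  memory error ``gamma``), and the tiger belief is always the memory-noised
  marginal of the room belief.  One free parameter (gamma).
* **parallel** — the two chains never exchange information.  The tiger
  belief follows the roar Bayes update on Listen trials and, on Move
  trials, a direction-transition matrix obtained by counting, over all
  rooms, how each room's tiger direction maps to its successor's.  The room
  belief follows the top-down rules.  Free parameters (delta, gamma).
* **hierarchical without re-estimation** — the full model with epsilon
  pinned to 1, which provably reduces the re-estimation mixture to the
  plain update branch.  Free parameters (delta, beta, gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hierarchical_model import (Belief, BeliefModel, HierarchicalModel,
                                 ModelParams, _safe_normalize,
                                 _three_way_weights, tiger_from_grid,
                                 tiger_update_from_roar)
from .maze_env import MazeConfig, turn


@dataclass(frozen=True)
class ModelSpec:
    """Name plus free-parameter set of one of the four candidate models."""

    name: str
    free_parameters: tuple

    def __post_init__(self) -> None:
        expected = FREE_PARAMETERS.get(self.name)
        if expected is None:
            raise ValueError(f"unknown model {self.name!r}")
        if tuple(self.free_parameters) != expected:
            raise ValueError(
                f"{self.name} must expose free parameters {expected}")


FREE_PARAMETERS = {
    "hierarchical": ("delta", "beta", "epsilon", "gamma"),
    "hierarchical_no_reest": ("delta", "beta", "gamma"),
    "parallel": ("delta", "gamma"),
    "topdown": ("gamma",),
}


# -- top-down ----------------------------------------------------------------


def topdown_listen_update(belief: Belief, v: int, d: int, gamma: float,
                          alpha: float, maze: MazeConfig) -> Belief:
    """Listen-trial update of the top-down model: the room belief is
    reweighted three ways by [(1-g)a + g(1-a)] / [g*a + (1-g)(1-a)] / g
    according to whether the room's tiger direction matches the roar,
    differs, or is behind; the tiger belief is then re-derived as the
    memory-noised marginal."""
    w = _three_way_weights(maze.td_rel[d], v,
                           (1.0 - gamma) * alpha + gamma * (1.0 - alpha),
                           gamma * alpha + (1.0 - gamma) * (1.0 - alpha),
                           gamma)
    new_grid = _safe_normalize(belief.p_grid * w, belief.anchor_prior,
                               "top-down listen update")
    new_tiger = tiger_from_grid(new_grid, d, gamma, maze)
    return Belief(new_tiger, new_grid, belief.anchor_prior,
                  belief.anchor_trial)


class TopDownModel(BeliefModel):
    name = "topdown"
    free_parameters = FREE_PARAMETERS["topdown"]

    def listen_step(self, belief, v, d, params, maze):
        return topdown_listen_update(belief, v, d, params.gamma,
                                     maze.alpha, maze), None

    def move_step(self, belief, direction, d, params, maze, trial_index):
        perm = maze.trans_cell[d, direction]
        new_grid = np.empty_like(belief.p_grid)
        new_grid[perm] = belief.p_grid
        d_next = turn(d, direction)
        new_tiger = tiger_from_grid(new_grid, d_next, params.gamma, maze)
        return Belief(new_tiger, new_grid, new_grid.copy(), trial_index)


# -- parallel ----------------------------------------------------------------


class TigerContradictionError(ValueError):
    """All tiger belief mass sat on the just-opened (hence passable) door."""


def tiger_transition_matrix(d_now: int, move_direction: int,
                            maze: MazeConfig) -> np.ndarray:
    """Empirical 3x3 tiger-direction transition matrix for a move.

    Entry (i, j) is the fraction, among rooms whose tiger direction is i at
    orientation ``d_now``, of rooms whose successor (through the chosen
    door) has tiger direction j at the post-move orientation.  Successors
    with the tiger behind fall out of the count; rows with no mass default
    to uniform so the propagation stays defined."""
    d_next = turn(d_now, move_direction)
    src_rel = maze.td_rel[d_now]
    dst_rel = maze.td_rel[d_next][maze.trans_cell[d_now, move_direction]]
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.count_nonzero((src_rel == i) & (dst_rel == j))
    rowsum = counts.sum(axis=1, keepdims=True)
    out = np.full((3, 3), 1.0 / 3.0)
    nz = rowsum[:, 0] > 0
    out[nz] = counts[nz] / rowsum[nz]
    return out


def parallel_move_tiger_update(p_tiger: np.ndarray, move_direction: int,
                               d_now: int, maze: MazeConfig) -> np.ndarray:
    """Move-trial tiger update of the parallel model: the opened door was
    passable, so its direction is zeroed out of the prior, which is then
    propagated through the empirical tiger-direction transition matrix.
    Raises :class:`TigerContradictionError` if the whole prior sat on the
    opened door."""
    p = np.asarray(p_tiger, dtype=float).copy()
    p[move_direction] = 0.0
    if p.sum() <= 0.0:
        raise TigerContradictionError(
            "tiger belief was entirely on the moved-through door")
    M = tiger_transition_matrix(d_now, move_direction, maze)
    post = p @ M
    return post / post.sum()


class ParallelModel(BeliefModel):
    name = "parallel"
    free_parameters = FREE_PARAMETERS["parallel"]

    def listen_step(self, belief, v, d, params, maze):
        new_tiger = tiger_update_from_roar(belief.p_tiger, v, params.delta,
                                           maze.alpha)
        # the room chain is updated exactly as in the top-down model and
        # never sees the tiger chain
        stage = topdown_listen_update(belief, v, d, params.gamma,
                                      maze.alpha, maze)
        return Belief(new_tiger, stage.p_grid, belief.anchor_prior,
                      belief.anchor_trial), None

    def move_step(self, belief, direction, d, params, maze, trial_index):
        perm = maze.trans_cell[d, direction]
        new_grid = np.empty_like(belief.p_grid)
        new_grid[perm] = belief.p_grid
        new_tiger = parallel_move_tiger_update(belief.p_tiger, direction, d,
                                               maze)
        return Belief(new_tiger, new_grid, new_grid.copy(), trial_index)


# -- the epsilon = 1 reduction ----------------------------------------------


class HierarchicalNoReestimation(HierarchicalModel):
    """The hierarchical model with epsilon pinned at 1: the re-estimation
    mixture then equals the plain update branch on every trial, so no
    separate code path exists to diverge from."""

    name = "hierarchical_no_reest"
    free_parameters = FREE_PARAMETERS["hierarchical_no_reest"]

    def listen_step(self, belief, v, d, params, maze):
        return super().listen_step(belief, v, d,
                                   replace(params, epsilon=1.0), maze)


_MODEL_CLASSES = {
    "hierarchical": HierarchicalModel,
    "hierarchical_no_reest": HierarchicalNoReestimation,
    "parallel": ParallelModel,
    "topdown": TopDownModel,
}

MODEL_NAMES = tuple(_MODEL_CLASSES)


def make_model(spec) -> BeliefModel:
    """Build a model from a :class:`ModelSpec` or a bare name; all four
    share the session-replay interface of :class:`BeliefModel`."""
    name = spec.name if isinstance(spec, ModelSpec) else str(spec)
    try:
        return _MODEL_CLASSES[name]()
    except KeyError:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
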
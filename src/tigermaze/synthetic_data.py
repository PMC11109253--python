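"""Closed-loop synthetic participants.

The generator couples the maze environment to a belief model and a simple
exploration policy, producing complete session logs — actions, roars,
reported predictions, binary confidences, missed trials — with the
statistical structure the downstream fitting and analysis stages assume.

The policy is deliberately plain plumbing (the navigation behaviour itself
is treated as observed, not modelled): listen whenever either posterior
entropy is above its threshold, otherwise move towards believed-unvisited
rooms while avoiding the MAP tiger direction.  Reports are drawn from the
model's posteriors (probability matching) by default, which makes the
expected negative log evidence minimal exactly at the generating
parameters and hence makes parameter recovery a well-posed experiment; MAP
reporting is available as an option.  Confidence is high exactly when the
corresponding posterior entropy is below its threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hierarchical_model import (Belief, BeliefModel, GameTrace,
                                 HierarchicalModel, ModelParams, entropies,
                                 map_predict)
from .maze_env import (F, L, LISTEN, R, Action, Game, GameRecord, MazeConfig,
                       game_score, move, new_game, step_game)

LN3 = math.log(3.0)
LN16 = math.log(16.0)


@dataclass
class AgentPolicy:
    """Exploration and report policy of a synthetic participant.

    Entropy thresholds are in nats (tiger chain within [0, ln 3], grid
    chain within [0, ln 16]).  Defaults are calibrated once so that default
    cohorts land near the task's descriptive ranges (about five listens per
    game within 2-14 trials); they are a fixed convention, not fitted
    quantities.
    """

    listen_threshold_tiger: float = 0.5
    listen_threshold_grid: float = 1.6
    softmax_temperature: float = 1.0
    lapse_rate: float = 0.0
    confidence_threshold_tiger: float = 0.5
    confidence_threshold_grid: float = 1.0
    miss_rate: float = 0.05
    report_style: str = "sample"   # "sample" (probability matching) | "map"
    report_lapse: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.listen_threshold_tiger <= LN3:
            raise ValueError("tiger listen threshold outside [0, ln 3]")
        if not 0.0 <= self.listen_threshold_grid <= LN16:
            raise ValueError("grid listen threshold outside [0, ln 16]")
        if not 0.0 <= self.confidence_threshold_tiger <= LN3:
            raise ValueError("tiger confidence threshold outside [0, ln 3]")
        if not 0.0 <= self.confidence_threshold_grid <= LN16:
            raise ValueError("grid confidence threshold outside [0, ln 16]")
        for name in ("lapse_rate", "miss_rate", "report_lapse"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.softmax_temperature <= 0.0:
            raise ValueError("softmax temperature must be positive")
        if self.report_style not in ("sample", "map"):
            raise ValueError("report_style must be 'sample' or 'map'")


def choose_action(belief: Belief, visit_counts: np.ndarray,
                  policy: AgentPolicy, rng: np.random.Generator,
                  maze: MazeConfig, orientation: int) -> Action:
    """Listen if either posterior entropy exceeds its threshold (with lapse
    noise); otherwise move, avoiding the MAP tiger direction, with a
    softmax preference for directions whose expected (belief-weighted)
    visit count is lowest."""
    u_td, u_gr = entropies(belief)
    want_listen = (u_td > policy.listen_threshold_tiger
                   or u_gr > policy.listen_threshold_grid)
    if policy.lapse_rate > 0.0 and rng.random() < policy.lapse_rate:
        want_listen = not want_listen
    if want_listen:
        return LISTEN
    map_td = int(np.argmax(belief.p_tiger))
    candidates = [a for a in (L, F, R) if a != map_td]
    expected_visits = np.array([
        float(belief.p_grid @ visit_counts[maze.trans_cell[orientation, a]])
        for a in candidates])
    logits = -expected_visits / policy.softmax_temperature
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return move(candidates[int(rng.choice(len(candidates), p=p))])


def report_predictions(belief: Belief, policy: AgentPolicy,
                       rng: np.random.Generator) -> tuple:
    """(tiger report, grid report, tiger confidence, grid confidence).

    Reports are posterior samples (default) or MAP states with random
    tie-breaks; with probability ``report_lapse`` a report is replaced by a
    uniform draw.  Confidence is high iff the matching posterior entropy is
    below its threshold."""
    if policy.report_style == "sample":
        td = int(rng.choice(3, p=belief.p_tiger))
        gr = int(rng.choice(belief.p_grid.size, p=belief.p_grid))
    else:
        td, gr = map_predict(belief, rng)
    if policy.report_lapse > 0.0:
        if rng.random() < policy.report_lapse:
            td = int(rng.integers(3))
        if rng.random() < policy.report_lapse:
            gr = int(rng.integers(belief.p_grid.size))
    u_td, u_gr = entropies(belief)
    return (td, gr, u_td < policy.confidence_threshold_tiger,
            u_gr < policy.confidence_threshold_grid)


@dataclass
class ParticipantData:
    """One synthetic participant: session logs plus the generator's own
    belief trajectories (ground truth for replay tests)."""

    participant_id: str
    sessions: list               # list[GameRecord]
    traces: list                 # list[GameTrace], aligned with sessions
    params: ModelParams
    model_name: str
    seed: int


def simulate_participant(params: ModelParams, policy: AgentPolicy,
                         maze: MazeConfig, n_games: int = 24,
                         seed: int = 0,
                         model: Optional[BeliefModel] = None,
                         participant_id: str = "sim",
                         ) -> ParticipantData:
    """Simulate a full participant in closed loop.

    The first half of the games is labelled the behavioural experiment and
    the second half the scanning experiment, mirroring the task's 12 + 12
    game structure.  Deterministic per seed.
    """
    if model is None:
        model = HierarchicalModel()
    rng = np.random.default_rng(seed)
    sessions: list = []
    traces: list = []
    for g in range(n_games):
        game = new_game(maze, rng)
        belief = model.init_belief(maze, game.pose.orientation, params)
        visit_counts = np.zeros(maze.n_cells)
        prior_td, prior_gr, post_td, post_gr, modes = [], [], [], [], []
        while not game.terminated:
            visit_counts += belief.p_grid
            prior_td.append(belief.p_tiger.copy())
            prior_gr.append(belief.p_grid.copy())
            if policy.miss_rate > 0.0 and rng.random() < policy.miss_rate:
                action = None
            else:
                action = choose_action(belief, visit_counts, policy, rng,
                                       maze, game.pose.orientation)
            trial = step_game(game, action, rng)
            if action is None:
                modes.append(None)
            elif action.kind == "listen":
                belief, mode = model.listen_step(belief, trial.roar,
                                                 trial.pose.orientation,
                                                 params, maze)
                modes.append(mode)
            else:
                belief = model.move_step(belief, action.direction,
                                         trial.pose.orientation, params,
                                         maze, len(game.record.trials))
                modes.append(None)
            post_td.append(belief.p_tiger.copy())
            post_gr.append(belief.p_grid.copy())
            if not game.terminated:
                td, gr, c_td, c_gr = report_predictions(belief, policy, rng)
                if policy.miss_rate > 0.0 and rng.random() < policy.miss_rate:
                    trial.missed_report_td = True
                else:
                    trial.report_td, trial.conf_td = td, c_td
                if policy.miss_rate > 0.0 and rng.random() < policy.miss_rate:
                    trial.missed_report_gr = True
                else:
                    trial.report_grid, trial.conf_grid = gr, c_gr
        record = game.record
        record.game_index = g
        record.half = "behavioural" if g < n_games // 2 else "scanning"
        record.score = game_score(record, maze)
        sessions.append(record)
        traces.append(GameTrace(np.array(prior_td), np.array(prior_gr),
                                np.array(post_td), np.array(post_gr), modes))
    return ParticipantData(participant_id, sessions, traces, params,
                           model.name, seed)


def simulate_cohort(n_participants: int, params: ModelParams,
                    policy: AgentPolicy, maze: MazeConfig,
                    n_games: int = 24, seed: int = 0,
                    model: Optional[BeliefModel] = None) -> list:
    """Simulate ``n_participants`` independent participants; per-participant
    seeds are spawned from ``seed`` so the cohort is reproducible as a
    whole and participant-by-participant."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_participants)
    return [
        simulate_participant(params, policy, maze, n_games=n_games,
                             seed=int(s % (2**31)), model=model,
                             participant_id=f"sim{i:03d}")
        for i, s in enumerate(child_seeds)
    ]
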
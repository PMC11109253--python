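"""Parameter estimation, BIC and random-effects model comparison.

Per participant, the free parameters of a model are estimated by minimising
the scaled negative log evidence (NLE) of the participant's reported
predictions: per trial, the model posterior's probability mass on the
reported tiger direction and on the reported room, log-summed over trials
and games, with each state space's term divided by log K (K = 3 and 16) so
the two chains contribute on a common scale.  Missed reports are excluded.
Model comparison treats -BIC/2 as the per-participant log model evidence
and runs the standard variational random-effects scheme over a Dirichlet
distribution of model frequencies, reporting expected model probabilities
(MF) and Monte-Carlo exceedance probabilities (XP).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize, special

from .hierarchical_model import BeliefModel, ModelParams
from .maze_env import MazeConfig

ETA_TD = 1.0 / math.log(3.0)
ETA_GR = 1.0 / math.log(16.0)

#: per-trial likelihood floor, applied before logs so the objective stays
#: finite when a report falls on a zero-mass state (possible at the edges
#: of the gamma/epsilon boxes)
LIKELIHOOD_FLOOR = 1e-6


# -- negative log evidence ---------------------------------------------------


@dataclass
class NLEResult:
    nle_td: float
    nle_gr: float
    nle_tot: float
    n_td: int
    n_gr: int

    @property
    def n_predictions(self) -> int:
        return self.n_td + self.n_gr


def negative_log_evidence(model: BeliefModel, params: ModelParams,
                          sessions: list, maze: MazeConfig,
                          floor: float = LIKELIHOOD_FLOOR) -> NLEResult:
    """Scaled NLE of the reported predictions under ``model``.

    Each scored trial contributes -log p(report)/log K for its chain;
    trials with missed reports contribute nothing.  An empty session
    scores (0, 0, 0)."""
    nle_td = 0.0
    nle_gr = 0.0
    n_td = 0
    n_gr = 0
    for game in sessions:
        if any(t.report_grid is not None and not 0 <= t.report_grid < maze.n_cells
               for t in game.trials):
            raise ValueError("session reports a room outside the given maze")
        trace = model.replay_game(game, params, maze)
        for t, trial in enumerate(game.trials):
            if trial.report_td is not None:
                nle_td -= math.log(max(trace.post_td[t, trial.report_td], floor))
                n_td += 1
            if trial.report_grid is not None:
                nle_gr -= math.log(max(trace.post_gr[t, trial.report_grid], floor))
                n_gr += 1
    return NLEResult(nle_td, nle_gr, ETA_TD * nle_td + ETA_GR * nle_gr,
                     n_td, n_gr)


# -- per-participant fit -----------------------------------------------------


@dataclass
class FitResult:
    model: str
    params: ModelParams
    nle_td: float
    nle_gr: float
    nle_tot: float
    n_predictions: int
    k_params: int
    bic: float

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {"delta": self.params.delta, "beta": self.params.beta,
                       "epsilon": self.params.epsilon,
                       "gamma": self.params.gamma},
            "nle_td": self.nle_td, "nle_gr": self.nle_gr,
            "nle_tot": self.nle_tot, "n_predictions": self.n_predictions,
            "k_params": self.k_params, "bic": self.bic,
        }


def _params_from_vector(model: BeliefModel, x: np.ndarray) -> ModelParams:
    base = ModelParams()
    return replace(base, **dict(zip(model.free_parameters, map(float, x))))


def fit_participant(model: BeliefModel, sessions: list, maze: MazeConfig,
                    seed: int = 0, grid_points: int = 5,
                    n_starts: int = 3, maxfev: int = 150,
                    bic_on: str = "unscaled") -> FitResult:
    """Estimate the model's free parameters for one participant.

    A coarse ``grid_points``-per-box grid scan is followed by bounded
    Nelder-Mead refinement from the best ``n_starts`` grid points.  The
    whole procedure is deterministic (the ``seed`` argument is kept for
    interface uniformity; nothing in the optimiser draws random numbers).

    The objective is the scaled ``nle_tot``; BIC is computed on the actual
    log evidence, 2 * (NLE_TD + NLE_GR) + k * log(n), with n the total
    number of scored prediction responses (tiger and grid counted
    separately) — the eta weights balance the two chains during fitting
    but do not define a deviance.  ``bic_on='scaled'`` switches to
    2 * nle_tot + k * log(n).
    """
    free = model.free_parameters
    if not free:
        raise ValueError(f"model {model.name} exposes no free parameters")
    n_scored = sum((t.report_td is not None) + (t.report_grid is not None)
                   for g in sessions for t in g.trials)
    if n_scored == 0:
        raise ValueError("no scored prediction trials to fit on")
    bounds = [ModelParams.BOUNDS[p] for p in free]

    def objective(x: np.ndarray) -> float:
        return negative_log_evidence(
            model, _params_from_vector(model, x), sessions, maze).nle_tot

    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]
    grid = np.array(list(itertools.product(*axes)))
    scores = np.array([objective(x) for x in grid])
    if not np.isfinite(scores).any():
        raise RuntimeError("optimizer never evaluated a finite objective")

    order = np.argsort(scores)
    best_x, best_f = grid[order[0]], scores[order[0]]
    for idx in order[:n_starts]:
        res = optimize.minimize(
            objective, grid[idx], method="Nelder-Mead", bounds=bounds,
            options={"maxfev": maxfev, "xatol": 1e-3, "fatol": 1e-4})
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = np.clip(res.x, [b[0] for b in bounds],
                                     [b[1] for b in bounds]), res.fun

    params = _params_from_vector(model, best_x)
    nle = negative_log_evidence(model, params, sessions, maze)
    k = len(free)
    deviance = nle.nle_tot if bic_on == "scaled" else nle.nle_td + nle.nle_gr
    bic = 2.0 * deviance + k * math.log(nle.n_predictions)
    return FitResult(model.name, params, nle.nle_td, nle.nle_gr,
                     nle.nle_tot, nle.n_predictions, k, bic)


# -- random-effects model selection -----------------------------------------


@dataclass
class BMSResult:
    model_names: tuple
    mf: np.ndarray         # expected model probabilities, sums to 1
    xp: np.ndarray         # exceedance probabilities, sums to 1
    alpha: np.ndarray      # fitted Dirichlet concentrations


def random_effects_bms(bic_table: np.ndarray,
                       model_names: Optional[tuple] = None,
                       seed: int = 0, n_samples: int = 200_000) -> BMSResult:
    """Random-effects Bayesian model selection from a participants x models
    BIC table.

    -BIC/2 is taken as the per-participant log model evidence; a
    variational scheme fits a Dirichlet over model frequencies
    (concentration 1 prior), whose mean gives the expected probabilities MF
    and whose seeded Monte-Carlo samples give the exceedance probabilities
    XP (probability each model is the most frequent)."""
    bic = np.asarray(bic_table, dtype=float)
    if bic.ndim != 2 or bic.shape[0] < 2 or bic.shape[1] < 2:
        raise ValueError("need a 2-D table with >=2 participants and >=2 models")
    if not np.isfinite(bic).all():
        raise ValueError("non-finite BIC values")
    n_subj, n_models = bic.shape
    if model_names is None:
        model_names = tuple(f"model{i}" for i in range(n_models))
    lme = -bic / 2.0

    alpha = np.ones(n_models)
    for _ in range(10_000):
        log_u = lme + special.digamma(alpha) - special.digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = 1.0 + u.sum(axis=0)
        if np.abs(new_alpha - alpha).max() < 1e-8:
            alpha = new_alpha
            break
        alpha = new_alpha

    mf = alpha / alpha.sum()
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    xp = np.bincount(winners, minlength=n_models) / n_samples
    return BMSResult(tuple(model_names), mf, xp, alpha)


# -- validation --------------------------------------------------------------


@dataclass
class AgreementResult:
    tiger: float
    grid: float
    tiger_on_errors: float   # agreement restricted to participant-incorrect trials
    grid_on_errors: float
    n_tiger: int
    n_grid: int


def prediction_agreement(model: BeliefModel, params: ModelParams,
                         sessions: list, maze: MazeConfig) -> AgreementResult:
    """Fraction of scored trials on which the model's MAP prediction equals
    the participant's report, overall and restricted to trials where the
    report differed from the true upcoming state.

    MAP tie-breaks are averaged analytically: a report inside the argmax
    set counts 1/|argmax set|, so the result is deterministic."""
    from .maze_env import true_tiger_direction

    td_terms, gr_terms = [], []
    td_err_terms, gr_err_terms = [], []
    tol = 1e-12
    for game in sessions:
        trace = model.replay_game(game, params, maze)
        for t, trial in enumerate(game.trials):
            has_next = t + 1 < len(game.trials)
            if trial.report_td is not None:
                p = trace.post_td[t]
                top = np.flatnonzero(p >= p.max() - tol)
                a = (1.0 / top.size) if trial.report_td in top else 0.0
                td_terms.append(a)
                if has_next and trial.report_td != true_tiger_direction(
                        game.trials[t + 1].pose, maze):
                    td_err_terms.append(a)
            if trial.report_grid is not None:
                p = trace.post_gr[t]
                top = np.flatnonzero(p >= p.max() - tol)
                a = (1.0 / top.size) if trial.report_grid in top else 0.0
                gr_terms.append(a)
                if has_next and trial.report_grid != game.trials[t + 1].pose.grid:
                    gr_err_terms.append(a)

    def _mean(xs):
        return float(np.mean(xs)) if xs else float("nan")

    return AgreementResult(_mean(td_terms), _mean(gr_terms),
                           _mean(td_err_terms), _mean(gr_err_terms),
                           len(td_terms), len(gr_terms))


@dataclass
class SplitValidation:
    fit: FitResult
    holdout_nle: NLEResult
    holdout_agreement: AgreementResult


def split_fit_validate(model: BeliefModel, sessions: list, maze: MazeConfig,
                       seed: int = 0, fit_half: str = "behavioural",
                       **fit_kwargs) -> SplitValidation:
    """Fit on one experiment half and evaluate NLE and agreement on the
    other, mirroring the anti-circularity split between the behavioural and
    scanning sessions.  Raises if either half is empty."""
    train = [g for g in sessions if g.half == fit_half]
    test = [g for g in sessions if g.half != fit_half]
    if not train or not test:
        raise ValueError("both experiment halves must be non-empty")
    fit = fit_participant(model, train, maze, seed=seed, **fit_kwargs)
    nle = negative_log_evidence(model, fit.params, test, maze)
    agree = prediction_agreement(model, fit.params, test, maze)
    return SplitValidation(fit, nle, agree)
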
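# tigermaze

Hierarchical belief inference in the Tiger-maze navigation task: a POMDP
maze simulator, four competing behavioural models of hidden-state
inference, maximum-likelihood parameter fitting with random-effects model
comparison, and entropy-based uncertainty analyses — all exercised
end-to-end on synthetic participants, so no human dataset is required.

## The problem

An agent explores a 4×4 grid of rooms with torus topology.  Every room has
four doors; exactly one (a *tiger door*, shared as an undirected edge with
the neighbouring room) must not be opened.  All rooms look identical, so
the agent's location s_GR (16 states) is hidden; so is the relative
direction s_TD ∈ {L, F, R} of the current room's tiger door.  Listening
yields a roar from the true tiger door with probability α = 0.85 and from
each normal door with probability 0.075; moving through a door relocates
the agent (and ends the game scoreless if the door was the tiger's).  The
two hidden states form a hierarchy: knowing the room determines the tiger
door through the memorised maze map, while roars inform the room only
indirectly.

The core model maintains coupled discrete posteriors P_t(s_TD) and
P_t(s_GR) whose information flow depends on the action:

* **Listen**: first a Bayes update of the tiger belief,
  P_{t+1}(s_TD) ∝ P_t(s_TD)·L(s_TD|v_t)^δ, then a three-way reweighting of
  the room belief according to whether each room's tiger direction matches
  the roar (weight (1−γ)β + γ(1−β)), differs (γβ + (1−γ)(1−β)), or lies
  behind the agent (γ).  If the roar contradicts the predicted (MAP) tiger
  direction, the model *re-estimates*: the same weighting applied to the
  room belief held on first entering the room (the anchor prior), mixed
  with the ordinary update with weight ε.
* **Move**: the room belief is pushed through the (bijective) maze
  transition map and the tiger belief is rebuilt as a γ-noised marginal of
  the room belief.

Free parameters and fitting boxes: δ ∈ [1,3] (observation sensitivity),
β ∈ [0.5,0.999] (tiger-dependence of the room update), ε ∈ [0,1]
(update probability under re-estimation), γ ∈ [0,0.3] (maze-memory error).
Competitors behind the same interface: a top-down model (room belief only,
tiger always its marginal; γ), a parallel model (independent chains; δ, γ),
and the hierarchical model without re-estimation (ε ≡ 1; δ, β, γ).

Models are scored per participant by the scaled negative log evidence of
the reported predictions, NLE_tot = NLE_TD/log 3 + NLE_GR/log 16, and
compared via BIC and random-effects Bayesian model selection (expected
model probabilities MF and exceedance probabilities XP).  Posterior
Shannon entropies of the two beliefs quantify the two levels of
uncertainty that the task's binary confidence reports track.

## Worked example

```python
import numpy as np
import tigermaze as tm

maze = tm.reference_maze()                      # fixed 4x4 torus, alpha=0.85
params = tm.ModelParams()                       # delta=1.8, beta=0.97, eps=0.14, gamma=0.074

# simulate one synthetic participant (24 games) in closed loop
p = tm.simulate_participant(params, tm.AgentPolicy(), maze, n_games=24, seed=7)
print(np.mean([g.n_trials for g in p.sessions]),
      np.mean([g.n_listen for g in p.sessions]))
# 11.375 5.0

# refit the generating model to the participant's reports
fit = tm.fit_participant(tm.HierarchicalModel(), p.sessions, maze)
print(round(fit.params.beta, 3), round(fit.params.gamma, 3), round(fit.bic, 1))
# 0.966 0.081 753.7
```

The first line says games last ~11 trials with ~5 listens each, matching
the task's descriptive ranges.  The refit recovers the tiger-dependence
weight β and memory error γ close to the generating values (0.97, 0.074);
BIC is the fit score used for model comparison.  See
`tigermaze --help` for the CLI (`simulate-env`, `simulate`, `fit`,
`compare`, `report`).

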
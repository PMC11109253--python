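# Methods

## Task model

The environment is a partially observable Markov decision process on an
n_rows × n_cols torus grid (4 × 4 by default, 16 rooms).  Tiger doors are
undirected edges between adjacent rooms forming a perfect matching, so
every room has exactly one tiger door and a tiger door seen as "front"
from one side is seen from the other side too.  `generate_maze` draws a
random perfect matching by seeded randomised greedy matching with bounded
retries; `reference_maze` is a fixed layout shipped as the common default
(the original task used one hand-designed maze whose edge list is not
available in machine-readable form, so the shipped layout is a synthetic
stand-in playing the same role).  All downstream code is maze-agnostic.

Rooms are indexed row-major with row 0 at the top; moving forward while
facing north from the top row wraps to the bottom row.  Relative
directions are L/F/R/Back; moving left or right rotates the body to the
direction of travel.  Listening produces a roar from the true tiger door
with probability α = 0.85 and from each of the two other visible doors
with probability 0.075; these are the task's stated observation
probabilities and α is configurable in (1/3, 1].

Games start from an initial (room, orientation) pair sampled uniformly
over states whose tiger door is not behind the agent.  The task never
states whether the tiger could start behind the participant, but the
model's room update assigns tiger-behind rooms the bare memory-error
weight precisely because the entry door was just traversed; sampling
initial states the same way keeps listening defined on every reachable
state and makes that exclusion an invariant rather than a reachable
truth.  Games end when the agent opens a tiger door ("eaten", score 0),
when more than eight distinct rooms have been visited (≥ 9 counting the
start room), or at a per-game trial limit drawn uniformly from 10–14.
The game score is N_exp·5 − N_lis·1 plus prediction rewards over trials
1..T−1; the published prediction-reward table was not released, so the
defaults (correct/high = 3, correct/low = 2, incorrect = 0, identical for
both prediction types) respect the stated ordering and are fully
configurable.

## Inference models

Belief state: a 3-vector over tiger direction, a 16-vector over rooms,
and the *anchor prior* — the room belief at the first trial after
entering the current room, refreshed exactly on moves.  All updates run
in linear space with per-step renormalization (state spaces of 3 and 16
make log-space unnecessary); vectors stay normalized to 1e-9.

Initialization: uniform over rooms; the initial tiger belief is the
γ-noised marginal of the uniform room belief at the observed starting
orientation.  (Initialization is not stated by the task description;
uniformity is the symmetric choice consistent with "unknown initial
state".)

**Hierarchical model** (δ, β, ε, γ).  Listen trials update the tiger
belief first — posterior ∝ prior × likelihood^δ — then reweight the room
belief three ways: rooms whose memorised tiger direction matches the roar
get (1−γ)β + γ(1−β), mismatching rooms γβ + (1−γ)(1−β), tiger-behind
rooms γ.  The *mode gate* compares the roar against the MAP tiger
direction of the **pre-roar** posterior (the prediction the agent
actually reported on the previous trial); the source equations can also
be read as gating on the post-roar posterior, so both readings are
switchable (`gate=`), as is the direction conditioning the re-estimation
weights (`reest_condition=`, default the post-roar MAP).  In
re-estimation mode the same weighting is applied to the anchor prior and
mixed with the ordinary update, weight ε on the latter.  Move trials push
the room belief through the transition permutation (a bijection, so
entropy is preserved and no renormalization is needed) and rebuild the
tiger belief as the γ-noised marginal restricted to the three visible
doors.

Degenerate corners: if a room update annihilates all mass (reachable
only at γ = 0 under exhaustive contradiction) the filter restarts from
the anchor prior with a warning — the fitted γ box keeps this
unreachable in practice, but the filter must be total.  MAP states used
*inside* updates break ties by first index (reproducible likelihoods);
only reported predictions break ties uniformly at random.

**Alternatives.**  Top-down (γ): the room belief is reweighted directly
against the roar with α in place of β; the tiger belief is always the
marginal.  Parallel (δ, γ): the chains never interact — the tiger chain
uses the roar Bayes update on listens and, on moves, zeroes the
moved-through direction and propagates through the empirical 3×3
direction-transition matrix counted over all rooms (rows without support
default to uniform so the propagation stays total; the post-move
orientation is derived deterministically from the move).  No
re-estimation (δ, β, γ): the hierarchical model with ε pinned to 1,
which provably collapses the re-estimation mixture onto the plain
update — one code path, no duplicate to test.

Entropies are Shannon entropies in natural log (the evidence scaling
uses unitless ratios, so only consistency of base matters).

## Fitting and model comparison

Per-trial likelihoods are the model posterior's mass on the reported
state (the smooth choice; tie-broken MAP probabilities would make the
objective piecewise constant), floored at 1e-6 so reports on zero-mass
states at the γ/ε box edges keep the objective finite.  Missed reports
are excluded.  The fitting objective is the scaled evidence
NLE_tot = NLE_TD/log 3 + NLE_GR/log 16, minimised per participant by a
5-points-per-box grid scan followed by bounded Nelder–Mead refinement
from the best three grid points (xatol 1e-3, fatol 1e-4, ≤150
evaluations per start); the procedure is deterministic.

BIC is computed on the unscaled deviance, 2·(NLE_TD + NLE_GR) +
k·log(n) with n the number of scored responses (tiger and grid counted
separately): the η weights balance the two chains during fitting but a
deviance must be an actual log evidence, and the published BIC
magnitudes are consistent with the unscaled convention.  A
`bic_on="scaled"` switch keeps the alternative.  Random-effects model
selection treats −BIC/2 as log model evidence and fits a Dirichlet over
model frequencies by the standard variational scheme (uniform
concentration prior, fixed point of the digamma responsibilities); MF is
the Dirichlet mean and XP the seeded Monte-Carlo probability that each
model's frequency is largest.

Prediction agreement averages MAP tie-breaks analytically (a report in
the argmax set counts 1/|set|), making the statistic deterministic.
`split_fit_validate` fits on the behavioural-experiment half and
evaluates evidence and agreement on the scanning half, mirroring the
anti-circularity split.

## Synthetic participants

The generator closes the loop between environment, a belief model, and a
deliberately plain exploration policy: listen whenever either posterior
entropy exceeds its threshold, otherwise move while avoiding the MAP
tiger direction, softmax-preferring directions whose belief-weighted
visit count is lowest.  The policy makes no claim to model human
exploration; it exists so the generated sessions carry the statistical
structure the analyses assume.

Reports are drawn from the model's posteriors (probability matching) by
default.  This is the choice that makes parameter recovery well-posed:
with posterior-sampled reports the expected negative log evidence is a
cross-entropy, minimised exactly at the generating parameters, whereas
pure MAP reporting rewards over-sharpened posteriors (biasing δ up and γ
down).  It is also consistent with the published human agreement rates
(≈87% tiger, ≈61% grid — about the mean posterior maxima, far from the
~100% that deterministic MAP reporting would produce).  MAP reporting
remains available (`report_style="map"`).  Confidence is high exactly
when the corresponding posterior entropy is below its threshold; misses
are injected independently at `miss_rate` for the action phase (state
unchanged for a trial) and for each report.

Policy defaults were calibrated once against the task's descriptive
statistics and then frozen: thresholds 0.5 nats (tiger) and 1.6 nats
(grid), confidence thresholds 0.5 and 1.0 nats, lapse 0, miss rate 0.05.
Default cohorts then show ≈5.2 listens per game, ≈11.2 trials per game
and ≈83% game success (reported: 5.0 ± 1.6, 10.9 ± 2.4, 81.3%), listen
proportion declining over trials, higher accuracy under high confidence,
and tiger uncertainty resolving before room uncertainty in Listen
trials.  These are the study conditions for every experiment below; they
were not revisited afterwards.

What the generator does **not** emulate: human exploration strategies
(approach–avoidance conflict, goal-directed coverage), sequential
dependencies in confidence reporting, lapses correlated with fatigue,
or any deviation of human inference from the generating model.  Passing
recovery and signature tests therefore shows that the pipeline is
self-consistent and well-posed at the published operating point — not
that humans obey the model.

## Experiment scales

Chosen so that each experiment is informative at desk scale:

* Parameter recovery — 10 participants × 12 games at the published
  cohort means (δ = 1.80, β = 0.97, ε = 0.14, γ = 0.074).  Recovery
  tolerances in the tests were calibrated from four independent repeated
  recovery runs before freezing: cohort-mean β and γ recover essentially
  unbiased (spreads ≈ ±0.02 and ±0.004); δ scatters upward (its
  likelihood is flat above the generating value and the box truncates at
  3); ε is weakly identified — few trials distinguish re-estimation from
  updating, so its maximum-likelihood estimates pile on the box bounds
  and the cohort mean drifts toward the box midpoint.  The published ε
  SD (0.29) already signals this weak identifiability; the tests
  accordingly do not assert ε recovery.
* Model recovery — 5 participants per generating model (each model's
  published mean parameters), fitted by all four models.  The top-down,
  parallel and no-re-estimation rows recover their generators.  For
  hierarchical-generated data the re-estimation parameter contributes
  ≈1–2 units of log evidence per participant at this scale, below the
  BIC penalty log(n) ≈ 5.4 for the fourth parameter, so BIC prefers the
  nested no-re-estimation model; the tests assert that confusion stays
  within the hierarchical family, a known limitation of BIC for nested
  models at small n rather than an implementation defect.
* Exceedance-probability dominance is checked at the published cohort
  size (20 participants), where a model better by ≥10 BIC for everyone
  reaches XP > 0.99; smaller cohorts cannot exceed that bound even under
  total dominance (with 5 participants, P(Beta(6,1) > 1/2) ≈ 0.984).

## Known limitations

* The shipped reference maze approximates, but is not, the original
  hand-designed maze.
* The BIC sample-size convention (n = scored responses) and the
  optimizer are this package's choices; the source analysis names
  neither.
* ε is structurally hard to estimate whenever agents move after one or
  two listens per room, because the anchor prior then rarely differs
  from the running room belief on re-estimation trials.
* The behavioural analyses report the tabulations and the standard tests
  (Wilcoxon signed-rank, Pearson/Spearman); repeated-measures ANOVAs on
  listen proportions are out of scope of the shipped tables.
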
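# Methods

## Task model

The engine implements an iterated, *simultaneous* prisoner's dilemma: on each
round the player's move and their answer to the prediction-registration
question are collected before the opponent's move is revealed; both moves are
then resolved against the payoff matrix and the full outcome is fed back to
the agent. The payoff matrix is configurable but validated against the PD
ordering T > R > P > S (defaults 5, 3, 1, 0). A session is four games, one
per opponent strategy, in an order drawn uniformly at random per participant;
round counts default to 20 (TFT, WSLS) and 10 (AC, AD). Agents receive an
`is_last_round` flag on the final round, mirroring the task's announcement of
the last round; the default agents ignore it.

Opponent strategies:

- **TFT** cooperates on round 1, then copies the player's previous move.
- **WSLS** opens with cooperation; thereafter it repeats its own previous
  move if its previous payoff was in the win set {T, R}, else switches. The
  opening move and the win/lose partition are not forced by the task
  description; cooperation on round 1 (symmetric with TFT) and the standard
  {T, R} / {P, S} partition are the conventional choices and are what this
  package uses. "Rewarded" is evaluated on the opponent's *own* payoff, not
  the joint outcome.
- **AC** / **AD** play a constant move regardless of history.

## Participant model

Nothing in the original task constrains participants' internal computations,
so the cognitive model is this package's own construction: the minimal model
that (a) produces all five behavioral metrics and (b) cleanly separates the
two candidate mechanisms for a reduced correct-prediction count.

Beliefs are independent Beta–Bernoulli posteriors over "opponent cooperates
next", one per context, where the context is the previous round's
(player, opponent) move pair plus a START context — five contexts in all.
This representation can learn both TFT-like contingencies (opponent's move
depends on my last move) and WSLS-like ones (depends on the last joint
outcome), while staying analytically transparent: after k defections in one
context with η = 1 and a (1, 1) prior, p = 1/(k+2).

Parameters (all validated at construction):

| parameter | range | default | role |
|---|---|---|---|
| θ (theta) | [0, 1] | 0.2 | registration confidence threshold — *reluctance* |
| ε (epsilon) | [0, 0.5] | 0.05 | prediction emission-noise probability — *accuracy impairment* |
| η (eta) | (0, 1] | 1.0 | belief memory decay — *learning impairment* |
| ω (omega) | ℝ | 2.0 | cooperation bias, utility units |
| τ (tau) | > 0 | 1.0 | softmax decision temperature |
| α₀, β₀ | > 0 | 1, 1 | prior pseudo-counts per context |

Per round, in task order: the agent derives (p, confidence) for the current
context with confidence = 2·|p − 0.5|; commits a move by sampling
P(C) = logistic((U_C − U_D + ω)/τ) (the move is chosen *before* the
prediction question, as in the task); registers iff confidence ≥ θ, the
registered move being C iff p ≥ 0.5, flipped with probability ε; then decays
the active context's counts by η and increments the observed outcome.

θ gates only registration and never accuracy among still-registered
predictions; ε degrades only accuracy and never the registration pattern
(with a shared random stream the registration sequence is bit-identical
across ε values — a property the tests exploit). These are the two
behavioral signatures the identifiability experiment separates.

Tie-breaks and edge cases: at p = 0.5 confidence is 0, so the prediction is
never registered for θ > 0; at θ = 0 every round registers and the tie
prediction is C. Against AC the θ = 0 agent is at ceiling from round 1 for
that reason (the tie-break already names the right move), so the
improves-over-rounds property is a statement about confidence-gated agents,
where round 1 can never register and later rounds mostly do. ω defaults to
2.0 so that default agents cooperate at realistic rates (≈ 50–70% depending
on beliefs) rather than collapsing to all-defect, which the unbiased softmax
would do since U_D > U_C for every p in a PD.

Beliefs reset between opponents: no transfer rule is defined by the task, and
independent games are the conservative choice.

## Synthetic cohorts

`generate_cohort` draws two groups with the study demographics — autism
n = 43 (35 male), IQ ~ N(105, 13.4²); control n = 42 (35 male), IQ ~
N(113, 11.6²); ages N(28, 9²) and N(26, 5.8²) — truncating IQ at 70 and age
at 18 by resampling (mirroring the adult, no-intellectual-disability inclusion
criteria), rounding IQ to an integer. Sex labels are assigned to match the
male counts exactly. Per-participant seeds derive from
SeedSequence(master_seed, group, index), so cohorts are reproducible and
extending one group leaves the other byte-identical.

Scenarios set the group parameter contrast, each moving exactly one knob:
reluctance θ = 0.6 vs 0.2; impairment_noise ε = 0.25 vs 0.05;
impairment_memory η = 0.6 vs 1.0; null = identical. These effect sizes are
calibration choices, not empirical claims; under this model the reluctance
default produces a declared-inability gap of roughly 20 rounds at study
scale — larger than the observed ≈ 10-round gap — which sharpens the
qualitative contrast without affecting any conclusion drawn here, since the
package's claims are about the *pattern* of significant terms, not effect
magnitudes.

What the generator does **not** emulate: the deposited data's covariance
structure between IQ and task behavior (synthetic IQ is independent of agent
parameters), comorbidity/medication, practice games, reaction times, or
within-session fatigue. Passing tests on synthetic cohorts therefore
demonstrate that the pipeline recovers known ground truth and that the two
mechanisms are statistically distinguishable at n = 200/group — not that
either mechanism describes real autistic participants.

## Statistics

OLS (via statsmodels) with classical unbiased-variance inference; the overall
F tests the two non-intercept terms jointly, df = (2, n − 3). The test suite
cross-checks coefficients, standard errors and F against an independent
normal-equations oracle at 1e−8 relative tolerance. The diagnosis indicator
defaults to autism = 1 (exposed as a flag; signs follow the coding). IQ
enters raw so coefficients stay on the metric's natural scale. Two-sided
p-values throughout; no multiple-testing correction is applied. Participants
who attempted no prediction or made no correct prediction are flagged and
excluded (the task's own exclusion rule); an undefined failed ratio
(0 attempts) is NaN and dropped from ratio analyses, never imputed.

Mann-Whitney U uses exact enumeration when min(n) ≤ 8 without ties, else the
normal approximation with tie and continuity corrections (cross-checked
against brute-force enumeration over all rank assignments). One-way ANOVA is
checked against the two-group F = t² identity. Quantiles use linear
interpolation between order statistics. The normality-screening rule that
decides between the two demographic tests is a judgment call in the original
analysis and is not automated here; `analyze` reports both tests.

The per-round accuracy curve counts a non-registered round as not-correct by
default (realized correct predictions per round); accuracy-among-attempts is
available via `mode="attempted"` since the figure being mirrored does not
state its denominator. Cooperation is reported both as a count and a
proportion; regressions default to the count.

## Problem sizes and runtime

Defaults were chosen so everything is interactive on one CPU: the study-scale
cohort (85 participants × 60 rounds) simulates in well under a second; the
identifiability experiment uses n = 200/group × 4 scenarios (≈ 1 s); the
property battery uses 1,000 simulated participants, 100 random OLS problems,
and exhaustive Mann-Whitney enumeration up to 8 + 8 samples. The full test
suite runs in a few seconds.

## Known limitations

- The cognitive model is deliberately minimal: no theory-of-mind recursion,
  no reinforcement-learning move policy, no cross-game transfer, no
  parameter fitting to individual humans.
- The reluctance/impairment separation holds within this model family;
  richer models could blur the signatures (e.g. confidence-dependent noise).
- The adapter for externally deposited datasets is mapping-driven because no
  canonical schema exists; reproducing published coefficients requires the
  original per-participant file, which is distributed with the article, not
  with this package.
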
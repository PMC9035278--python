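"""Parameterized participant models: beta-Bernoulli opponent learning with
confidence-gated prediction registration.

The model separates two mechanisms that both depress the number of correct
registered predictions but are observationally distinct:

* **reluctance** — a high registration threshold ``theta``: the agent forms
  predictions normally but declines to register them unless confident;
* **impairment** — either emission noise ``epsilon`` (a formed prediction is
  flipped before registration, degrading accuracy without touching the
  registration rate) or memory decay ``eta`` (beliefs are leaky, degrading
  both confidence and accuracy).

Beliefs are per-context Beta pseudo-counts over "opponent cooperates next",
keyed by the previous round's (player, opponent) move pair — a representation
rich enough to learn TFT-like and WSLS-like contingencies.  Moves follow a
softmax over expected payoffs plus a cooperation bias ``omega``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .pd_engine import DEFAULT_PAYOFFS, Move, PayoffMatrix

__all__ = [
    "AgentParams",
    "BeliefState",
    "Context",
    "START",
    "CONTEXTS",
    "beta_predict",
    "registration_decision",
    "cooperation_probability",
    "choose_move",
    "update_beliefs",
    "BetaBernoulliAgent",
]

#: Belief contexts: the previous round's (player, opponent) move pair, or
#: START on the first round of a game.
START = "START"
Context = "str | tuple[Move, Move]"
CONTEXTS: tuple = (
    START,
    (Move.C, Move.C),
    (Move.C, Move.D),
    (Move.D, Move.C),
    (Move.D, Move.D),
)


@dataclass(frozen=True)
class AgentParams:
    """Cognitive-model parameters.

    theta : registration confidence threshold in [0, 1]; a prediction is
        registered only when confidence >= theta.  Encodes reluctance.
    epsilon : emission-noise probability in [0, 0.5]; a registered prediction
        is flipped with this probability.  Pure accuracy impairment.
    eta : belief memory-decay factor in (0, 1]; pseudo-counts are multiplied
        by eta before each update.  eta < 1 is leaky memory.
    omega : cooperation bias in utility units added to the cooperate side of
        the move policy.
    tau : softmax decision temperature (> 0).
    alpha0, beta0 : prior pseudo-counts (> 0) for every context.
    """

    theta: float = 0.2
    epsilon: float = 0.05
    eta: float = 1.0
    omega: float = 2.0
    tau: float = 1.0
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must be in [0, 0.5]")
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must be in (0, 1]")
        if self.tau <= 0.0:
            raise ValueError("tau must be > 0")
        if self.alpha0 <= 0.0 or self.beta0 <= 0.0:
            raise ValueError("prior pseudo-counts must be > 0")


@dataclass
class BeliefState:
    """Per-context Beta pseudo-counts (alpha = cooperation, beta = defection)."""

    counts: dict = field(default_factory=dict)

    @classmethod
    def fresh(cls, alpha0: float = 1.0, beta0: float = 1.0) -> "BeliefState":
        return cls(counts={c: (alpha0, beta0) for c in CONTEXTS})

    def get(self, context) -> tuple[float, float]:
        try:
            return self.counts[context]
        except KeyError:
            raise ValueError(f"unknown belief context {context!r}") from None


def beta_predict(beliefs: BeliefState, context) -> tuple[float, float]:
    """Posterior-mean cooperation probability and a confidence score.

    p = alpha / (alpha + beta); confidence = 2 * |p - 0.5|, i.e. 0 at an
    uninformative posterior and 1 at certainty.
    """
    alpha, beta = beliefs.get(context)
    p = alpha / (alpha + beta)
    confidence = 2.0 * abs(p - 0.5)
    return p, confidence


def registration_decision(
    p: float,
    confidence: float,
    params: AgentParams,
    rng: np.random.Generator,
) -> tuple[bool, Optional[Move]]:
    """Answer the "can you predict your opponent's move?" question.

    Registration happens iff confidence >= theta — theta alone gates whether
    a prediction is registered.  A registered prediction is C when p >= 0.5,
    else D, then flipped with probability epsilon (epsilon never affects the
    registration outcome itself).  At p = 0.5 confidence is 0, so the tie is
    only reachable with theta = 0, where the pre-noise prediction is C.
    """
    registered = confidence >= params.theta
    if not registered:
        return False, None
    predicted = Move.C if p >= 0.5 else Move.D
    if params.epsilon > 0 and rng.random() < params.epsilon:
        predicted = Move.D if predicted is Move.C else Move.C
    return True, predicted


def cooperation_probability(
    p: float, params: AgentParams, payoffs: PayoffMatrix = DEFAULT_PAYOFFS
) -> float:
    """P(cooperate) under the softmax move policy.

    U_C = p*R + (1-p)*S, U_D = p*T + (1-p)*P;
    P(cooperate) = logistic((U_C - U_D + omega) / tau).  In a PD
    U_D > U_C for every p, so without the bias omega the greedy (tau -> 0)
    limit always defects.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    u_c = p * payoffs.R + (1.0 - p) * payoffs.S
    u_d = p * payoffs.T + (1.0 - p) * payoffs.P
    return float(expit((u_c - u_d + params.omega) / params.tau))


def choose_move(
    p: float,
    params: AgentParams,
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
    rng: Optional[np.random.Generator] = None,
) -> Move:
    """Sample a move from the softmax policy (see cooperation_probability)."""
    p_coop = cooperation_probability(p, params, payoffs)
    rng = rng if rng is not None else np.random.default_rng()
    return Move.C if rng.random() < p_coop else Move.D


def update_beliefs(
    beliefs: BeliefState,
    context,
    observed: Move,
    params: AgentParams,
) -> BeliefState:
    """Decay-then-increment update of the active context; others untouched."""
    alpha, beta = beliefs.get(context)
    alpha *= params.eta
    beta *= params.eta
    if Move.parse(observed) is Move.C:
        alpha += 1.0
    else:
        beta += 1.0
    new_counts = dict(beliefs.counts)
    new_counts[context] = (alpha, beta)
    return BeliefState(counts=new_counts)


class BetaBernoulliAgent:
    """A simulated participant implementing the engine's three-hook interface.

    Per round, in task order: derive (p, confidence) for the current context,
    commit a move (move first, prediction question second), answer the
    registration question, then observe the outcome and update beliefs.
    """

    def __init__(
        self,
        params: AgentParams = AgentParams(),
        payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
    ) -> None:
        self.params = params
        self.payoffs = payoffs
        self.beliefs = BeliefState.fresh(params.alpha0, params.beta0)
        self._context = START
        self._pending: Optional[tuple[float, float]] = None

    def reset(self, rng: np.random.Generator) -> None:
        self.beliefs = BeliefState.fresh(self.params.alpha0, self.params.beta0)
        self._context = START
        self._pending = None

    def choose_move(
        self, round_index: int, is_last_round: bool, rng: np.random.Generator
    ) -> Move:
        p, confidence = beta_predict(self.beliefs, self._context)
        self._pending = (p, confidence)
        return choose_move(p, self.params, self.payoffs, rng=rng)

    def predict(self, rng: np.random.Generator) -> tuple[bool, Optional[Move]]:
        if self._pending is None:
            raise RuntimeError("predict called before choose_move")
        p, confidence = self._pending
        return registration_decision(p, confidence, self.params, rng)

    def observe(
        self,
        player_move: Move,
        opponent_move: Move,
        player_payoff: float,
        opponent_payoff: float,
    ) -> None:
        self.beliefs = update_beliefs(
            self.beliefs, self._context, opponent_move, self.params
        )
        self._context = (player_move, opponent_move)
        self._pending = None
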
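"""Iterated, simultaneous prisoner's dilemma engine with a prediction-registration step.

Implements the task protocol: on every round the player commits a move and is
then asked whether they can predict the opponent's move (and, if so, for the
prediction itself) *before* the opponent's move is revealed.  Both moves are
resolved simultaneously against a standard PD payoff matrix (T > R > P > S).
Four scripted opponent strategies are provided: tit-for-tat (TFT),
win-stay-lose-shift (WSLS), always-cooperate (AC) and always-defect (AD).
A session is one participant's four games, one per strategy, in randomized
order: 20 rounds against TFT and WSLS, 10 against AC and AD by default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

__all__ = [
    "Move",
    "PayoffMatrix",
    "DEFAULT_PAYOFFS",
    "StrategyName",
    "STRATEGIES",
    "DEFAULT_ROUNDS",
    "PredictionRecord",
    "RoundRecord",
    "GameRecord",
    "SessionRecord",
    "SessionConfig",
    "Agent",
    "ScriptedAgent",
    "resolve_round",
    "opponent_move",
    "draw_opponent_order",
    "play_game",
    "play_session",
    "replay_check",
]


class Move(str, enum.Enum):
    """A binary PD choice: cooperate or defect.

    The task presented the choices as 'paper' (cooperate) and 'scissors'
    (defect) to avoid the social loading of the words themselves; those
    aliases are accepted on input, the canonical serialization is "C"/"D".
    """

    C = "C"
    D = "D"

    @classmethod
    def parse(cls, value: "str | Move") -> "Move":
        if isinstance(value, Move):
            return value
        key = str(value).strip().lower()
        aliases = {
            "c": cls.C,
            "cooperate": cls.C,
            "paper": cls.C,
            "d": cls.D,
            "defect": cls.D,
            "betray": cls.D,
            "scissors": cls.D,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unrecognized move {value!r}") from None

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class PayoffMatrix:
    """PD payoffs: temptation T, reward R, punishment P, sucker's payoff S.

    A prisoner's dilemma requires T > R > P > S, validated at construction.
    """

    T: float = 5.0
    R: float = 3.0
    P: float = 1.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError(
                f"payoffs must satisfy T > R > P > S, got "
                f"T={self.T}, R={self.R}, P={self.P}, S={self.S}"
            )


DEFAULT_PAYOFFS = PayoffMatrix()


class StrategyName(str, enum.Enum):
    """The four scripted opponent strategies."""

    TFT = "TFT"
    WSLS = "WSLS"
    AC = "AC"
    AD = "AD"

    @classmethod
    def parse(cls, value: "str | StrategyName") -> "StrategyName":
        if isinstance(value, StrategyName):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown strategy {value!r}") from None


STRATEGIES: tuple[StrategyName, ...] = (
    StrategyName.TFT,
    StrategyName.WSLS,
    StrategyName.AC,
    StrategyName.AD,
)

#: Round counts used in the study: 20 for the reactive strategies, 10 for the
#: constant ones (the opponent's response never changes, so fewer rounds
#: suffice).
DEFAULT_ROUNDS: dict[StrategyName, int] = {
    StrategyName.TFT: 20,
    StrategyName.WSLS: 20,
    StrategyName.AC: 10,
    StrategyName.AD: 10,
}


@dataclass(frozen=True)
class PredictionRecord:
    """Outcome of the per-round prediction-registration question.

    ``registered`` is the answer to "can you predict your opponent's move?".
    ``predicted_move`` and ``correct`` are present iff a prediction was
    registered; a round with ``registered=False`` is a declared inability.
    """

    registered: bool
    predicted_move: Optional[Move] = None
    correct: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.registered:
            if self.predicted_move is None or self.correct is None:
                raise ValueError(
                    "registered prediction requires predicted_move and correct"
                )
        else:
            if self.predicted_move is not None or self.correct is not None:
                raise ValueError(
                    "unregistered prediction must not carry a move or outcome"
                )


@dataclass(frozen=True)
class RoundRecord:
    """One simultaneous round: both moves, payoffs and the prediction outcome."""

    round_index: int  # 1-based
    player_move: Move
    opponent_move: Move
    prediction: PredictionRecord
    player_payoff: float
    opponent_payoff: float
    is_last_round: bool = False


@dataclass(frozen=True)
class GameRecord:
    """One game against a single scripted opponent."""

    strategy: StrategyName
    n_rounds: int
    rounds: tuple[RoundRecord, ...]

    def __post_init__(self) -> None:
        if len(self.rounds) != self.n_rounds:
            raise ValueError(
                f"{self.strategy.value}: expected {self.n_rounds} rounds, "
                f"got {len(self.rounds)}"
            )

    @property
    def player_score(self) -> float:
        return sum(r.player_payoff for r in self.rounds)

    @property
    def opponent_score(self) -> float:
        return sum(r.opponent_payoff for r in self.rounds)


@dataclass(frozen=True)
class SessionRecord:
    """One participant's full session: four games, one per strategy."""

    participant_id: str
    games: tuple[GameRecord, ...]

    def __post_init__(self) -> None:
        seen = [g.strategy for g in self.games]
        if sorted(s.value for s in seen) != sorted(s.value for s in STRATEGIES):
            raise ValueError("session must contain each strategy exactly once")

    @property
    def opponent_order(self) -> tuple[StrategyName, ...]:
        return tuple(g.strategy for g in self.games)

    @property
    def total_score(self) -> float:
        return sum(g.player_score for g in self.games)

    @property
    def total_rounds(self) -> int:
        return sum(g.n_rounds for g in self.games)


@dataclass(frozen=True)
class SessionConfig:
    """Payoff matrix and per-strategy round counts for a session."""

    payoffs: PayoffMatrix = DEFAULT_PAYOFFS
    rounds: dict[StrategyName, int] = field(
        default_factory=lambda: dict(DEFAULT_ROUNDS)
    )

    def __post_init__(self) -> None:
        for s in STRATEGIES:
            if self.rounds.get(s, 0) < 1:
                raise ValueError(f"round count for {s.value} must be >= 1")


# ---------------------------------------------------------------------------
# Agent interface
# ---------------------------------------------------------------------------


class Agent(Protocol):
    """The three-hook interface the engine drives each round.

    Call order per round mirrors the task: ``choose_move`` first, then
    ``predict`` (the registration question), and only afterwards does the
    agent ``observe`` the resolved outcome.  ``reset`` is called at the start
    of every game; beliefs do not carry over between opponents.
    """

    def reset(self, rng: np.random.Generator) -> None: ...

    def choose_move(
        self, round_index: int, is_last_round: bool, rng: np.random.Generator
    ) -> Move: ...

    def predict(
        self, rng: np.random.Generator
    ) -> tuple[bool, Optional[Move]]: ...

    def observe(
        self,
        player_move: Move,
        opponent_move: Move,
        player_payoff: float,
        opponent_payoff: float,
    ) -> None: ...


class ScriptedAgent:
    """Deterministic agent replaying a fixed move script; useful for traces.

    ``predictions`` is an optional parallel script of (registered, move)
    tuples; by default the agent declares inability every round.
    """

    def __init__(
        self,
        moves: Sequence["Move | str"],
        predictions: Optional[Sequence[tuple[bool, Optional["Move | str"]]]] = None,
        cycle: bool = True,
    ) -> None:
        self.moves = [Move.parse(m) for m in moves]
        self.predictions = (
            None
            if predictions is None
            else [
                (bool(reg), None if mv is None else Move.parse(mv))
                for reg, mv in predictions
            ]
        )
        self.cycle = cycle
        self._i = 0

    def reset(self, rng: np.random.Generator) -> None:
        self._i = 0

    def _index(self) -> int:
        i = self._i % len(self.moves) if self.cycle else self._i
        if i >= len(self.moves):
            raise IndexError("scripted agent ran out of moves")
        return i

    def choose_move(
        self, round_index: int, is_last_round: bool, rng: np.random.Generator
    ) -> Move:
        return self.moves[self._index()]

    def predict(self, rng: np.random.Generator) -> tuple[bool, Optional[Move]]:
        if self.predictions is None:
            return False, None
        return self.predictions[self._index()]

    def observe(
        self,
        player_move: Move,
        opponent_move: Move,
        player_payoff: float,
        opponent_payoff: float,
    ) -> None:
        self._i += 1


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def resolve_round(
    player_move: Move,
    opponent_move: Move,
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
) -> tuple[float, float]:
    """Resolve one simultaneous round, returning (player, opponent) payoffs.

    Mutual cooperation pays (R, R); mutual defection (P, P); a lone defector
    earns T against the cooperator's S.
    """
    player_move = Move.parse(player_move)
    opponent_move = Move.parse(opponent_move)
    table = {
        (Move.C, Move.C): (payoffs.R, payoffs.R),
        (Move.C, Move.D): (payoffs.S, payoffs.T),
        (Move.D, Move.C): (payoffs.T, payoffs.S),
        (Move.D, Move.D): (payoffs.P, payoffs.P),
    }
    return table[(player_move, opponent_move)]


def opponent_move(
    strategy: StrategyName,
    history: Sequence[tuple[Move, Move, float]],
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
) -> Move:
    """The scripted opponent's next move.

    ``history`` lists prior rounds of the current game oldest-first as
    (player_move, opponent_move, opponent_payoff) triples.

    * AC / AD ignore history entirely.
    * TFT cooperates on round one and thereafter copies the player's previous
      move.
    * WSLS opens with cooperation and then repeats its own previous move if
      its previous payoff was rewarding (T or R), otherwise switches.
    """
    strategy = StrategyName.parse(strategy)
    if strategy is StrategyName.AC:
        return Move.C
    if strategy is StrategyName.AD:
        return Move.D
    if strategy is StrategyName.TFT:
        if not history:
            return Move.C
        return history[-1][0]
    if strategy is StrategyName.WSLS:
        if not history:
            return Move.C
        _, own_prev, own_payoff = history[-1]
        rewarded = own_payoff in (payoffs.T, payoffs.R)
        if rewarded:
            return own_prev
        return Move.D if own_prev is Move.C else Move.C
    raise ValueError(f"unknown strategy {strategy!r}")  # pragma: no cover


def play_game(
    agent: Agent,
    strategy: StrategyName,
    n_rounds: int,
    payoffs: PayoffMatrix = DEFAULT_PAYOFFS,
    rng_seed: "int | np.random.Generator" = 0,
) -> GameRecord:
    """Run one game, enforcing the simultaneity and question-order contracts.

    Each round the agent commits a move, then answers the registration
    question; only afterwards is the opponent's move revealed and the round
    resolved.  The agent is notified (via ``is_last_round``) when the final
    round begins, matching the task.
    """
    strategy = StrategyName.parse(strategy)
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    agent.reset(rng)
    history: list[tuple[Move, Move, float]] = []
    rounds: list[RoundRecord] = []
    for r in range(1, n_rounds + 1):
        is_last = r == n_rounds
        try:
            player = agent.choose_move(r, is_last, rng)
            registered, predicted = agent.predict(rng)
        except Exception as exc:
            raise RuntimeError(
                f"agent hook failed at {strategy.value} round {r}: {exc}"
            ) from exc
        opp = opponent_move(strategy, history, payoffs)
        p_pay, o_pay = resolve_round(player, opp, payoffs)
        prediction = PredictionRecord(
            registered=registered,
            predicted_move=predicted if registered else None,
            correct=(predicted == opp) if registered else None,
        )
        rounds.append(
            RoundRecord(
                round_index=r,
                player_move=player,
                opponent_move=opp,
                prediction=prediction,
                player_payoff=p_pay,
                opponent_payoff=o_pay,
                is_last_round=is_last,
            )
        )
        agent.observe(player, opp, p_pay, o_pay)
        history.append((player, opp, o_pay))
    return GameRecord(strategy=strategy, n_rounds=n_rounds, rounds=tuple(rounds))


def draw_opponent_order(rng: np.random.Generator) -> tuple[StrategyName, ...]:
    """Uniformly random permutation of the four opponent strategies."""
    idx = rng.permutation(len(STRATEGIES))
    return tuple(STRATEGIES[i] for i in idx)


def play_session(
    agent: Agent,
    config: SessionConfig = SessionConfig(),
    rng_seed: int = 0,
    participant_id: str = "P0",
) -> SessionRecord:
    """Run one participant's session: four games in seeded random order.

    Agent state is reset at the start of each game (no belief carry-over
    between opponents).  The same seed and agent yield an identical record.
    """
    rng = np.random.default_rng(rng_seed)
    order = draw_opponent_order(rng)
    game_seeds = rng.integers(0, 2**31 - 1, size=len(order))
    games = tuple(
        play_game(
            agent,
            strat,
            config.rounds[strat],
            config.payoffs,
            int(seed),
        )
        for strat, seed in zip(order, game_seeds)
    )
    return SessionRecord(participant_id=participant_id, games=games)


def replay_check(session: SessionRecord, payoffs: PayoffMatrix = DEFAULT_PAYOFFS) -> bool:
    """Re-resolve every stored round; True iff all payoffs reproduce exactly."""
    for game in session.games:
        for rec in game.rounds:
            expect = resolve_round(rec.player_move, rec.opponent_move, payoffs)
            if expect != (rec.player_payoff, rec.opponent_payoff):
                return False
    return True
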
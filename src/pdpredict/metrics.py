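"""Per-participant behavioral metrics and per-round accuracy curves.

Five session-level metrics drive the group comparison: the number of correct
registered predictions, the number of rounds with a declared inability to
predict, the failed/attempted prediction ratio, the cooperation level, and
the total score.  Because every participant plays the same 60 rounds, the
three prediction counts partition the session exactly:

    correct + wrong_attempted + declared_inability = total_rounds
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pd_engine import STRATEGIES, GameRecord, SessionRecord, StrategyName

__all__ = [
    "ParticipantSummary",
    "summarize_rounds",
    "summarize_participant",
    "per_strategy_summary",
    "accuracy_curve",
    "summaries_frame",
    "METRIC_COLUMNS",
    "STRATEGY_PREFIX",
]

#: session-level metric column names used across the pipeline
METRIC_COLUMNS = (
    "correct_predictions",
    "declared_inability",
    "failed_ratio",
    "total_score",
    "cooperation_count",
)

STRATEGY_PREFIX = {
    StrategyName.TFT: "tft",
    StrategyName.WSLS: "wsls",
    StrategyName.AC: "ac",
    StrategyName.AD: "ad",
}


@dataclass(frozen=True)
class ParticipantSummary:
    """The behavioral metrics for one participant (or one game).

    ``failed_ratio`` is wrong/attempted and is NaN when no prediction was
    attempted.  ``excluded`` flags participants who attempted no prediction or
    made no correct prediction — the task's exclusion rule; such participants
    are dropped from ratio analyses rather than imputed.
    """

    total_rounds: int
    correct_predictions: int
    declared_inability: int
    wrong_attempted: int
    cooperation_count: int
    total_score: float

    @property
    def attempted(self) -> int:
        return self.correct_predictions + self.wrong_attempted

    @property
    def failed_ratio(self) -> float:
        if self.attempted == 0:
            return math.nan
        return self.wrong_attempted / self.attempted

    @property
    def cooperation_level(self) -> float:
        return self.cooperation_count / self.total_rounds

    @property
    def excluded(self) -> bool:
        return self.attempted == 0 or self.correct_predictions == 0


def summarize_rounds(rounds: Iterable, total_score: Optional[float] = None) -> ParticipantSummary:
    """Tally prediction / cooperation / score counts over an iterable of rounds."""
    correct = wrong = inability = coop = n = 0
    score = 0.0
    for rec in rounds:
        n += 1
        score += rec.player_payoff
        if rec.player_move.value == "C":
            coop += 1
        if not rec.prediction.registered:
            inability += 1
        elif rec.prediction.correct:
            correct += 1
        else:
            wrong += 1
    return ParticipantSummary(
        total_rounds=n,
        correct_predictions=correct,
        declared_inability=inability,
        wrong_attempted=wrong,
        cooperation_count=coop,
        total_score=score if total_score is None else total_score,
    )


def summarize_participant(session: SessionRecord) -> ParticipantSummary:
    """Session-level summary: the study metrics over all four games."""
    return summarize_rounds(r for g in session.games for r in g.rounds)


def per_strategy_summary(session: SessionRecord) -> dict[StrategyName, ParticipantSummary]:
    """The same metrics restricted to each opponent strategy's game."""
    return {g.strategy: summarize_rounds(g.rounds) for g in session.games}


def accuracy_curve(
    sessions: Sequence[SessionRecord],
    game_length: int = 20,
    mode: str = "all",
    strategy: Optional[StrategyName] = None,
) -> np.ndarray:
    """Proportion of correct registered predictions at each round number.

    Pools all games of ``game_length`` rounds across the given sessions
    (optionally restricted to one opponent ``strategy``).  With
    ``mode="all"`` the denominator at round r is every (participant, game)
    pair — a round without a registered prediction counts as not correct.
    ``mode="attempted"`` divides by registered predictions only (accuracy
    among attempts); rounds with no attempts anywhere give NaN.
    """
    if not sessions:
        raise ValueError("sessions must be non-empty")
    if mode not in ("all", "attempted"):
        raise ValueError("mode must be 'all' or 'attempted'")
    correct = np.zeros(game_length)
    denom = np.zeros(game_length)
    for session in sessions:
        for game in session.games:
            if game.n_rounds != game_length:
                continue
            if strategy is not None and game.strategy is not StrategyName.parse(strategy):
                continue
            for rec in game.rounds:
                i = rec.round_index - 1
                if mode == "all":
                    denom[i] += 1
                elif rec.prediction.registered:
                    denom[i] += 1
                if rec.prediction.registered and rec.prediction.correct:
                    correct[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, correct / np.maximum(denom, 1), np.nan)


def summaries_frame(
    participants: Sequence,
    sessions: Sequence[SessionRecord],
) -> pd.DataFrame:
    """One row per participant: covariates, session metrics, per-strategy metrics.

    ``participants`` are matched to ``sessions`` by participant id; an
    unmatched id on either side is an error.
    """
    by_id = {p.id: p for p in participants}
    if len(by_id) != len(participants):
        raise ValueError("duplicate participant ids")
    rows = []
    for session in sessions:
        try:
            part = by_id[session.participant_id]
        except KeyError:
            raise ValueError(
                f"session {session.participant_id!r} has no matching participant"
            ) from None
        s = summarize_participant(session)
        row: dict = {
            "participant_id": part.id,
            "group": part.group,
            "age": part.age,
            "sex": part.sex,
            "iq": part.iq,
            "total_rounds": s.total_rounds,
            "correct_predictions": s.correct_predictions,
            "declared_inability": s.declared_inability,
            "wrong_attempted": s.wrong_attempted,
            "attempted": s.attempted,
            "failed_ratio": s.failed_ratio,
            "cooperation_count": s.cooperation_count,
            "cooperation_level": s.cooperation_level,
            "total_score": s.total_score,
            "excluded": s.excluded,
        }
        for strat, gs in per_strategy_summary(session).items():
            pre = STRATEGY_PREFIX[strat]
            row[f"{pre}_correct_predictions"] = gs.correct_predictions
            row[f"{pre}_declared_inability"] = gs.declared_inability
            row[f"{pre}_failed_ratio"] = gs.failed_ratio
            row[f"{pre}_total_score"] = gs.total_score
            row[f"{pre}_cooperation_count"] = gs.cooperation_count
        rows.append(row)
    missing = set(by_id) - {s.participant_id for s in sessions}
    if missing:
        raise ValueError(f"participants without sessions: {sorted(missing)}")
    return pd.DataFrame(rows)
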
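"""Shared fixtures: hand-built games/sessions and a small simulated cohort."""

from __future__ import annotations

import pytest

from pdpredict.pd_engine import (
    DEFAULT_PAYOFFS,
    GameRecord,
    Move,
    PredictionRecord,
    RoundRecord,
    SessionRecord,
    StrategyName,
    resolve_round,
)


def build_game(strategy, rounds_spec):
    """Build a GameRecord from (player, opponent, registered, predicted) tuples.

    Payoffs and prediction correctness are derived, so hand-written fixtures
    satisfy the record invariants by construction.
    """
    strategy = StrategyName.parse(strategy)
    rounds = []
    n = len(rounds_spec)
    for i, (player, opp, registered, predicted) in enumerate(rounds_spec, start=1):
        player, opp = Move.parse(player), Move.parse(opp)
        if registered:
            predicted = Move.parse(predicted)
            pred = PredictionRecord(True, predicted, predicted == opp)
        else:
            pred = PredictionRecord(False)
        p_pay, o_pay = resolve_round(player, opp, DEFAULT_PAYOFFS)
        rounds.append(
            RoundRecord(
                round_index=i,
                player_move=player,
                opponent_move=opp,
                prediction=pred,
                player_payoff=p_pay,
                opponent_payoff=o_pay,
                is_last_round=i == n,
            )
        )
    return GameRecord(strategy=strategy, n_rounds=n, rounds=tuple(rounds))


def build_session(participant_id, games_spec):
    """Session from {strategy: rounds_spec}; must cover all four strategies."""
    games = tuple(build_game(s, spec) for s, spec in games_spec.items())
    return SessionRecord(participant_id=participant_id, games=games)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6+6 participant reluctance cohort with full sessions (fixed seed)."""
    from dataclasses import replace

    from pdpredict.synthetic_cohort import CohortConfig, generate_cohort

    base = CohortConfig()
    config = CohortConfig(
        autism=replace(base.autism, n=6, n_male=5),
        control=replace(base.control, n=6, n_male=5),
        scenario="reluctance",
        master_seed=7,
    )
    return generate_cohort(config)


@pytest.fixture()
def mixed_session():
    """Hand-built session with known tallies.

    TFT game (6 rounds): 3 correct, 1 wrong, 2 declared inability; 4 C moves.
    WSLS game (2 rounds): 1 correct, 1 inability; 1 C move.
    AC game (2 rounds): 2 correct; 2 C moves.
    AD game (2 rounds): 1 wrong, 1 inability; 0 C moves.
    Session: 12 rounds, 6 correct, 2 wrong, 4 inability, 7 cooperations.
    """
    return build_session(
        "P1",
        {
            "TFT": [
                ("C", "C", True, "C"),   # correct, payoff 3
                ("C", "C", True, "C"),   # correct, payoff 3
                ("D", "C", True, "D"),   # wrong (opp played C), payoff 5
                ("C", "D", False, None), # inability, payoff 0
                ("C", "C", True, "C"),   # correct, payoff 3
                ("D", "C", False, None), # inability, payoff 5
            ],
            "WSLS": [
                ("C", "C", True, "C"),   # correct, payoff 3
                ("D", "C", False, None), # inability, payoff 5
            ],
            "AC": [
                ("C", "C", True, "C"),   # correct, payoff 3
                ("C", "C", True, "C"),   # correct, payoff 3
            ],
            "AD": [
                ("D", "D", True, "C"),   # wrong, payoff 1
                ("D", "D", False, None), # inability, payoff 1
            ],
        },
    )
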
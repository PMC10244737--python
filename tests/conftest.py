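"""Shared fixtures: hand-built toy logs and session-scoped simulations."""

from __future__ import annotations

import pytest

from dispersim.game_model import (
    ColorRGB,
    Condition,
    GameLog,
    PadPoint,
    Signal,
    Trial,
    xy_to_rgb,
)
from dispersim.synthetic_data import SimConfig, simulate_dyad


def make_log(
    moves,
    condition: str = "outer_edge",
    pair_id: str = "toy",
) -> GameLog:
    """Build a valid log from (referent_id, (x, y), correct) triples.

    Senders alternate automatically, turns are numbered 1..n, colors follow
    the condition's pad-to-color law, and the guess is made consistent with
    the requested outcome.
    """
    cond = Condition.parse(condition)
    trials = []
    for i, (referent, xy, correct) in enumerate(moves):
        point = PadPoint(*xy)
        guess = referent if correct else (referent + 1) % 12
        trials.append(
            Trial(
                turn=i + 1,
                sender_id=i % 2,
                referent_id=referent,
                signal=Signal(colors=((point, xy_to_rgb(point, cond)),)),
                guess_id=guess,
                correct=correct,
            )
        )
    return GameLog(pair_id=pair_id, condition=cond, trials=trials)


@pytest.fixture(scope="session")
def toy_log() -> GameLog:
    """Ten turns, four referents, mixed outcomes, known coordinates."""
    moves = [
        (0, (0.1, 0.1), True),
        (1, (0.9, 0.9), True),
        (0, (0.1, 0.2), False),
        (2, (0.5, 0.5), True),
        (1, (0.9, 0.8), True),
        (3, (0.2, 0.8), False),
        (0, (0.15, 0.1), True),
        (2, (0.5, 0.55), True),
        (3, (0.25, 0.85), True),
        (1, (0.85, 0.9), True),
    ]
    return make_log(moves)


@pytest.fixture(scope="session")
def sim_logs_outer():
    """Twenty simulated outer-edge dyads, 200 turns each, default params."""
    return [
        simulate_dyad(
            SimConfig(n_turns=200, seed=1000 + s, pair_id=f"outer-{s}")
        )
        for s in range(20)
    ]


@pytest.fixture(scope="session")
def sim_logs_inner():
    """Six simulated inner-edge dyads for condition-contrast analyses."""
    return [
        simulate_dyad(
            SimConfig(
                condition="inner_edge",
                n_turns=200,
                seed=2000 + s,
                pair_id=f"inner-{s}",
            )
        )
        for s in range(6)
    ]
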
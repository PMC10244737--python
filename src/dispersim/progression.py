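"""Referent establishment and unlocking rules.

The game starts with 4 active referents. A referent counts as *established*
once it has been communicated successfully in at least three of the last
four rounds in which it occurred. When every active referent is established,
a block of 4 new referents unlocks, up to a cap of 12. ``s`` — the number of
currently established referents — is the per-round mastery count feeding the
success index.

Establishment is evaluated at the dyad level by default: a referent's
occurrence history pools both senders. A per-player variant is available via
``per_player=True`` on :class:`MasteryTracker` for success-by-player
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from .game_model import GameLog, Trial, ValidationError

__all__ = [
    "MasteryState",
    "MasteryTracker",
    "is_established",
    "step_mastery",
    "mastery_trajectory",
    "INITIAL_REFERENTS",
    "BLOCK_SIZE",
    "MAX_REFERENTS",
]

INITIAL_REFERENTS = 4
BLOCK_SIZE = 4
MAX_REFERENTS = 12

# minimum successes within the trailing window of (up to) 4 occurrences
WINDOW = 4
REQUIRED_SUCCESSES = 3


def is_established(outcome_history: Sequence[bool]) -> bool:
    """Whether a referent counts as established given its outcome history.

    ``outcome_history`` is ordered oldest-to-newest, one boolean per
    occurrence of the referent. Established means at least 3 successes among
    the last ``min(4, len)`` occurrences; with fewer than 3 occurrences the
    criterion cannot be met.
    """
    window = list(outcome_history)[-WINDOW:]
    return len(window) >= REQUIRED_SUCCESSES and sum(window) >= REQUIRED_SUCCESSES


@dataclass
class MasteryState:
    """Active referent set and per-referent establishment at one round."""

    active_referents: Tuple[int, ...]
    established: Dict[int, bool]

    def __post_init__(self) -> None:
        if len(self.active_referents) not in (4, 8, 12):
            raise ValidationError(
                f"active set size must be 4, 8 or 12: {len(self.active_referents)}"
            )
        for r in self.established:
            if r not in self.active_referents:
                raise ValidationError(f"established referent {r} is not active")

    @property
    def s(self) -> int:
        """Number of currently established referents."""
        return sum(bool(v) for v in self.established.values())

    @property
    def all_established(self) -> bool:
        return all(self.established.get(r, False) for r in self.active_referents)


def _initial_state() -> MasteryState:
    active = tuple(range(INITIAL_REFERENTS))
    return MasteryState(active, {r: False for r in active})


def step_mastery(
    state: MasteryState,
    trial: Trial,
    history: Dict[int, List[bool]],
) -> MasteryState:
    """Advance the mastery state by one round.

    ``history`` maps referent id to its outcome history *including* this
    trial's outcome. Re-evaluates establishment for the trial's referent and
    unlocks the next block of 4 referents if every active referent is
    established and fewer than 12 are active. Referents are never removed.
    """
    if trial.referent_id not in state.active_referents:
        raise ValidationError(
            f"trial referent {trial.referent_id} not in active set "
            f"{state.active_referents}"
        )
    established = dict(state.established)
    established[trial.referent_id] = is_established(
        history.get(trial.referent_id, [])
    )
    active = state.active_referents
    if all(established.get(r, False) for r in active) and len(active) < MAX_REFERENTS:
        new_block = tuple(range(len(active), len(active) + BLOCK_SIZE))
        active = active + new_block
        for r in new_block:
            established[r] = False
    return MasteryState(active, established)


class MasteryTracker:
    """Sequentially consume trials and expose the per-round mastery state.

    With ``per_player=True`` each player's occurrence history is tracked
    separately and establishment requires the criterion for the observing
    player; the default pools both senders (dyad-level establishment).
    Unlocking is always evaluated on the dyad-level state at round end.
    """

    def __init__(self, per_player: bool = False) -> None:
        self.per_player = per_player
        self.state = _initial_state()
        self._history: Dict[int, List[bool]] = {}
        self._player_history: Dict[Tuple[int, int], List[bool]] = {}
        self.s_series: List[int] = []
        self.active_size_series: List[int] = []
        self.unlock_turns: List[int] = []

    def update(self, trial: Trial) -> MasteryState:
        self._history.setdefault(trial.referent_id, []).append(trial.correct)
        self._player_history.setdefault(
            (trial.sender_id, trial.referent_id), []
        ).append(trial.correct)
        prev_size = len(self.state.active_referents)
        self.state = step_mastery(self.state, trial, self._history)
        if len(self.state.active_referents) > prev_size:
            self.unlock_turns.append(trial.turn)
        self.s_series.append(self.current_s(trial.sender_id))
        self.active_size_series.append(len(self.state.active_referents))
        return self.state

    def current_s(self, player_id: int = 0) -> int:
        if not self.per_player:
            return self.state.s
        return sum(
            is_established(self._player_history.get((player_id, r), []))
            for r in self.state.active_referents
        )


def mastery_trajectory(log: GameLog, per_player: bool = False) -> MasteryTracker:
    """Run the mastery rules over a whole log and return the tracker."""
    tracker = MasteryTracker(per_player=per_player)
    for trial in log:
        tracker.update(trial)
    return tracker
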
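"""Agent-based simulator of dyads playing the color-signaling game.

The simulator reproduces, by construction, the behavioral regularities the
analysis pipeline is designed to detect:

* initial exploration in a comfortable diagonal band of the pad (positive
  x-y correlation; the bottom strip is avoided), reflecting the reach of a
  right-handed finger resting at the bottom of a trackpad;
* increasing motor precision with practice (per-turn decay of motor noise);
* outcome-contingent signal choice — after a success for a referent the
  sender stays close to the last signal that worked, after a failure a new
  candidate is tried, repelled from the points already claimed by other
  referents (the distinctiveness pressure from which above-chance
  dispersion emerges);
* a receiver that classifies the observed color to the nearest remembered
  exemplar in RGB space. The original study does not model receivers; this
  nearest-exemplar rule is the minimal classifier consistent with the task.
  Condition asymmetry needs no hand-coding: under the inner-edge law,
  extreme pad points map to dark, confusable colors, so perception alone
  makes them poor signals.

Each simulated turn emits one effective color token; the log format supports
multi-token signals but the generator does not produce them by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .game_model import (
    ColorRGB,
    Condition,
    GameLog,
    PadPoint,
    Signal,
    Trial,
    xy_to_rgb,
)
from .progression import MasteryTracker

__all__ = [
    "AgentParams",
    "SimConfig",
    "sample_initial_point",
    "motor_sd_at",
    "sender_policy",
    "receiver_policy",
    "simulate_dyad",
    "simulate_many",
]


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one simulated player.

    comfort_correlation: target correlation between x and y of initial
        exploration draws (diagonal comfort band), default 0.4.
    comfort_exclusion: fraction of the pad's bottom excluded from initial
        sampling (hard to reach without moving the palm), default 0.25.
    motor_sd0 / motor_sd_min / motor_decay: motor noise starts at
        ``motor_sd0`` (pad units) and decays multiplicatively by
        ``motor_decay`` per send toward ``motor_sd_min``.
    stay_prob_success: probability of reusing the last successful point for
        a referent rather than re-exploring, default 0.95.
    repel_weight: strength of the distinctiveness pressure pushing new
        candidates away from already-established points.
    perceptual_sd: receiver noise (sd per RGB channel).
    n_candidates: candidate draws scored when exploring a new point.
    """

    comfort_correlation: float = 0.4
    comfort_exclusion: float = 0.25
    motor_sd0: float = 0.08
    motor_sd_min: float = 0.015
    motor_decay: float = 0.015
    stay_prob_success: float = 0.95
    repel_weight: float = 1.0
    perceptual_sd: float = 0.05
    n_candidates: int = 12

    def __post_init__(self) -> None:
        if not (0.0 <= self.stay_prob_success <= 1.0):
            raise ValueError("stay_prob_success must be a probability")
        if not (0.0 <= self.comfort_exclusion < 1.0):
            raise ValueError("comfort_exclusion must be in [0,1)")
        if not (-1.0 < self.comfort_correlation < 1.0):
            raise ValueError("comfort_correlation must be in (-1,1)")
        for name in ("motor_sd0", "motor_sd_min", "perceptual_sd", "repel_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """One simulated game: condition, length, seed, per-player parameters."""

    condition: Condition = Condition.OUTER_EDGE
    n_turns: int = 250
    seed: int = 0
    pair_id: str = "sim-0"
    params: Tuple[AgentParams, AgentParams] = (AgentParams(), AgentParams())

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition.parse(self.condition))
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")


def sample_initial_point(params: AgentParams, rng: np.random.Generator) -> PadPoint:
    """Draw an exploration point from the diagonal comfort band.

    x is uniform; y mixes x with an independent uniform so that
    corr(x, y) equals ``comfort_correlation``, then is rescaled into
    [comfort_exclusion, 1] so the bottom strip is never sampled.
    """
    rho = params.comfort_correlation
    denom = rho + math.sqrt(max(1.0 - rho * rho, 0.0))
    w = rho / denom if denom > 0 else 0.0
    x = rng.random()
    raw = w * x + (1.0 - w) * rng.random()  # in [0, 1]
    y = params.comfort_exclusion + (1.0 - params.comfort_exclusion) * raw
    return PadPoint(x, min(y, 1.0))


def motor_sd_at(params: AgentParams, n_sends: int) -> float:
    """Motor noise sd after ``n_sends`` practiced sends (geometric decay)."""
    return params.motor_sd_min + (params.motor_sd0 - params.motor_sd_min) * (
        1.0 - params.motor_decay
    ) ** n_sends


def _clip_point(x: float, y: float) -> PadPoint:
    return PadPoint(min(max(x, 0.0), 1.0), min(max(y, 0.0), 1.0))


@dataclass
class _PlayerState:
    """Mutable per-player memory during a simulation."""

    params: AgentParams
    n_sends: int = 0
    # receiver memory: per referent, the last color confirmed by feedback
    exemplars: Dict[int, ColorRGB] = field(default_factory=dict)


def sender_policy(
    last_signal: Optional[Tuple[PadPoint, bool]],
    established_points: List[PadPoint],
    params: AgentParams,
    n_sends: int,
    rng: np.random.Generator,
) -> PadPoint:
    """Choose the pad point for one send.

    ``last_signal`` is the dyad's most recent (point, outcome) for the
    referent, or None if it has never been signaled. After a success the
    sender reuses that point plus motor noise (with probability
    ``stay_prob_success``); otherwise a new candidate is drawn and scored by
    its minimum distance to the established points of other referents,
    weighted by ``repel_weight`` — the distinctiveness pressure. A
    referent's first-ever candidate comes from the diagonal comfort band;
    re-exploration after a failure samples the whole pad, mirroring how
    players reach more of the space once practiced. With
    ``repel_weight = 0`` the first candidate is taken unscored.
    """
    sd = motor_sd_at(params, n_sends)
    if (
        last_signal is not None
        and last_signal[1]
        and rng.random() < params.stay_prob_success
    ):
        base = last_signal[0]
        dx, dy = rng.normal(0.0, sd, size=2)
        return _clip_point(base.x + dx, base.y + dy)
    n_cand = max(params.n_candidates, 1)
    if last_signal is None:
        candidates = [sample_initial_point(params, rng) for _ in range(n_cand)]
    else:
        candidates = [PadPoint(*rng.random(2)) for _ in range(n_cand)]
    if params.repel_weight <= 0 or not established_points:
        choice = candidates[0]
    else:
        scores = [
            params.repel_weight
            * min(c.distance_to(p) for p in established_points)
            for c in candidates
        ]
        choice = candidates[int(np.argmax(scores))]
    dx, dy = rng.normal(0.0, sd, size=2)
    return _clip_point(choice.x + dx, choice.y + dy)


def receiver_policy(
    observed: ColorRGB,
    memory: Dict[int, ColorRGB],
    active_referents: Tuple[int, ...],
    params: AgentParams,
    rng: np.random.Generator,
) -> int:
    """Guess the referent for an observed color.

    The observed color is perturbed by Gaussian perceptual noise per channel
    and matched to the nearest remembered exemplar in RGB Euclidean
    distance; ties break to the lowest referent id. With no memory the guess
    is uniform over the active referents.
    """
    known = [r for r in sorted(memory) if r in active_referents]
    if not known:
        return int(rng.choice(active_referents))
    noise = rng.normal(0.0, params.perceptual_sd, size=3)
    perceived = (
        min(max(observed.r + noise[0], 0.0), 1.0),
        min(max(observed.g + noise[1], 0.0), 1.0),
        min(max(observed.b + noise[2], 0.0), 1.0),
    )
    best_r, best_d = known[0], float("inf")
    for r in known:
        ex = memory[r]
        d = math.sqrt(
            (perceived[0] - ex.r) ** 2
            + (perceived[1] - ex.g) ** 2
            + (perceived[2] - ex.b) ** 2
        )
        if d < best_d:  # strict: ties keep the lowest referent id
            best_r, best_d = r, d
    return best_r


def simulate_dyad(config: SimConfig) -> GameLog:
    """Simulate one dyad playing ``config.n_turns`` turns.

    Senders alternate each turn; the referent is drawn uniformly from the
    currently active set; mastery/unlocking rules are applied at round end;
    both players receive outcome feedback (the receiver learns the true
    referent's color, the sender records the outcome). Reproducible given
    the seed; all randomness flows from one generator.
    """
    rng = np.random.default_rng(config.seed)
    players = [_PlayerState(config.params[0]), _PlayerState(config.params[1])]
    tracker = MasteryTracker()
    # dyad-level last (point, outcome) per referent, shared signal memory
    last_signal: Dict[int, Tuple[PadPoint, bool]] = {}
    trials: List[Trial] = []

    for turn in range(1, config.n_turns + 1):
        sender_id = (turn - 1) % 2
        sender = players[sender_id]
        receiver = players[1 - sender_id]
        active = tracker.state.active_referents
        referent = int(rng.choice(active))

        established_points = [
            last_signal[r][0]
            for r in active
            if r != referent
            and tracker.state.established.get(r, False)
            and r in last_signal
        ]
        point = sender_policy(
            last_signal.get(referent),
            established_points,
            sender.params,
            sender.n_sends,
            rng,
        )
        sender.n_sends += 1
        color = xy_to_rgb(point, config.condition)
        guess = receiver_policy(
            color, receiver.exemplars, active, receiver.params, rng
        )
        correct = guess == referent
        trial = Trial(
            turn=turn,
            sender_id=sender_id,
            referent_id=referent,
            signal=Signal(colors=((point, color),)),
            guess_id=guess,
            correct=correct,
        )
        trials.append(trial)
        tracker.update(trial)
        # feedback: both players learn the true referent's color
        receiver.exemplars[referent] = color
        sender.exemplars[referent] = color
        last_signal[referent] = (point, correct)

    return GameLog(
        pair_id=config.pair_id,
        condition=config.condition,
        trials=trials,
        seed=config.seed,
    )


def simulate_many(
    n_dyads: int,
    condition: "str | Condition" = Condition.OUTER_EDGE,
    n_turns: int = 250,
    seed: int = 0,
    params: Optional[AgentParams] = None,
) -> List[GameLog]:
    """Simulate ``n_dyads`` independent games with per-dyad derived seeds."""
    condition = Condition.parse(condition)
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n_dyads)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        p = params or AgentParams()
        out.append(
            simulate_dyad(
                SimConfig(
                    condition=condition,
                    n_turns=n_turns,
                    seed=child_seed,
                    pair_id=f"sim-{condition.value}-{i}",
                    params=(p, p),
                )
            )
        )
    return out
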
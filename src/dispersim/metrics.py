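"""Per-log statistics: success index, dispersion measures, extremeness,
auto/partner distance, rolling dispersion, and signal-area clouds.

All distance-based measures operate on the first-color pad point of each
turn; inventory-level variants accept arbitrary point sets (e.g., phoneme
centroids) directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .game_model import (
    MAX_RADIUS,
    GameLog,
    PadPoint,
    Trial,
    distance_from_center,
    first_color,
)
from .progression import mastery_trajectory

__all__ = [
    "success_index",
    "success_index_from_counts",
    "mean_pairwise_distance",
    "mean_distance_from_center",
    "mode_brightness",
    "extremeness_index",
    "auto_distance",
    "partner_distance",
    "rolling_dispersion",
    "signal_area",
    "quintile_areas",
    "quintile_bounds",
    "descriptive_counts",
    "turn_series",
    "CloudSummary",
]


def success_index_from_counts(s_series: Sequence[int]) -> float:
    """Success index from per-round established-word counts: the cumulative
    count normalized by 12 * n_rounds, its maximum given 12 referents."""
    if len(s_series) == 0:
        raise ValueError("success index is undefined for zero rounds")
    return float(sum(s_series)) / (12.0 * len(s_series))


def success_index(log: GameLog) -> float:
    """Cumulative established-word count normalized by its maximum.

    For each round i, s_i is the number of currently established referents;
    the index is (sum_i s_i) / (12 * n_r) where n_r is the number of rounds,
    so it lies in [0, 1] and equals 1 only if all 12 referents are
    established on every round.
    """
    if len(log) == 0:
        raise ValueError("success_index is undefined for an empty log")
    tracker = mastery_trajectory(log)
    return success_index_from_counts(tracker.s_series)


def _as_array(points: Sequence) -> np.ndarray:
    arr = np.asarray(
        [(p.x, p.y) if isinstance(p, PadPoint) else tuple(p) for p in points],
        dtype=float,
    )
    return arr.reshape(-1, 2)


def mean_pairwise_distance(points: Sequence) -> float:
    """Mean Euclidean distance over all unordered pairs of points."""
    arr = _as_array(points)
    if len(arr) < 2:
        raise ValueError("mean pairwise distance requires at least 2 points")
    diffs = arr[:, None, :] - arr[None, :, :]
    d = np.sqrt((diffs**2).sum(-1))
    iu = np.triu_indices(len(arr), k=1)
    return float(d[iu].mean())


def mean_distance_from_center(points: Sequence) -> float:
    """Mean Euclidean distance of points from the pad center (0.5, 0.5)."""
    arr = _as_array(points)
    if len(arr) == 0:
        raise ValueError("mean distance from center requires at least 1 point")
    return float(np.hypot(arr[:, 0] - 0.5, arr[:, 1] - 0.5).mean())


def mode_brightness(inventory: Sequence[Sequence]) -> float:
    """Mean over phonemes of the average brightest RGB channel.

    ``inventory`` is a list of phonemes, each a non-empty list of colors
    (objects with a ``brightness`` attribute, or RGB triples).
    """
    if len(inventory) == 0:
        raise ValueError("mode brightness requires a non-empty inventory")
    per_phoneme = []
    for phoneme in inventory:
        if len(phoneme) == 0:
            raise ValueError("every phoneme must have at least one exemplar")
        vals = [
            c.brightness if hasattr(c, "brightness") else max(c) for c in phoneme
        ]
        per_phoneme.append(float(np.mean(vals)))
    return float(np.mean(per_phoneme))


def extremeness_index(point: PadPoint) -> float:
    """|norm_dist - 0.5| / 0.5, where norm_dist is the distance from the pad
    center normalized by the center-to-corner distance.

    Scores 1 at the absolute center and at the corners, 0 on the ring
    exactly halfway between center and corner.
    """
    norm_dist = distance_from_center(point) / MAX_RADIUS
    return abs(norm_dist - 0.5) / 0.5


def _last_index_by(log: GameLog, trial: Trial, same_player: bool) -> Optional[int]:
    """Index of the most recent prior trial for the same referent by the
    same player (``same_player``) or the partner."""
    target_sender = trial.sender_id if same_player else 1 - trial.sender_id
    idx = log.trials.index(trial)
    for j in range(idx - 1, -1, -1):
        prev = log.trials[j]
        if prev.referent_id == trial.referent_id and prev.sender_id == target_sender:
            return j
    return None


def auto_distance(log: GameLog, trial: Trial) -> Optional[float]:
    """Distance between this trial's first-color point and the same player's
    most recent prior point for the same referent; None if none exists."""
    j = _last_index_by(log, trial, same_player=True)
    if j is None:
        return None
    return trial.first_point.distance_to(log.trials[j].first_point)


def partner_distance(log: GameLog, trial: Trial) -> Optional[float]:
    """Distance between this trial's first-color point and the partner's
    most recent point for the same referent; None if the partner has never
    signaled this referent."""
    j = _last_index_by(log, trial, same_player=False)
    if j is None:
        return None
    return trial.first_point.distance_to(log.trials[j].first_point)


def rolling_dispersion(log: GameLog, turn: int) -> Optional[float]:
    """Mean pairwise distance among the most recent successful signal per
    referent at or before ``turn``; None if fewer than 2 referents have a
    successful signal by then."""
    latest: Dict[int, PadPoint] = {}
    for t in log:
        if t.turn > turn:
            break
        if t.correct:
            latest[t.referent_id] = t.first_point
    if len(latest) < 2:
        return None
    return mean_pairwise_distance(list(latest.values()))


def signal_area(cloud: Sequence) -> float:
    """Area of the ellipse spanned by a coordinate cloud.

    Points whose distance from the cloud centroid exceeds mean + 2 SD of
    those distances are removed (once, not iterated). The survivors are
    centered and projected onto their first two principal components; the
    ellipse's width and height are the coordinate ranges along PC1 and PC2
    and its area is pi * (width/2) * (height/2). Degenerate clouds (<= 1
    surviving point, or collinear) give 0. Areas are in pad units squared,
    so the whole space has area 1.
    """
    arr = _as_array(cloud)
    if len(arr) == 0:
        raise ValueError("signal_area requires a non-empty cloud")
    centroid = arr.mean(axis=0)
    dists = np.hypot(*(arr - centroid).T)
    keep = dists <= dists.mean() + 2.0 * dists.std()
    arr = arr[keep]
    if len(arr) <= 1:
        return 0.0
    centered = arr - arr.mean(axis=0)
    # principal axes via SVD of the centered cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    projected = centered @ vt.T
    width = float(projected[:, 0].max() - projected[:, 0].min())
    height = 0.0
    if projected.shape[1] > 1:
        height = float(projected[:, 1].max() - projected[:, 1].min())
    return math.pi * (width / 2.0) * (height / 2.0)


@dataclass(frozen=True)
class CloudSummary:
    """Signal-area summary for one referent in one quintile of a game."""

    referent_id: int
    quintile: int  # 1-5
    n_points: int
    area: float


def quintile_bounds(n_turns: int) -> List[Tuple[int, int]]:
    """Half-open index ranges splitting ``n_turns`` turns into 5 contiguous
    blocks; earlier blocks absorb any remainder (sizes differ by <= 1)."""
    sizes = [n_turns // 5 + (1 if i < n_turns % 5 else 0) for i in range(5)]
    bounds, start = [], 0
    for size in sizes:
        bounds.append((start, start + size))
        start += size
    return bounds


def quintile_areas(log: GameLog) -> List[CloudSummary]:
    """Signal areas per (quintile, referent).

    The turn sequence is split into 5 contiguous blocks; within each block
    the coordinate cloud for a referent is the set of first-color points of
    its successful trials. Referents with no successful trial in a quintile
    are omitted.
    """
    if len(log) < 5:
        raise ValueError("quintile analysis requires at least 5 turns")
    summaries: List[CloudSummary] = []
    for q, (lo, hi) in enumerate(quintile_bounds(len(log)), start=1):
        clouds: Dict[int, List[PadPoint]] = {}
        for t in log.trials[lo:hi]:
            if t.correct:
                clouds.setdefault(t.referent_id, []).append(t.first_point)
        for rid in sorted(clouds):
            pts = clouds[rid]
            summaries.append(
                CloudSummary(rid, q, len(pts), signal_area(pts))
            )
    return summaries


def descriptive_counts(log: GameLog) -> Dict[str, float]:
    """End-of-game counts: final number of established signals, mean word
    length (color tokens per signal), and phoneme count."""
    from .phoneme_inventory import identify_phonemes

    tracker = mastery_trajectory(log)
    mean_word_length = float(np.mean([len(t.signal) for t in log]))
    inventory = identify_phonemes(log)
    return {
        "final_established": float(tracker.state.s),
        "mean_word_length": mean_word_length,
        "n_phonemes": float(len(inventory.phonemes)),
    }


def turn_series(log: GameLog) -> pd.DataFrame:
    """One row of derived quantities per trial.

    Columns: pair_id, condition, turn, sender_id, referent_id, x, y,
    correct, dist_center, extremeness, auto_distance, partner_distance,
    rolling_dispersion, last_outcome_same_referent, quintile,
    turns_since_new_referent, referent_set. Missing values are NaN (e.g.
    auto_distance on a referent's first per-player occurrence).
    """
    tracker = mastery_trajectory(log)
    unlock_turns = list(tracker.unlock_turns)
    bounds = quintile_bounds(len(log)) if len(log) >= 5 else None

    last_outcome: Dict[int, bool] = {}
    rows = []
    for i, t in enumerate(log):
        p = t.first_point
        quintile = np.nan
        if bounds is not None:
            for q, (lo, hi) in enumerate(bounds, start=1):
                if lo <= i < hi:
                    quintile = q
                    break
        # game start counts as an unlock at turn 0, so the first turn after
        # any unlock event scores 0
        last_unlock = max((u for u in unlock_turns if u < t.turn), default=0)
        ad = auto_distance(log, t)
        pdist = partner_distance(log, t)
        rd = rolling_dispersion(log, t.turn)
        rows.append(
            {
                "pair_id": log.pair_id,
                "condition": log.condition.value,
                "turn": t.turn,
                "sender_id": t.sender_id,
                "referent_id": t.referent_id,
                "x": p.x,
                "y": p.y,
                "correct": t.correct,
                "dist_center": distance_from_center(p),
                "extremeness": extremeness_index(p),
                "auto_distance": np.nan if ad is None else ad,
                "partner_distance": np.nan if pdist is None else pdist,
                "rolling_dispersion": np.nan if rd is None else rd,
                "last_outcome_same_referent": last_outcome.get(
                    t.referent_id, np.nan
                ),
                "quintile": quintile,
                "turns_since_new_referent": t.turn - last_unlock - 1,
                "referent_set": t.referent_id // 4 + 1,
                "s": tracker.s_series[i],
                "active_set_size": tracker.active_size_series[i],
            }
        )
        last_outcome[t.referent_id] = t.correct
    return pd.DataFrame(rows)
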
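"""Color-phoneme identification via Pillai-trace merging.

A dyad's colors are pooled per referent and statistically indistinguishable
groups are merged into shared "phonemes": meaningless reusable signal units,
analogous to the Pillai-score treatment of vowel mergers in sociophonetics.
The Pillai-Bartlett trace of a two-group MANOVA on the 2-D pad coordinates
measures multivariate separation in [0, 1]; groups scoring below a merge
threshold are considered one category.

The original study's exact merge criterion is not published; the greedy
lowest-score-first procedure and the default threshold of 0.3 here are a
documented reconstruction, exposed as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .game_model import GameLog, PadPoint

__all__ = ["Inventory", "pillai_score", "identify_phonemes"]

MIN_GROUP_SIZE = 3
DEFAULT_MERGE_THRESHOLD = 0.3
RIDGE = 1e-10  # regularization added to a singular pooled covariance


@dataclass
class Inventory:
    """Phoneme groups for one dyad, with the merge trace that produced them.

    Each phoneme is a list of (PadPoint, ColorRGB) exemplars; ``labels``
    records which referent ids were pooled into each phoneme, and
    ``merge_trace`` lists (group_a, group_b, pillai_score) in merge order.
    """

    phonemes: List[list]
    labels: List[Tuple[int, ...]]
    merge_trace: List[Tuple[Tuple[int, ...], Tuple[int, ...], float]] = field(
        default_factory=list
    )

    def __len__(self) -> int:
        return len(self.phonemes)

    def centroids(self) -> List[PadPoint]:
        """Per-phoneme centroid of exemplar pad points."""
        out = []
        for group in self.phonemes:
            xs = [p.x for p, _ in group]
            ys = [p.y for p, _ in group]
            out.append(PadPoint(float(np.mean(xs)), float(np.mean(ys))))
        return out


def pillai_score(
    group_a: Sequence, group_b: Sequence
) -> Optional[float]:
    """Pillai-Bartlett trace of a two-group one-way MANOVA on 2-D points.

    Computed as trace(H (H + E)^-1) with H the between-group and E the
    within-group SSCP matrices; for two groups the value lies in [0, 1],
    with 0 meaning indistinguishable means and 1 perfect separation. A
    singular total SSCP is ridge-regularized; if still degenerate, returns
    None.
    """
    a = np.asarray([(p.x, p.y) if isinstance(p, PadPoint) else tuple(p) for p in group_a])
    b = np.asarray([(p.x, p.y) if isinstance(p, PadPoint) else tuple(p) for p in group_b])
    if len(a) < MIN_GROUP_SIZE or len(b) < MIN_GROUP_SIZE:
        raise ValueError(
            f"each group needs >= {MIN_GROUP_SIZE} points: got {len(a)}, {len(b)}"
        )
    pooled = np.vstack([a, b])
    grand = pooled.mean(axis=0)
    if np.allclose(pooled, grand):  # zero variance in every direction
        return None
    h = np.zeros((2, 2))
    e = np.zeros((2, 2))
    for g in (a, b):
        gm = g.mean(axis=0)
        d = (gm - grand)[:, None]
        h += len(g) * (d @ d.T)
        r = g - gm
        e += r.T @ r
    total = h + e
    try:
        inv = np.linalg.inv(total)
    except np.linalg.LinAlgError:
        try:
            inv = np.linalg.inv(total + RIDGE * np.eye(2))
        except np.linalg.LinAlgError:
            return None
    score = float(np.trace(h @ inv))
    if not np.isfinite(score):
        return None
    return min(max(score, 0.0), 1.0)


def identify_phonemes(
    log: GameLog, merge_threshold: float = DEFAULT_MERGE_THRESHOLD
) -> Inventory:
    """Pool a dyad's colors per referent and merge indistinguishable groups.

    Groups are seeded one per referent (both players' color tokens for that
    referent pooled). Iteratively, the pair of groups with the lowest Pillai
    score is merged while that score is below ``merge_threshold``. Groups
    too small to score are merged into their nearest group by centroid
    distance at the end. Ties break on the lexicographically lowest pair of
    referent-id labels, making the trace deterministic.
    """
    if len(log) == 0:
        raise ValueError("cannot identify phonemes in an empty log")
    groups: Dict[Tuple[int, ...], list] = {}
    for trial in log:
        key = (trial.referent_id,)
        groups.setdefault(key, []).extend(trial.signal.colors)
    trace: List[Tuple[Tuple[int, ...], Tuple[int, ...], float]] = []

    def points(key: Tuple[int, ...]) -> List[PadPoint]:
        return [p for p, _ in groups[key]]

    while len(groups) > 1:
        keys = sorted(groups)
        best: Optional[Tuple[float, Tuple[int, ...], Tuple[int, ...]]] = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                ka, kb = keys[i], keys[j]
                if len(groups[ka]) < MIN_GROUP_SIZE or len(groups[kb]) < MIN_GROUP_SIZE:
                    continue
                score = pillai_score(points(ka), points(kb))
                if score is None:
                    continue
                if best is None or score < best[0]:
                    best = (score, ka, kb)
        if best is None or best[0] >= merge_threshold:
            break
        score, ka, kb = best
        merged_key = tuple(sorted(ka + kb))
        merged = groups.pop(ka) + groups.pop(kb)
        groups[merged_key] = merged
        trace.append((ka, kb, score))

    # attach unscoreable (tiny) groups to the nearest centroid; recompute
    # each round since a merge target may itself have been small
    while len(groups) > 1:
        small = sorted(k for k in groups if len(groups[k]) < MIN_GROUP_SIZE)
        if not small:
            break
        k = small[0]
        pts = np.asarray([(p.x, p.y) for p, _ in groups[k]])
        c = pts.mean(axis=0)
        candidates = sorted(kk for kk in groups if kk != k)
        dists = []
        for kk in candidates:
            other = np.asarray([(p.x, p.y) for p, _ in groups[kk]])
            dists.append(float(np.hypot(*(other.mean(axis=0) - c))))
        target = candidates[int(np.argmin(dists))]
        merged_key = tuple(sorted(k + target))
        merged = groups.pop(k) + groups.pop(target)
        groups[merged_key] = merged
        trace.append((k, target, float("nan")))

    keys = sorted(groups)
    return Inventory(
        phonemes=[groups[k] for k in keys],
        labels=list(keys),
        merge_trace=trace,
    )
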
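"""Monte Carlo chance-level baselines for the dispersion measures.

Observed dispersion is compared against inventories of points drawn
uniformly on the unit-square pad (the maximum-entropy "by chance" law; the
sampling distribution is a modeling choice and is documented as such). For
each random inventory the dispersion statistic is computed, and the mean
over (by default) 100,000 inventories is the chance level.

Closed-form checks: for two independent uniform points on the unit square
the expected distance is (2 + sqrt(2) + 5 asinh(1)) / 15 = 0.521405...,
and the expected distance of one uniform point from the center is
(sqrt(2) + ln(1 + sqrt(2))) / 6 = 0.382598...
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

import numpy as np

from .game_model import Condition, PadPoint, xy_to_rgb

__all__ = [
    "NullDistribution",
    "generate_null",
    "empirical_p",
    "EXPECTED_PAIRWISE_UNIFORM",
    "EXPECTED_CENTER_DIST_UNIFORM",
    "MEASURES",
]

#: E[distance between two uniform points on the unit square]
EXPECTED_PAIRWISE_UNIFORM = (2.0 + math.sqrt(2.0) + 5.0 * math.asinh(1.0)) / 15.0
#: E[distance of a uniform point from the square's center]
EXPECTED_CENTER_DIST_UNIFORM = (math.sqrt(2.0) + math.log(1.0 + math.sqrt(2.0))) / 6.0

MEASURES = ("pairwise", "center_distance", "mode_brightness")


@dataclass
class NullDistribution:
    """Samples of a dispersion statistic over random uniform inventories."""

    measure: str
    n_inventories: int
    inventory_size: int
    samples: np.ndarray
    seed: int
    condition: str = Condition.OUTER_EDGE.value

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != self.n_inventories:
            raise ValueError("sample count must equal n_inventories")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def mc_se(self) -> float:
        """Monte Carlo standard error of the null mean."""
        return float(self.samples.std(ddof=1) / math.sqrt(len(self.samples)))


def _pairwise_means(pts: np.ndarray) -> np.ndarray:
    """Mean pairwise distance per inventory for an (n, k, 2) point array."""
    diffs = pts[:, :, None, :] - pts[:, None, :, :]
    d = np.sqrt((diffs**2).sum(-1))
    k = pts.shape[1]
    iu = np.triu_indices(k, k=1)
    return d[:, iu[0], iu[1]].mean(axis=1)


def generate_null(
    measure: str,
    inventory_size: int,
    n_inventories: int = 100_000,
    condition: "str | Condition" = Condition.OUTER_EDGE,
    seed: int = 0,
) -> NullDistribution:
    """Chance-level distribution of a dispersion measure.

    Each inventory is ``inventory_size`` points drawn uniformly on the unit
    square; the statistic is computed per inventory. For ``mode_brightness``
    the points are mapped through the pad-to-color law of ``condition`` and
    each point is treated as a one-exemplar phoneme.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if n_inventories < 1:
        raise ValueError("n_inventories must be >= 1")
    if inventory_size < 1 or (measure == "pairwise" and inventory_size < 2):
        raise ValueError(
            f"inventory_size {inventory_size} too small for measure {measure!r}"
        )
    condition = Condition.parse(condition)
    rng = np.random.default_rng(seed)
    pts = rng.random((n_inventories, inventory_size, 2))
    if measure == "pairwise":
        samples = _pairwise_means(pts)
    elif measure == "center_distance":
        samples = np.hypot(pts[..., 0] - 0.5, pts[..., 1] - 0.5).mean(axis=1)
    else:  # mode_brightness: the brightest channel equals the HSV value,
        # which depends on radius only, so the law vectorizes over radii
        from .game_model import DEFAULT_COLOR_MAP

        radii = np.hypot(pts[..., 0] - 0.5, pts[..., 1] - 0.5)
        bright = DEFAULT_COLOR_MAP.brightness(radii, condition)
        samples = bright.mean(axis=1)
    return NullDistribution(
        measure=measure,
        n_inventories=n_inventories,
        inventory_size=inventory_size,
        samples=samples,
        seed=seed,
        condition=condition.value,
    )


def empirical_p(observed: float, null: NullDistribution, tail: str = "upper") -> float:
    """Add-one empirical p-value of an observed statistic against the null.

    Upper tail: (1 + #{samples >= observed}) / (n + 1); lower tail mirrored.
    """
    n = len(null.samples)
    if n == 0:
        raise ValueError("null distribution has no samples")
    if tail == "upper":
        count = int((null.samples >= observed).sum())
    elif tail == "lower":
        count = int((null.samples <= observed).sum())
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return (1 + count) / (n + 1)
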
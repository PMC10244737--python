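"""Core domain types for the dyadic color-signaling game.

Two players alternate as sender and receiver, communicating referents
(indexed 0-11) by touching a normalized unit-square pad. The pad position
maps deterministically to a color; the mapping differs between the two
experimental conditions:

* ``outer_edge`` — colors get brighter and more distinct the further the
  finger is from the pad center, so the most perceptually useful colors sit
  at the (motorically easy) edges and corners.
* ``inner_edge`` — brightness rises with radial distance up to an interior
  ridge and then falls off again toward the edge, so the best colors lie on
  a ring that is harder to hit reliably.

The exact color law of the original apparatus is not published; the mapping
here is a documented polar reconstruction (hue follows the angle about the
pad center, brightness follows radius) that preserves the qualitative
contrast between conditions. It is isolated behind :func:`xy_to_rgb` and
:class:`ColorMap` so an alternative law can be swapped in.
"""

from __future__ import annotations

import colorsys
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Optional, Sequence

__all__ = [
    "PadPoint",
    "ColorRGB",
    "Condition",
    "Signal",
    "Trial",
    "GameLog",
    "ColorMap",
    "MAX_RADIUS",
    "CENTER",
    "xy_to_rgb",
    "distance_from_center",
    "first_color",
    "ValidationError",
]

#: distance from pad center (0.5, 0.5) to any corner
MAX_RADIUS: float = math.sqrt(0.5)
CENTER = (0.5, 0.5)

N_REFERENTS = 12


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


class Condition(str, Enum):
    """Pad-to-color mapping regime."""

    OUTER_EDGE = "outer_edge"
    INNER_EDGE = "inner_edge"

    @classmethod
    def parse(cls, label: "str | Condition") -> "Condition":
        if isinstance(label, Condition):
            return label
        try:
            return cls(label)
        except ValueError:
            raise ValidationError(
                f"unknown condition {label!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


@dataclass(frozen=True)
class PadPoint:
    """A position on the unit-square signal pad.

    Origin is the bottom-left corner; the pad center is (0.5, 0.5).
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValidationError(
                f"pad coordinates must lie in [0,1]: got ({self.x}, {self.y})"
            )

    def distance_to(self, other: "PadPoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class ColorRGB:
    """A color in normalized RGB space; channels in [0, 1]."""

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"channel {name}={v} outside [0,1]")

    @property
    def brightness(self) -> float:
        """The brightest channel (HSV value)."""
        return max(self.r, self.g, self.b)

    def distance_to(self, other: "ColorRGB") -> float:
        return math.sqrt(
            (self.r - other.r) ** 2
            + (self.g - other.g) ** 2
            + (self.b - other.b) ** 2
        )


def distance_from_center(point: PadPoint) -> float:
    """Euclidean distance from the pad center (0.5, 0.5), in pad units."""
    return math.hypot(point.x - 0.5, point.y - 0.5)


@dataclass(frozen=True)
class ColorMap:
    """Polar pad-to-color law.

    Hue varies with the angle about the pad center; brightness (HSV value)
    is a function of radial distance r in [0, MAX_RADIUS]:

    * outer_edge: linear ramp from ``b_min`` at the center to ``b_max`` at
      the corners.
    * inner_edge: triangular profile rising from ``b_min`` at the center to
      ``b_max`` at the ridge radius ``ridge_frac * MAX_RADIUS`` and falling
      back to ``b_min`` at the corners.

    Saturation is fixed at 1 so the brightest channel equals the HSV value.
    """

    b_min: float = 0.15
    b_max: float = 1.0
    # fraction of MAX_RADIUS; kept below 0.5/MAX_RADIUS ~ 0.707 so the ridge
    # ring lies inside the pad along every ray, not only toward the corners
    ridge_frac: float = 0.6

    def brightness(self, radius, condition: Condition):
        """Brightness as a function of radial distance from center.

        Accepts a scalar or a numpy array of radii.
        """
        import numpy as np

        t = np.clip(np.asarray(radius, dtype=float) / MAX_RADIUS, 0.0, 1.0)
        if condition is Condition.OUTER_EDGE:
            frac = t
        else:
            # triangular ridge profile
            rising = t / self.ridge_frac if self.ridge_frac > 0 else np.ones_like(t)
            falling = (1.0 - t) / (1.0 - self.ridge_frac)
            frac = np.where(t <= self.ridge_frac, rising, falling)
        out = self.b_min + (self.b_max - self.b_min) * frac
        return float(out) if out.ndim == 0 else out

    def __call__(self, point: PadPoint, condition: Condition) -> ColorRGB:
        condition = Condition.parse(condition)
        dx, dy = point.x - 0.5, point.y - 0.5
        radius = math.hypot(dx, dy)
        # hue from the angle; arbitrary but fixed at radius 0
        hue = (math.atan2(dy, dx) / (2.0 * math.pi)) % 1.0 if radius > 0 else 0.0
        value = self.brightness(radius, condition)
        r, g, b = colorsys.hsv_to_rgb(hue, 1.0, value)
        return ColorRGB(r, g, b)


DEFAULT_COLOR_MAP = ColorMap()


def xy_to_rgb(
    point: PadPoint,
    condition: "str | Condition",
    color_map: ColorMap = DEFAULT_COLOR_MAP,
) -> ColorRGB:
    """Map a pad position to the on-screen color for a condition.

    Deterministic; under ``outer_edge`` the brightest RGB channel is
    non-decreasing in radial distance from the pad center, while under
    ``inner_edge`` it peaks at an interior ridge and then falls.
    """
    return color_map(point, Condition.parse(condition))


@dataclass(frozen=True)
class Signal:
    """An ordered, non-empty series of colors sent in one turn."""

    colors: tuple  # of (PadPoint, ColorRGB)

    def __post_init__(self) -> None:
        if len(self.colors) == 0:
            raise ValidationError("a signal must contain at least one color")

    def __len__(self) -> int:
        return len(self.colors)


def first_color(signal: Signal) -> "tuple[PadPoint, ColorRGB]":
    """The first color token of a signal.

    Signals overwhelmingly consist of one color repeated, so the analyses
    operate on the first token of each turn only.
    """
    return signal.colors[0]


@dataclass(frozen=True)
class Trial:
    """One turn of the game: a sender, a referent, a signal, and an outcome."""

    turn: int
    sender_id: int
    referent_id: int
    signal: Signal
    guess_id: Optional[int]
    correct: bool

    def __post_init__(self) -> None:
        if self.turn < 1:
            raise ValidationError(f"turn must be a positive integer: {self.turn}")
        if self.sender_id not in (0, 1):
            raise ValidationError(f"sender_id must be 0 or 1: {self.sender_id}")
        if not (0 <= self.referent_id < N_REFERENTS):
            raise ValidationError(f"referent_id out of range: {self.referent_id}")
        if self.guess_id is not None and not (0 <= self.guess_id < N_REFERENTS):
            raise ValidationError(f"guess_id out of range: {self.guess_id}")
        if self.correct != (self.guess_id == self.referent_id):
            raise ValidationError(
                f"correct flag {self.correct} contradicts guess {self.guess_id} "
                f"vs referent {self.referent_id}"
            )

    @property
    def first_point(self) -> PadPoint:
        return first_color(self.signal)[0]


@dataclass
class GameLog:
    """The ordered trials of one dyad under one condition."""

    pair_id: str
    condition: Condition
    trials: list = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.condition = Condition.parse(self.condition)
        self.validate()

    def validate(self) -> None:
        """Check turn ordering and sender alternation across trials."""
        prev_turn = 0
        prev_sender = None
        for t in self.trials:
            if t.turn <= prev_turn:
                raise ValidationError(
                    f"turn numbers must strictly increase: {t.turn} after {prev_turn}"
                )
            if prev_sender is not None and t.sender_id == prev_sender:
                raise ValidationError(
                    f"sender must alternate between consecutive turns "
                    f"(turn {t.turn} repeats sender {t.sender_id})"
                )
            prev_turn, prev_sender = t.turn, t.sender_id

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    @property
    def n_rounds(self) -> int:
        return len(self.trials)
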
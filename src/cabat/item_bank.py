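"""Automatic item generation for the beat-alignment test.

An item is defined by four structural features: the musical track, the
lure's beep-track accuracy (a transform of its temporal offset from the
beat), the displacement direction (ahead of or behind the beat) and the
stimulus order (target first or lure first).  Accuracy and direction are
*radicals* — they drive item difficulty through the explanatory model —
while stimulus order is an *incidental*.  Difficulty is predicted from the
features by a linear model whose published coefficients ship as defaults,
so banks of arbitrary size can be generated without per-item calibration.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Direction",
    "Order",
    "ItemSpec",
    "DifficultyCoefficients",
    "ItemBank",
    "PUBLISHED_COEFFICIENTS",
    "TRACK_RANDOM_EFFECTS",
    "accuracy_from_offset",
    "offset_from_accuracy",
    "accuracy_grid",
    "predict_difficulty",
    "glmm_to_irt_coefficients",
    "build_bank",
]

Direction = Literal["ahead", "behind"]
Order = Literal["target_first", "lure_first"]

DIRECTIONS: tuple[Direction, ...] = ("ahead", "behind")
ORDERS: tuple[Order, ...] = ("target_first", "lure_first")


def accuracy_from_offset(offset):
    """Beep-track accuracy ``cos^4(pi * P)`` of a lure offset ``P``.

    ``P`` is the displacement of the lure's beeps from the beat, as a
    fraction of one beat period, restricted to (0, 0.5] — beyond half a
    beat displacement wraps around to the neighbouring beat.  The quartic
    cosine transform linearises the relation between displacement and item
    difficulty.
    """
    offset = np.asarray(offset, dtype=float)
    if np.any(offset <= 0.0) or np.any(offset > 0.5):
        raise ValueError("offset must lie in (0, 0.5] beats")
    return np.cos(np.pi * offset) ** 4


def offset_from_accuracy(accuracy):
    """Inverse of :func:`accuracy_from_offset`: ``arccos(d^(1/4)) / pi``."""
    accuracy = np.asarray(accuracy, dtype=float)
    if np.any(accuracy < 0.0) or np.any(accuracy >= 1.0):
        raise ValueError("accuracy must lie in [0, 1)")
    return np.arccos(accuracy**0.25) / np.pi


def accuracy_grid(n_levels: int, low: float = 0.5, high_exclusive: float = 1.0) -> np.ndarray:
    """Equally spaced accuracy levels on [low, high_exclusive).

    Starts at ``low`` with step ``(high_exclusive - low) / n_levels`` so the
    endpoint is excluded (an accuracy of exactly 1 would be a zero-offset
    lure, i.e. a second target).
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if not low < high_exclusive:
        raise ValueError("require low < high_exclusive")
    step = (high_exclusive - low) / n_levels
    return low + step * np.arange(n_levels)


@dataclass(frozen=True)
class DifficultyCoefficients:
    """Linear difficulty model: intercept + accuracy and direction effects.

    ``difficulty = intercept + accuracy_effect * accuracy
    + direction_effect * [direction == "behind"]``.  Defaults are the
    published calibration estimates (intercept −5.393, accuracy 7.247,
    behind-the-beat −0.576) together with the shared discrimination 1.166.
    ``metadata`` carries the calibration's track-level random-effect
    summaries; they are documentation only and never enter prediction.
    """

    intercept: float = -5.393
    accuracy_effect: float = 7.247
    direction_effect: float = -0.576
    discrimination: float = 1.166
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.discrimination > 0:
            raise ValueError("discrimination must be > 0")


#: Track-level random-effect summaries from the calibration fit, stored as
#: provenance only: the near-perfect negative intercept/slope correlation
#: made them unstable, and they are deliberately excluded from difficulty
#: prediction.
TRACK_RANDOM_EFFECTS = {
    "track_intercept_sd": 2.121,
    "track_accuracy_slope_sd": 1.477,
    "track_intercept_slope_correlation": -1.000,
}

PUBLISHED_COEFFICIENTS = DifficultyCoefficients(metadata=dict(TRACK_RANDOM_EFFECTS))


def predict_difficulty(
    accuracy, direction, coefficients: DifficultyCoefficients = PUBLISHED_COEFFICIENTS
):
    """Predicted item difficulty from its radicals.

    Direction is dummy-coded behind=1, ahead=0.  Track and stimulus order do
    not enter the prediction.
    """
    accuracy = np.asarray(accuracy, dtype=float)
    if np.any(accuracy < 0.0) or np.any(accuracy >= 1.0):
        raise ValueError("accuracy must lie in [0, 1)")
    behind = np.asarray(
        [d == "behind" for d in np.atleast_1d(direction)]
        if not np.isscalar(direction)
        else direction == "behind",
        dtype=float,
    )
    out = coefficients.intercept + coefficients.accuracy_effect * accuracy
    out = out + coefficients.direction_effect * behind
    return float(out) if out.ndim == 0 else out


def glmm_to_irt_coefficients(
    raw_effects: Sequence[float], person_sd: float, metadata: dict | None = None
) -> DifficultyCoefficients:
    """Convert raw mixed-model fixed effects to the IRT difficulty scale.

    In the mixed-model parameterisation the person random intercept has SD
    equal to the IRT discrimination ``a``, and each fixed effect ``B`` maps
    to a difficulty coefficient ``-B / a``.  ``raw_effects`` is
    (intercept, accuracy effect, direction effect); a missing direction
    effect defaults to 0.
    """
    if not person_sd > 0:
        raise ValueError("person_sd must be > 0")
    eff = [(-b / person_sd) for b in raw_effects]
    if len(eff) == 2:
        eff.append(0.0)
    if len(eff) != 3:
        raise ValueError("expected 2 or 3 raw effects (intercept, accuracy[, direction])")
    return DifficultyCoefficients(
        intercept=eff[0],
        accuracy_effect=eff[1],
        direction_effect=eff[2],
        discrimination=person_sd,
        metadata=metadata or {},
    )


@dataclass(frozen=True)
class ItemSpec:
    """One generated 2-AFC item."""

    item_id: str
    track_id: str
    offset: float
    accuracy: float
    direction: Direction
    order: Order
    difficulty: float

    def __post_init__(self) -> None:
        if not (0.0 < self.offset <= 0.5):
            raise ValueError(f"offset must lie in (0, 0.5], got {self.offset}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.order not in ORDERS:
            raise ValueError(f"unknown order {self.order!r}")
        expected = float(np.cos(np.pi * self.offset) ** 4)
        if abs(expected - self.accuracy) > 1e-9:
            raise ValueError(
                f"accuracy {self.accuracy} inconsistent with offset {self.offset} "
                f"(expected {expected})"
            )


def make_item_id(track_id: str, accuracy: float, direction: str, order: str) -> str:
    """Deterministic item identifier from the item's features."""
    key = f"{track_id}|{accuracy:.9f}|{direction}|{order}"
    digest = hashlib.sha1(key.encode()).hexdigest()[:8]
    return f"{track_id}-{direction[0]}{order[0]}-{digest}"


@dataclass(frozen=True)
class ItemBank:
    """A collection of items plus the coefficients that generated them."""

    items: tuple[ItemSpec, ...]
    coefficients: DifficultyCoefficients
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_ids in bank")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def difficulties(self) -> np.ndarray:
        return np.asarray([it.difficulty for it in self.items])

    @property
    def track_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.track_id, None)
        return tuple(seen)


def _make_item(track, accuracy, direction, order, coefficients) -> ItemSpec:
    accuracy = float(accuracy)
    return ItemSpec(
        item_id=make_item_id(track, accuracy, direction, order),
        track_id=str(track),
        offset=float(offset_from_accuracy(accuracy)),
        accuracy=accuracy,
        direction=direction,
        order=order,
        difficulty=float(predict_difficulty(accuracy, direction, coefficients)),
    )


def _random_halves(n: int, rng: np.random.Generator, options: tuple) -> list:
    """Assign options to items in (near-)equal randomly chosen halves."""
    half = n // 2
    labels = [options[0]] * half + [options[1]] * (n - half)
    return list(rng.permutation(np.asarray(labels, dtype=object)))


def build_bank(
    tracks: Sequence[str],
    accuracies: Sequence[float],
    directions: Sequence[str] = DIRECTIONS,
    orders: Sequence[str] = ORDERS,
    coefficients: DifficultyCoefficients = PUBLISHED_COEFFICIENTS,
    mode: str = "factorial",
    seed: int | None = 0,
) -> ItemBank:
    """Generate an item bank.

    factorial
        The full cross of tracks × accuracies × directions × orders, e.g.
        27 × 27 × 2 × 2 = 2,916 items for the calibration design, or
        25 × 100 × 2 × 2 = 10,000 items for the adaptive test bank.
    paired
        One item per track via a seeded one-to-one random pairing of tracks
        with accuracy levels, with direction and order each assigned to
        seeded random halves (the exploratory-study design: 16 of 32 items
        ahead, 16 behind, and likewise for order).
    """
    tracks = [str(t) for t in tracks]
    if len(set(tracks)) != len(tracks):
        raise ValueError("duplicate track ids")
    if not tracks or len(accuracies) == 0:
        raise ValueError("tracks and accuracies must be nonempty")
    rng = np.random.default_rng(seed)
    items: list[ItemSpec] = []
    if mode == "factorial":
        if not directions or not orders:
            raise ValueError("directions and orders must be nonempty")
        for track in tracks:
            for acc in accuracies:
                for direction in directions:
                    for order in orders:
                        items.append(_make_item(track, acc, direction, order, coefficients))
    elif mode == "paired":
        if len(tracks) != len(accuracies):
            raise ValueError("paired mode requires equal numbers of tracks and accuracies")
        paired_acc = rng.permutation(np.asarray(accuracies, dtype=float))
        dir_assign = _random_halves(len(tracks), rng, DIRECTIONS)
        order_assign = _random_halves(len(tracks), rng, ORDERS)
        for track, acc, direction, order in zip(tracks, paired_acc, dir_assign, order_assign):
            items.append(_make_item(track, acc, direction, order, coefficients))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    provenance = {
        "mode": mode,
        "seed": seed,
        "n_tracks": len(tracks),
        "n_accuracies": len(accuracies),
        "directions": list(directions),
        "orders": list(orders),
    }
    return ItemBank(items=tuple(items), coefficients=coefficients, provenance=provenance)
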
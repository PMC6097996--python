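"""Seeded synthetic-data generators.

Everything the other modules consume can be generated here with the
model's assumed structure: tap takes (true beats plus per-drummer motor
offset and Gaussian tap jitter) and binary response matrices (abilities
drawn from the standard normal, responses Bernoulli under the constrained
2-AFC response model).  Generators return the generating truth alongside
the data so parameter-recovery tests have an oracle, and are bit-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ResponseMatrix
from .item_bank import (
    DifficultyCoefficients,
    ItemBank,
    PUBLISHED_COEFFICIENTS,
    accuracy_grid,
    build_bank,
)
from .model_core import prob_correct_cabat
from .stimulus import TapTake

__all__ = [
    "TapFixtureSpec",
    "MatrixFixtureSpec",
    "make_tap_takes",
    "make_response_matrix",
    "make_balanced_assignment_matrix",
]


@dataclass(frozen=True)
class TapFixtureSpec:
    """Settings for synthetic drummer tap takes.

    ``drummer_offsets`` gives each drummer a constant motor offset in
    seconds; ``jitter_sd`` is the per-tap Gaussian jitter SD in seconds.
    ``tempo_drift`` optionally scales the period linearly over the excerpt.
    """

    n_beats: int = 12
    period: float = 0.5
    jitter_sd: float = 0.0
    drummer_offsets: dict = field(default_factory=lambda: {"d1": 0.0})
    takes_per_drummer: int = 3
    tempo_drift: float = 0.0
    start: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_beats < 3 or self.period <= 0:
            raise ValueError("need >= 3 beats and a positive period")


def make_tap_takes(spec: TapFixtureSpec) -> tuple[list[TapTake], np.ndarray]:
    """Generate tap takes; returns (takes, true beat times)."""
    rng = np.random.default_rng(spec.seed)
    periods = spec.period * (1.0 + spec.tempo_drift * np.linspace(0, 1, spec.n_beats - 1))
    beats = spec.start + np.concatenate([[0.0], np.cumsum(periods)])
    takes: list[TapTake] = []
    for drummer, offset in spec.drummer_offsets.items():
        for t in range(spec.takes_per_drummer):
            onsets = beats + offset + rng.normal(0.0, spec.jitter_sd, size=beats.size)
            takes.append(
                TapTake(
                    drummer_id=str(drummer),
                    take_id=f"{drummer}-take{t + 1}",
                    onsets=tuple(np.sort(onsets)),
                )
            )
    return takes, beats


@dataclass(frozen=True)
class MatrixFixtureSpec:
    """Settings for a synthetic response matrix."""

    n_persons: int = 200
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    fixed_abilities: tuple[float, ...] | None = None
    seed: int = 0


def _features_frame(items) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accuracy": [it.accuracy for it in items],
            "direction": [it.direction for it in items],
            "track_id": [it.track_id for it in items],
            "difficulty": [it.difficulty for it in items],
        },
        index=[it.item_id for it in items],
    )


def make_response_matrix(
    spec: MatrixFixtureSpec, items
) -> tuple[ResponseMatrix, dict]:
    """Complete response matrix under the response model.

    ``items`` is an :class:`ItemBank` or a sequence of item specs; every
    person answers every item.  Returns the matrix plus the generating
    truth (abilities, difficulties, discrimination).
    """
    item_list = list(items.items) if isinstance(items, ItemBank) else list(items)
    coeffs = items.coefficients if isinstance(items, ItemBank) else PUBLISHED_COEFFICIENTS
    rng = np.random.default_rng(spec.seed)
    if spec.fixed_abilities is not None:
        theta = np.asarray(spec.fixed_abilities, dtype=float)
    else:
        theta = spec.ability_mean + spec.ability_sd * rng.standard_normal(spec.n_persons)
    difficulties = np.asarray([it.difficulty for it in item_list])
    p = prob_correct_cabat(theta[:, None], difficulties[None, :], coeffs.discrimination)
    scores = (rng.random((theta.size, len(item_list))) < p).astype(float)
    matrix = ResponseMatrix(
        persons=[f"p{i:04d}" for i in range(theta.size)],
        items=[it.item_id for it in item_list],
        scores=scores,
        item_features=_features_frame(item_list),
    )
    truth = {
        "abilities": theta,
        "difficulties": difficulties,
        "discrimination": coeffs.discrimination,
        "coefficients": coeffs,
    }
    return matrix, truth


def make_balanced_assignment_matrix(
    spec: MatrixFixtureSpec,
    tracks: list[str] | None = None,
    n_levels: int = 27,
    coefficients: DifficultyCoefficients = PUBLISHED_COEFFICIENTS,
) -> tuple[ResponseMatrix, dict]:
    """Adaptively-missing matrix under the balanced calibration design.

    Each participant answers one item per musical track and one item per
    accuracy level — a seeded random track-to-level bijection per person —
    with direction and order drawn at random.  The full factorial bank is
    generated and unanswered cells are missing.  Requires equally many
    tracks and accuracy levels.
    """
    tracks = tracks or [f"t{i:02d}" for i in range(n_levels)]
    if len(tracks) != n_levels:
        raise ValueError(
            f"balanced assignment needs equal counts, got {len(tracks)} tracks "
            f"and {n_levels} accuracy levels"
        )
    bank = build_bank(
        tracks, accuracy_grid(n_levels, 0.5, 1.0), coefficients=coefficients,
        mode="factorial", seed=spec.seed,
    )
    index = {
        (it.track_id, round(it.accuracy, 12), it.direction, it.order): idx
        for idx, it in enumerate(bank.items)
    }
    levels = accuracy_grid(n_levels, 0.5, 1.0)
    rng = np.random.default_rng(spec.seed)
    if spec.fixed_abilities is not None:
        theta = np.asarray(spec.fixed_abilities, dtype=float)
    else:
        theta = spec.ability_mean + spec.ability_sd * rng.standard_normal(spec.n_persons)
    scores = np.full((theta.size, len(bank)), np.nan)
    difficulties = bank.difficulties
    a = coefficients.discrimination
    for p_idx in range(theta.size):
        perm = rng.permutation(n_levels)  # track i -> accuracy level perm[i]
        for t_idx, track in enumerate(tracks):
            acc = levels[perm[t_idx]]
            direction = ("ahead", "behind")[rng.integers(2)]
            order = ("target_first", "lure_first")[rng.integers(2)]
            j = index[(track, round(float(acc), 12), direction, order)]
            prob = float(prob_correct_cabat(theta[p_idx], difficulties[j], a))
            scores[p_idx, j] = float(rng.random() < prob)
    matrix = ResponseMatrix(
        persons=[f"p{i:04d}" for i in range(theta.size)],
        items=[it.item_id for it in bank.items],
        scores=scores,
        item_features=_features_frame(bank.items),
    )
    truth = {
        "abilities": theta,
        "difficulties": difficulties,
        "discrimination": a,
        "coefficients": coefficients,
        "bank": bank,
    }
    return matrix, truth
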
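"""Adaptive session loop for the beat-alignment test.

A session administers a fixed number of items (default 25).  The first item
targets average ability (difficulty near -0.01, the bank item closest to
the population mean), with stimulus order free to vary.  After each
response the ability is re-estimated by Bayes modal estimation with a
standard-normal prior, and the next item is drawn at random from the
eligible items maximally close in difficulty to the current estimate
(Urry's criterion), under the constraint that no musical track is heard
twice.  The final score is a Warm weighted-likelihood estimate over the
whole pattern, which removes the prior's shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .estimation import EstimateResult, estimate_bayes_modal, estimate_weighted_likelihood
from .item_bank import ItemBank, ItemSpec
from .model_core import ResponseModelParams, ScoredResponse

__all__ = [
    "SessionConfig",
    "SessionResult",
    "select_first_item",
    "select_next_item",
    "run_session",
    "interim_wl_curve",
]


@dataclass(frozen=True)
class SessionConfig:
    test_length: int = 25
    first_item_difficulty_target: float = -0.01
    randomesque_set_size: int = 1
    prior_mean: float = 0.0
    prior_sd: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.test_length < 1:
            raise ValueError("test_length must be >= 1")
        if self.randomesque_set_size < 1:
            raise ValueError("randomesque_set_size must be >= 1")


@dataclass
class SessionResult:
    administered: list[ItemSpec] = field(default_factory=list)
    responses: list[ScoredResponse] = field(default_factory=list)
    trajectory: list[EstimateResult] = field(default_factory=list)
    final: EstimateResult | None = None
    aborted: bool = False

    @property
    def difficulties(self) -> np.ndarray:
        return np.asarray([it.difficulty for it in self.administered])

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([r.correct for r in self.responses])


def _params_from_bank(bank: ItemBank) -> ResponseModelParams:
    return ResponseModelParams(discrimination=bank.coefficients.discrimination)


def _nearest_candidates(
    difficulties: np.ndarray, eligible: np.ndarray, target: float, set_size: int
) -> np.ndarray:
    """Indices of the eligible items closest in difficulty to ``target``.

    The candidate set is every exact tie at the minimal distance, expanded
    by next-nearest distance ranks until it holds at least ``set_size``
    items (a randomesque exposure control; set_size 1 keeps exact minima
    only).
    """
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        raise LookupError("no eligible items remain in the bank")
    dist = np.abs(difficulties[idx] - target)
    if set_size <= 1:
        return idx[np.isclose(dist, dist.min(), rtol=0.0, atol=1e-12)]
    order = np.argsort(dist, kind="stable")
    ranked = dist[order]
    cut = ranked[min(set_size, idx.size) - 1]
    return idx[dist <= cut + 1e-12]


def select_first_item(
    bank: ItemBank, config: SessionConfig, rng: np.random.Generator
) -> ItemSpec:
    """The fixed-difficulty opening item; only stimulus order varies."""
    if len(bank) == 0:
        raise LookupError("empty item bank")
    difficulties = bank.difficulties
    eligible = np.ones(len(bank), dtype=bool)
    cands = _nearest_candidates(
        difficulties, eligible, config.first_item_difficulty_target, 1
    )
    return bank.items[int(rng.choice(cands))]


def select_next_item(
    bank: ItemBank,
    theta_hat: float,
    used_tracks: set[str],
    config: SessionConfig,
    rng: np.random.Generator,
) -> ItemSpec:
    """Urry selection: nearest-difficulty eligible item, seeded tie-break."""
    eligible = np.asarray([it.track_id not in used_tracks for it in bank.items])
    cands = _nearest_candidates(
        bank.difficulties, eligible, float(theta_hat), config.randomesque_set_size
    )
    return bank.items[int(rng.choice(cands))]


def run_session(
    bank: ItemBank,
    responder: Callable[[ItemSpec], int],
    config: SessionConfig = SessionConfig(),
) -> SessionResult:
    """Administer one full adaptive session against ``bank``.

    ``responder`` maps an item to a scored response (1 correct, 0
    incorrect); a deterministic or seeded responder makes the whole session
    reproducible from (bank, config.seed, responder).  If the responder
    raises, the partial log is preserved on the raised ``SessionAborted``.
    """
    if config.test_length > len(bank.track_ids):
        raise ValueError(
            f"test_length {config.test_length} exceeds the {len(bank.track_ids)} "
            "distinct tracks in the bank (tracks may not repeat)"
        )
    rng = np.random.default_rng(config.seed)
    params = _params_from_bank(bank)
    result = SessionResult()
    used_tracks: set[str] = set()
    theta_hat = config.prior_mean
    for step in range(config.test_length):
        if step == 0:
            item = select_first_item(bank, config, rng)
        else:
            item = select_next_item(bank, theta_hat, used_tracks, config, rng)
        try:
            correct = int(responder(item))
        except Exception as exc:
            result.aborted = True
            raise SessionAborted(result) from exc
        result.administered.append(item)
        result.responses.append(ScoredResponse(item.item_id, correct))
        used_tracks.add(item.track_id)
        interim = estimate_bayes_modal(
            result.responses,
            result.difficulties,
            params,
            prior_mean=config.prior_mean,
            prior_sd=config.prior_sd,
        )
        result.trajectory.append(interim)
        theta_hat = interim.theta_hat
    result.final = estimate_weighted_likelihood(result.responses, result.difficulties, params)
    return result


class SessionAborted(RuntimeError):
    """Responder failure mid-session; carries the partial log."""

    def __init__(self, partial: SessionResult):
        super().__init__("responder failed; partial session log preserved")
        self.partial = partial


def interim_wl_curve(
    result: SessionResult,
    params: ResponseModelParams,
    lengths: Sequence[int] | None = None,
) -> dict[int, EstimateResult]:
    """Weighted-likelihood estimate and SE recomputed after the first k items.

    This is how shorter test lengths are scored post hoc: the WL estimator
    is re-run on the truncated response pattern for each requested k.
    """
    n = len(result.responses)
    if lengths is None:
        lengths = range(1, n + 1)
    diffs = result.difficulties
    out: dict[int, EstimateResult] = {}
    for k in lengths:
        if not 1 <= k <= n:
            raise ValueError(f"length {k} outside 1..{n}")
        out[k] = estimate_weighted_likelihood(result.responses[:k], diffs[:k], params)
    return out
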
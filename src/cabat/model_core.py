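"""Item response functions for the beat-alignment test.

The test is a two-alternative forced choice (2-AFC): each trial pairs an
on-beat *target* with a displaced *lure*, so a random responder scores 50%.
The response model is a four-parameter logistic (4PL) item characteristic
curve with the guessing floor fixed at 0.5, the inattention ceiling fixed at
1, and a single discrimination parameter shared by all items::

    P(correct | theta) = 0.5 + 0.5 * logistic(a * (theta - b))

where ``theta`` is the test-taker's latent ability (population-standardised,
mean 0, SD 1) and ``b`` the item difficulty on the same scale.

This module holds the probability functions, the Fisher information used for
standard errors, and the response-pattern log-likelihood that every
estimator and fitter in the package consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ResponseModelParams",
    "ScoredResponse",
    "prob_correct_4pl",
    "prob_correct_cabat",
    "item_information",
    "test_information",
    "loglik_pattern",
    "score_pattern",
    "information_derivative_term",
]


@dataclass(frozen=True)
class ResponseModelParams:
    """Shared item parameters of the constrained response model.

    discrimination
        Slope ``a`` of the item characteristic curve, shared across items.
        The published value from the calibration study is 1.166.
    guessing
        Lower asymptote ``c``; 0.5 for the 2-AFC paradigm.
    inattention
        Upper asymptote ``d``; fixed at 1 (sessions are short enough that
        lapses are ignored).
    """

    discrimination: float = 1.166
    guessing: float = 0.5
    inattention: float = 1.0

    def __post_init__(self) -> None:
        if not self.discrimination > 0:
            raise ValueError(f"discrimination must be > 0, got {self.discrimination}")
        if not (0.0 <= self.guessing < self.inattention <= 1.0):
            raise ValueError(
                "require 0 <= guessing < inattention <= 1, got "
                f"guessing={self.guessing}, inattention={self.inattention}"
            )


@dataclass(frozen=True)
class ScoredResponse:
    """A scored response to a single item (1 = correct, 0 = incorrect)."""

    item_id: str
    correct: int

    def __post_init__(self) -> None:
        if self.correct not in (0, 1):
            raise ValueError(f"correct must be 0 or 1, got {self.correct}")


def _validate_4pl(a: float, c: float, d: float) -> None:
    if not a > 0:
        raise ValueError(f"discrimination a must be > 0, got {a}")
    if not (0.0 <= c < d <= 1.0):
        raise ValueError(f"require 0 <= c < d <= 1, got c={c}, d={d}")


def prob_correct_4pl(theta, a: float, b, c: float = 0.0, d: float = 1.0):
    """Four-parameter logistic probability of a correct response.

    ``c + (d - c) * logistic(a * (theta - b))``, evaluated through
    :func:`scipy.special.expit` so extreme arguments saturate instead of
    overflowing. ``theta`` and ``b`` broadcast as arrays.
    """
    _validate_4pl(a, c, d)
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(b, dtype=float)
    return c + (d - c) * expit(a * (theta - b))


def prob_correct_cabat(theta, difficulty, a: float = 1.166):
    """Probability of a correct 2-AFC beat-alignment response.

    The constrained model: guessing 0.5, inattention 1, shared slope ``a``.
    """
    return prob_correct_4pl(theta, a, difficulty, c=0.5, d=1.0)


def item_information(theta, difficulty, params: ResponseModelParams = ResponseModelParams()):
    """Expected (Fisher) information of one item at ability ``theta``.

    For the three-parameter logistic with guessing ``c`` (upper asymptote 1)
    this is ``a^2 * ((1-P)/P) * ((P-c)/(1-c))^2``.  At ``theta == difficulty``
    with ``c = 0.5`` it equals ``a^2 / 12``.
    """
    a, c = params.discrimination, params.guessing
    if params.inattention != 1.0:
        raise ValueError("information formula assumes inattention ceiling 1")
    p = prob_correct_4pl(theta, a, difficulty, c=c, d=1.0)
    return a**2 * ((1.0 - p) / p) * ((p - c) / (1.0 - c)) ** 2


def test_information(theta, difficulties, params: ResponseModelParams = ResponseModelParams()):
    """Total Fisher information: sum of item informations (local independence)."""
    diffs = np.atleast_1d(np.asarray(difficulties, dtype=float))
    theta = np.asarray(theta, dtype=float)
    info = item_information(theta[..., None], diffs, params)
    return info.sum(axis=-1)


def _responses_to_array(responses: Sequence) -> np.ndarray:
    out = np.asarray(
        [r.correct if isinstance(r, ScoredResponse) else int(r) for r in responses],
        dtype=float,
    )
    if not np.isin(out, (0.0, 1.0)).all():
        raise ValueError("responses must be binary")
    return out


def loglik_pattern(
    theta,
    items: Sequence[float],
    responses: Sequence,
    params: ResponseModelParams = ResponseModelParams(),
):
    """Log-likelihood of a response pattern at ability ``theta``.

    ``items`` is the list of item difficulties, aligned with ``responses``
    (ScoredResponse objects or plain 0/1 values).
    """
    diffs = np.asarray(items, dtype=float)
    x = _responses_to_array(responses)
    if diffs.shape != x.shape:
        raise ValueError(f"{diffs.size} items but {x.size} responses")
    if diffs.size == 0:
        raise ValueError("empty response pattern")
    theta = np.asarray(theta, dtype=float)
    p = prob_correct_4pl(
        theta[..., None], params.discrimination, diffs, c=params.guessing, d=params.inattention
    )
    return (x * np.log(p) + (1.0 - x) * np.log1p(-p)).sum(axis=-1)


def _p_dp_ddp(theta, diffs, params):
    """P and its first/second theta-derivatives for the constrained model."""
    a, c = params.discrimination, params.guessing
    psi = expit(a * (np.asarray(theta, float)[..., None] - diffs))
    p = c + (1.0 - c) * psi
    dp = (1.0 - c) * a * psi * (1.0 - psi)
    ddp = (1.0 - c) * a**2 * psi * (1.0 - psi) * (1.0 - 2.0 * psi)
    return p, dp, ddp


def score_pattern(theta, items, responses, params: ResponseModelParams = ResponseModelParams()):
    """First derivative of :func:`loglik_pattern` with respect to theta."""
    diffs = np.asarray(items, dtype=float)
    x = _responses_to_array(responses)
    p, dp, _ = _p_dp_ddp(theta, diffs, params)
    return (dp * (x - p) / (p * (1.0 - p))).sum(axis=-1)


def information_derivative_term(theta, items, params: ResponseModelParams = ResponseModelParams()):
    """J(theta) = sum_j P'_j P''_j / (P_j (1 - P_j)).

    The numerator of Warm's weighted-likelihood bias correction; the
    corrected score equation is ``score + J / (2 I) = 0``.
    """
    diffs = np.asarray(items, dtype=float)
    p, dp, ddp = _p_dp_ddp(theta, diffs, params)
    return (dp * ddp / (p * (1.0 - p))).sum(axis=-1)
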
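"""Model-fit and data-screening diagnostics.

The procedures used to vet the beat-alignment item response model on new
response data:

* track screening — per-track success rates, flagging tracks that score at
  or near the 2-AFC chance level (misannotated beats or misleading tracks);
* Yen's Q1 item-fit statistic with a parametric-bootstrap null and
  Bonferroni correction;
* fit on the two- and three-way margins — observed vs model-implied joint
  response-pattern frequencies for every item pair/triplet;
* modified parallel analysis — the second eigenvalue of the tetrachoric
  correlation matrix against its distribution under the fitted
  unidimensional model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .calibration import GUESSING, ResponseMatrix, fit_constrained_3pl
from .estimation import estimate_eap
from .model_core import ResponseModelParams, prob_correct_cabat

__all__ = [
    "FitReport",
    "screen_tracks",
    "yen_q1",
    "margins_check",
    "tetrachoric_correlation",
    "tetrachoric_matrix",
    "modified_parallel_analysis",
]


@dataclass
class FitReport:
    """Aggregated diagnostics for one response matrix."""

    track_screen: dict | None = None
    q1: dict | None = None
    margins2: dict | None = None
    margins3: dict | None = None
    parallel_analysis: dict | None = None
    notes: list[str] = field(default_factory=list)


def screen_tracks(
    matrix: ResponseMatrix,
    item_to_track: dict[str, str],
    chance: float = 0.5,
    margin: float = 0.05,
) -> dict:
    """Per-track success rates, flagging rates <= chance + margin.

    The default margin of 0.05 catches tracks scoring "approximately at or
    below chance" (e.g. 52% and 46% against a 50% floor).
    """
    missing = [i for i in matrix.items if i not in item_to_track]
    if missing:
        raise KeyError(f"items without a track mapping: {missing[:5]}")
    tracks: dict[str, list[int]] = {}
    for j, item in enumerate(matrix.items):
        tracks.setdefault(item_to_track[item], []).append(j)
    report = {}
    for track, cols in tracks.items():
        vals = matrix.scores[:, cols]
        vals = vals[~np.isnan(vals)]
        rate = float(vals.mean()) if vals.size else math.nan
        report[track] = {
            "success_rate": rate,
            "n_responses": int(vals.size),
            "flagged": bool(vals.size and rate <= chance + margin),
        }
    return report


def _group_indices(theta_hats: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Near-equal-size ability groups by ranked estimate (stable sort)."""
    order = np.argsort(theta_hats, kind="stable")
    return [g for g in np.array_split(order, n_groups) if g.size]


def _eap_thetas(scores: np.ndarray, difficulties: np.ndarray, params: ResponseModelParams):
    obs = ~np.isnan(scores)
    if obs.all():  # complete matrix: score everyone in one quadrature pass
        from .estimation import gauss_hermite_prior

        nodes, weights = gauss_hermite_prior(61)
        p = np.clip(
            prob_correct_cabat(nodes[:, None], difficulties[None, :], params.discrimination),
            1e-12, 1.0 - 1e-12,
        )
        ll = scores @ np.log(p).T + (1.0 - scores) @ np.log1p(-p).T
        w = np.exp(ll - ll.max(axis=1, keepdims=True)) * weights[None, :]
        w /= w.sum(axis=1, keepdims=True)
        return w @ nodes
    out = np.empty(scores.shape[0])
    for p in range(scores.shape[0]):
        cols = np.nonzero(obs[p])[0]
        out[p] = estimate_eap(scores[p, cols].astype(int), difficulties[cols], params).theta_hat
    return out


def _q1_statistics(
    scores: np.ndarray,
    difficulties: np.ndarray,
    params: ResponseModelParams,
    theta_hats: np.ndarray,
    n_groups: int,
) -> np.ndarray:
    groups = _group_indices(theta_hats, n_groups)
    n_items = scores.shape[1]
    p_hat = np.clip(
        prob_correct_cabat(theta_hats[:, None], difficulties[None, :],
                           params.discrimination),
        1e-12, 1.0 - 1e-12,
    )
    stats = np.zeros(n_items)
    for g in groups:
        sub = scores[g]
        obs = ~np.isnan(sub)
        n_gj = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            o_gj = np.nanmean(sub, axis=0)
            e_gj = np.where(
                n_gj > 0,
                np.sum(np.where(obs, p_hat[g], 0.0), axis=0) / np.maximum(n_gj, 1),
                np.nan,
            )
        ok = (n_gj > 0) & (e_gj > 0) & (e_gj < 1)
        stats[ok] += n_gj[ok] * (o_gj[ok] - e_gj[ok]) ** 2 / (e_gj[ok] * (1 - e_gj[ok]))
    return stats


def yen_q1(
    model,
    matrix: ResponseMatrix,
    n_groups: int = 10,
    n_mc: int = 500,
    seed: int | None = 0,
) -> dict:
    """Yen's Q1 item-fit statistic with a parametric-bootstrap null.

    Persons are ranked into ``n_groups`` near-equal ability groups by their
    EAP estimates (empty groups collapse into their neighbours); each
    item's statistic sums the squared standardised gaps between observed
    and model-expected group success rates.  Significance comes from the
    rank of the observed statistic among ``n_mc`` datasets simulated from
    the fitted model (abilities redrawn from N(0,1), the scoring step
    re-run per replicate), Bonferroni-adjusted across items.  ``model`` is
    any object exposing ``discrimination`` and ``item_difficulties``.
    """
    params = ResponseModelParams(discrimination=float(model.discrimination))
    difficulties = np.asarray(model.item_difficulties, dtype=float)
    scores = matrix.scores
    obs_mask = ~np.isnan(scores)
    theta_hats = _eap_thetas(scores, difficulties, params)
    observed = _q1_statistics(scores, difficulties, params, theta_hats, n_groups)
    result = {
        "items": list(matrix.items),
        "q1": observed,
        "p_values": None,
        "p_bonferroni": None,
        "n_mc": n_mc,
    }
    if n_mc <= 0:
        return result
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(matrix.items))
    for _ in range(n_mc):
        theta = rng.standard_normal(scores.shape[0])
        p = prob_correct_cabat(theta[:, None], difficulties[None, :], params.discrimination)
        sim = np.where(obs_mask, (rng.random(scores.shape) < p).astype(float), np.nan)
        sim_thetas = _eap_thetas(sim, difficulties, params)
        sim_stats = _q1_statistics(sim, difficulties, params, sim_thetas, n_groups)
        exceed += sim_stats >= observed
    p_vals = (1.0 + exceed) / (n_mc + 1.0)
    result["p_values"] = p_vals
    result["p_bonferroni"] = np.minimum(1.0, p_vals * len(matrix.items))
    return result


def _pattern_bits(order: int) -> np.ndarray:
    codes = np.arange(2**order)
    return ((codes[:, None] >> (order - 1 - np.arange(order))) & 1).astype(bool)


def _pattern_probs(p_nodes: np.ndarray, weights: np.ndarray, cols: tuple[int, ...]):
    """Model-implied joint probabilities of all response patterns for cols."""
    k = len(cols)
    sub_p = p_nodes[:, list(cols)]  # nodes x k
    bits = _pattern_bits(k)  # 2^k x k
    sel = np.where(bits[None, :, :], sub_p[:, None, :], 1.0 - sub_p[:, None, :])
    return weights @ sel.prod(axis=2)


def margins_check(
    model,
    matrix: ResponseMatrix,
    order: int = 2,
    threshold: float = 4.0,
    n_quadrature: int = 61,
) -> dict:
    """Fit on the two- or three-way margins.

    Every item pair (order 2) or triplet (order 3) contributes one check
    per joint response pattern (4 or 8), comparing the observed pattern
    count among persons answering all items in the set to the model-implied
    probability integrated over the N(0,1) ability prior.  A combination is
    flagged when its squared standardised residual exceeds ``threshold``
    (default 4, a two-sigma criterion).  ``n_combinations`` is exactly
    C(n, order) * 2**order.
    """
    if order not in (2, 3):
        raise ValueError("order must be 2 or 3")
    from .estimation import gauss_hermite_prior

    difficulties = np.asarray(model.item_difficulties, dtype=float)
    a = float(model.discrimination)
    nodes, weights = gauss_hermite_prior(n_quadrature)
    p_nodes = np.asarray(prob_correct_cabat(nodes[:, None], difficulties[None, :], a))
    scores = matrix.scores
    obs = ~np.isnan(scores)
    n_items = len(matrix.items)
    flagged = []
    total = 0
    for cols in itertools.combinations(range(n_items), order):
        rows = obs[:, cols].all(axis=1)
        total += 2**order
        n = int(rows.sum())
        expected = _pattern_probs(p_nodes, weights, cols)
        if n == 0:
            continue
        sub = scores[np.ix_(rows.nonzero()[0], cols)].astype(int)
        codes = np.zeros(n, dtype=int)
        for i in range(order):
            codes = codes * 2 + sub[:, i]
        counts = np.bincount(codes, minlength=2**order)
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = (counts - n * expected) ** 2 / (n * expected * (1.0 - expected))
        for code in range(2**order):
            if np.isfinite(z2[code]) and z2[code] > threshold:
                flagged.append(
                    {
                        "items": tuple(matrix.items[c] for c in cols),
                        "pattern": tuple((code >> (order - 1 - i)) & 1 for i in range(order)),
                        "z_squared": float(z2[code]),
                    }
                )
    return {
        "order": order,
        "n_combinations": math.comb(n_items, order) * 2**order,
        "n_examined": total,
        "n_flagged": len(flagged),
        "flagged": flagged,
        "threshold": threshold,
    }


def tetrachoric_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum-likelihood tetrachoric correlation of two binary variables.

    Thresholds are fixed at the normal quantiles of the margins and the
    latent correlation is optimised against the multinomial likelihood of
    the 2x2 table.  Empty cells receive a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no jointly observed responses")
    n11 = float(np.sum((x == 1) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n00 = float(np.sum((x == 0) & (y == 0)))
    cells = np.array([n00, n01, n10, n11])
    if (cells == 0).any():
        cells = cells + 0.5
    n = cells.sum()
    px = (cells[2] + cells[3]) / n  # P(x = 1)
    py = (cells[1] + cells[3]) / n
    h = norm.ppf(1.0 - px)  # P(Z > h) = px
    k = norm.ppf(1.0 - py)

    def negll(rho):
        cov = [[1.0, rho], [rho, 1.0]]
        cdf_hk = multivariate_normal.cdf([h, k], mean=[0.0, 0.0], cov=cov)
        p11 = 1.0 - norm.cdf(h) - norm.cdf(k) + cdf_hk
        p10 = (1.0 - norm.cdf(h)) - p11
        p01 = (1.0 - norm.cdf(k)) - p11
        p00 = 1.0 - p11 - p10 - p01
        probs = np.clip([p00, p01, p10, p11], 1e-12, 1.0)
        return -float(np.dot(cells, np.log(probs)))

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def tetrachoric_matrix(scores: np.ndarray) -> np.ndarray:
    n_items = scores.shape[1]
    mat = np.eye(n_items)
    for i, j in itertools.combinations(range(n_items), 2):
        r = tetrachoric_correlation(scores[:, i], scores[:, j])
        mat[i, j] = mat[j, i] = r
    return mat


def second_eigenvalue(corr: np.ndarray) -> float:
    vals = np.linalg.eigvalsh(corr)
    return float(np.sort(vals)[-2])


def modified_parallel_analysis(
    matrix: ResponseMatrix,
    model=None,
    n_mc: int = 500,
    seed: int | None = 0,
) -> dict:
    """Unidimensionality check via the tetrachoric second eigenvalue.

    The observed second eigenvalue of the tetrachoric correlation matrix is
    compared to its distribution under ``n_mc`` datasets simulated from the
    fitted unidimensional model (fit here if ``model`` is None); the
    p-value is the rank-based upper-tail proportion.  A large second
    eigenvalue relative to the null indicates a second latent dimension.
    """
    if matrix.n_items < 3:
        raise ValueError("need at least 3 items")
    if model is None:
        model = fit_constrained_3pl(matrix)
    a = float(model.discrimination)
    difficulties = np.asarray(model.item_difficulties, dtype=float)
    observed = second_eigenvalue(tetrachoric_matrix(matrix.scores))
    rng = np.random.default_rng(seed)
    obs_mask = ~np.isnan(matrix.scores)
    exceed = 0
    sims = []
    for _ in range(n_mc):
        theta = rng.standard_normal(matrix.n_persons)
        p = prob_correct_cabat(theta[:, None], difficulties[None, :], a)
        sim = np.where(obs_mask, (rng.random(matrix.scores.shape) < p).astype(float), np.nan)
        ev = second_eigenvalue(tetrachoric_matrix(sim))
        sims.append(ev)
        exceed += ev >= observed
    p_val = (1.0 + exceed) / (n_mc + 1.0) if n_mc > 0 else None
    return {
        "second_eigenvalue": observed,
        "null_eigenvalues": np.asarray(sims),
        "p_value": p_val,
        "n_mc": n_mc,
    }
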
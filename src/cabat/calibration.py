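"""Calibration of the response model from observed response matrices.

Two routes estimate the item parameters:

* the two-stage route — fit a constrained three-parameter logistic model
  (guessing 0.5, inattention 1, one shared discrimination, free per-item
  difficulties) by marginal maximum likelihood, then regress the estimated
  difficulties on item features by ordinary least squares;
* the one-stage explanatory route — replace the per-item difficulty with a
  linear predictor of the item features and maximise the same marginal
  likelihood directly (the mixed-model formulation: a Gaussian person
  effect whose SD is the IRT discrimination, and raw fixed effects that map
  to difficulty coefficients as -B/a).

The marginal likelihood integrates ability over a standard-normal
population by Gauss-Hermite quadrature; missing responses (persons may
answer arbitrary item subsets, as under adaptive administration) are
treated as ignorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1

from .estimation import THETA_BOUNDS, gauss_hermite_prior
from .item_bank import DifficultyCoefficients, glmm_to_irt_coefficients

__all__ = [
    "ResponseMatrix",
    "CalibrationResult",
    "marginal_loglik_per_person",
    "fit_constrained_3pl",
    "regress_difficulty_on_features",
    "fit_explanatory_model",
]

GUESSING = 0.5


@dataclass
class ResponseMatrix:
    """Persons × items binary scores with missing entries allowed (NaN)."""

    persons: list[str]
    items: list[str]
    scores: np.ndarray  # float array, values in {0, 1, nan}
    item_features: pd.DataFrame | None = None  # indexed by item id

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.persons), len(self.items)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.persons)} persons x {len(self.items)} items"
            )
        observed = ~np.isnan(self.scores)
        vals = self.scores[observed]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("scores must be 0, 1 or missing")
        if not observed.any(axis=1).all():
            bad = [p for p, ok in zip(self.persons, observed.any(axis=1)) if not ok]
            raise ValueError(f"persons with no observed scores: {bad}")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.scores)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass
class CalibrationResult:
    discrimination: float
    discrimination_se: float
    log_likelihood: float
    converged: bool
    n_iter: int
    item_ids: list[str] = field(default_factory=list)
    item_difficulties: np.ndarray | None = None
    item_difficulty_ses: np.ndarray | None = None
    flagged_items: list[str] = field(default_factory=list)
    coefficients: DifficultyCoefficients | None = None
    raw_effects: np.ndarray | None = None
    raw_effect_ses: np.ndarray | None = None
    irt_effects: np.ndarray | None = None
    irt_effect_ses: np.ndarray | None = None
    gradient_norm: float | None = None


_P_CEIL = 1.0 - 1e-12  # keep log1p(-p) finite when the logistic saturates


def _pattern_loglik_matrix(scores: np.ndarray, log_p: np.ndarray, log_q: np.ndarray):
    """Persons x nodes matrix of conditional pattern log-likelihoods."""
    obs = ~np.isnan(scores)
    x = np.where(obs, scores, 0.0)
    m = obs.astype(float)
    return x @ log_p.T + (m - x) @ log_q.T


def _marginal_ll_and_posterior(scores, p, weights):
    """Total marginal log-likelihood and posterior node weights R (P x K)."""
    a_mat = _pattern_loglik_matrix(scores, np.log(p), np.log1p(-p)) + np.log(weights)[None, :]
    ll_p = logsumexp(a_mat, axis=1)
    post = np.exp(a_mat - ll_p[:, None])
    return float(ll_p.sum()), post


def marginal_loglik_per_person(
    scores: np.ndarray,
    difficulties: np.ndarray,
    discrimination: float,
    nodes: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Per-person log marginal likelihood at fixed item parameters.

    ``log sum_k w_k * L_p(theta_k)`` with the person's conditional pattern
    likelihood evaluated at each quadrature node.  Exposed separately so a
    dense-grid integration oracle can check the quadrature.
    """
    psi = expit(discrimination * (nodes[:, None] - difficulties[None, :]))
    p = np.clip(GUESSING + (1.0 - GUESSING) * psi, None, _P_CEIL)
    a_mat = _pattern_loglik_matrix(scores, np.log(p), np.log1p(-p))
    return logsumexp(a_mat + np.log(weights)[None, :], axis=1)


def _start_difficulties(scores: np.ndarray, a0: float) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pbar = np.nanmean(scores, axis=0)
    psi = np.clip((pbar - GUESSING) / (1.0 - GUESSING), 0.02, 0.98)
    return -np.log(psi / (1.0 - psi)) / a0


def fit_constrained_3pl(
    matrix: ResponseMatrix, quadrature: int = 61, maxiter: int = 500,
    standard_errors: bool = True,
) -> CalibrationResult:
    """Marginal ML fit of the constrained 3PL (free per-item difficulties).

    Items whose observed column is all-correct or all-incorrect have no
    interior difficulty optimum; they are flagged, a warning is emitted,
    and their estimates sit at the search bounds.  ``standard_errors=False``
    skips the observed-information (numerical Hessian) step, which grows
    quadratically in the number of items.
    """
    if matrix.n_items < 2:
        raise ValueError("need at least 2 items")
    scores = matrix.scores
    nodes, weights = gauss_hermite_prior(quadrature)
    obs = matrix.observed
    col_mean = np.array([
        scores[obs[:, j], j].mean() if obs[:, j].any() else np.nan
        for j in range(matrix.n_items)
    ])
    degenerate = np.isin(col_mean, (0.0, 1.0))
    flagged = [matrix.items[j] for j in np.nonzero(degenerate)[0]]
    if flagged:
        warnings.warn(
            f"items with all-correct/all-incorrect columns: {flagged}; "
            "their difficulties are reported at the search bounds",
            stacklevel=2,
        )

    lo, hi = THETA_BOUNDS
    obs_f = obs.astype(float)
    x_z = np.where(obs, scores, 0.0)

    def negll_grad(x):
        a = np.exp(x[0])
        b = x[1:]
        psi = expit(a * (nodes[:, None] - b[None, :]))
        p = np.clip(GUESSING + (1.0 - GUESSING) * psi, None, _P_CEIL)
        ll, post = _marginal_ll_and_posterior(scores, p, weights)
        # posterior-weighted score: inner_kj = sum_p r_pk (x_pj - p_kj) obs_pj
        inner = post.T @ x_z - p * (post.T @ obs_f)
        u = 1.0 / (p * (1.0 - p))
        dp_dpsi = (1.0 - GUESSING) * psi * (1.0 - psi)
        g_b = -(inner * u * dp_dpsi * a).sum(axis=0)
        g_loga = float((inner * u * dp_dpsi * a * (nodes[:, None] - b[None, :])).sum())
        return -ll, -np.concatenate([[g_loga], g_b])

    def negll(x):
        return negll_grad(x)[0]

    x0 = np.concatenate([[0.0], _start_difficulties(scores, 1.0)])
    bounds = [(np.log(0.05), np.log(20.0))] + [(lo, hi)] * matrix.n_items
    res = minimize(
        negll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    a_hat = float(np.exp(res.x[0]))
    b_hat = res.x[1:].copy()

    ses = np.full(matrix.n_items, np.nan)
    a_se = np.nan
    free = ~degenerate & ~np.isnan(col_mean)
    if not standard_errors:
        return CalibrationResult(
            discrimination=a_hat,
            discrimination_se=a_se,
            log_likelihood=-float(res.fun),
            converged=bool(res.success),
            n_iter=int(res.nit),
            item_ids=list(matrix.items),
            item_difficulties=b_hat,
            item_difficulty_ses=ses,
            flagged_items=flagged,
            gradient_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else None,
        )
    try:
        hess = approx_hess1(res.x, negll)
        keep = np.concatenate([[True], free])
        cov = np.linalg.inv(hess[np.ix_(keep, keep)])
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        a_se = float(a_hat * diag[0])  # delta method for a = exp(log a)
        ses[free] = diag[1:]
    except np.linalg.LinAlgError:  # pragma: no cover - singular information
        warnings.warn("observed information singular; standard errors unavailable")
    return CalibrationResult(
        discrimination=a_hat,
        discrimination_se=a_se,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        item_ids=list(matrix.items),
        item_difficulties=b_hat,
        item_difficulty_ses=ses,
        flagged_items=flagged,
        gradient_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else None,
    )


def regress_difficulty_on_features(
    difficulties: Sequence[float], features: pd.DataFrame
) -> dict:
    """OLS of estimated item difficulties on item features.

    Returns unstandardised and fully standardised coefficients with
    standard errors, the adjusted R^2 and the overall F test.  An empty
    feature frame fits the intercept-only model (coefficient = mean
    difficulty).
    """
    y = np.asarray(difficulties, dtype=float)
    x = features.astype(float) if features is not None else pd.DataFrame(index=range(len(y)))
    design = sm.add_constant(x, has_constant="add")
    model = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    beta = {}
    for name in x.columns:
        sd_x = x[name].std(ddof=1)
        if sd_x == 0:
            raise ValueError(f"feature {name!r} has no variation")
        beta[name] = float(model.params[name] * sd_x / sd_y) if sd_y > 0 else np.nan
    return {
        "coefficients": model.params.to_dict(),
        "standard_errors": model.bse.to_dict(),
        "standardized_coefficients": beta,
        "adj_r_squared": float(model.rsquared_adj) if len(x.columns) else np.nan,
        "f_statistic": float(model.fvalue) if len(x.columns) else np.nan,
        "f_pvalue": float(model.f_pvalue) if len(x.columns) else np.nan,
        "residuals": np.asarray(model.resid),
        "model": model,
    }


def _feature_design(matrix: ResponseMatrix) -> np.ndarray:
    if matrix.item_features is None:
        raise ValueError("item_features required for the explanatory fit")
    feats = matrix.item_features.loc[matrix.items]
    acc = feats["accuracy"].to_numpy(dtype=float)
    if "direction" in feats.columns:
        direction = feats["direction"]
        if direction.dtype == object:
            behind = (direction == "behind").to_numpy(dtype=float)
        else:
            behind = direction.to_numpy(dtype=float)
    else:
        behind = np.zeros_like(acc)
    return np.column_stack([np.ones_like(acc), acc, behind])


def fit_explanatory_model(
    matrix: ResponseMatrix, quadrature: int = 61, maxiter: int = 500
) -> CalibrationResult:
    """One-stage explanatory fit: difficulty = linear predictor of features.

    Parameterised on the raw (mixed-model) scale: the conditional linear
    predictor is ``a*theta + B0 + B1*accuracy + B2*behind`` with
    ``theta ~ N(0, 1)``, so the IRT difficulty coefficients are ``-B/a``
    and the discrimination is the person-effect SD ``a``.
    """
    design = _feature_design(matrix)  # n_items x 3
    scores = matrix.scores
    nodes, weights = gauss_hermite_prior(quadrature)
    obs = matrix.observed
    obs_f = obs.astype(float)
    x_z = np.where(obs, scores, 0.0)

    def negll_grad(x):
        a = np.exp(x[0])
        eta = nodes[:, None] * a + (design @ x[1:])[None, :]
        psi = expit(eta)
        p = np.clip(GUESSING + (1.0 - GUESSING) * psi, None, _P_CEIL)
        ll, post = _marginal_ll_and_posterior(scores, p, weights)
        inner = post.T @ x_z - p * (post.T @ obs_f)
        core = inner / (p * (1.0 - p)) * (1.0 - GUESSING) * psi * (1.0 - psi)
        g_b = core.sum(axis=0) @ design  # d ll / d B_i
        g_loga = float((core * (a * nodes[:, None])).sum())
        return -ll, -np.concatenate([[g_loga], g_b])

    def negll(x):
        return negll_grad(x)[0]

    x0 = np.array([0.0, 0.0, 0.0, 0.0])
    bounds = [(np.log(0.05), np.log(20.0))] + [(-50.0, 50.0)] * 3
    res = minimize(negll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8})
    a_hat = float(np.exp(res.x[0]))
    raw = res.x[1:].copy()  # B0, B1, B2
    raw_ses = np.full(3, np.nan)
    a_se = np.nan
    irt_ses = np.full(3, np.nan)
    try:
        hess = approx_hess1(res.x, negll)
        cov = np.linalg.inv(hess)
        diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        a_se = float(a_hat * diag[0])
        raw_ses = diag[1:]
        # first-order delta method for c = -B/a, holding a's covariance aside
        irt_ses = raw_ses / a_hat
    except np.linalg.LinAlgError:  # pragma: no cover
        warnings.warn("observed information singular; standard errors unavailable")
    coefficients = glmm_to_irt_coefficients(raw, a_hat)
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else None
    if not res.success:
        warnings.warn(f"explanatory fit did not converge (|grad| = {grad_norm})")
    return CalibrationResult(
        discrimination=a_hat,
        discrimination_se=a_se,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        n_iter=int(res.nit),
        item_ids=list(matrix.items),
        coefficients=coefficients,
        raw_effects=raw,
        raw_effect_ses=raw_ses,
        irt_effects=np.array(
            [coefficients.intercept, coefficients.accuracy_effect, coefficients.direction_effect]
        ),
        irt_effect_ses=irt_ses,
        gradient_norm=grad_norm,
    )
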
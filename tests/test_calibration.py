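"""Calibration fitters against simulation truth and integration oracles."""

import numpy as np
import pandas as pd
import pytest

import cabat
from cabat.calibration import (
    ResponseMatrix,
    fit_constrained_3pl,
    fit_explanatory_model,
    marginal_loglik_per_person,
    regress_difficulty_on_features,
)
from cabat.estimation import gauss_hermite_prior
from cabat.fixtures import MatrixFixtureSpec, make_balanced_assignment_matrix


def _simulated_matrix(difficulties, a, n_persons, seed):
    rng = np.random.default_rng(seed)
    difficulties = np.asarray(difficulties, dtype=float)
    theta = rng.standard_normal(n_persons)
    p = cabat.prob_correct_cabat(theta[:, None], difficulties[None, :], a)
    scores = (rng.random((n_persons, difficulties.size)) < p).astype(float)
    return ResponseMatrix(
        persons=[f"p{i}" for i in range(n_persons)],
        items=[f"i{j}" for j in range(difficulties.size)],
        scores=scores,
    )


class TestResponseMatrix:
    def test_shape_and_value_validation(self):
        with pytest.raises(ValueError):
            ResponseMatrix(["p"], ["a", "b"], np.zeros((1, 3)))
        with pytest.raises(ValueError):
            ResponseMatrix(["p"], ["a"], np.asarray([[2.0]]))
        with pytest.raises(ValueError):
            ResponseMatrix(["p"], ["a"], np.asarray([[np.nan]]))


class TestMarginalLikelihoodOracle:
    def test_quadrature_matches_dense_grid_integration(self):
        """61-node quadrature vs 10,001-point grid integration, per person."""
        matrix = _simulated_matrix(np.linspace(-1.5, 1.5, 8), 1.166, 30, seed=5)
        nodes, weights = gauss_hermite_prior(61)
        quad = marginal_loglik_per_person(matrix.scores, np.linspace(-1.5, 1.5, 8),
                                          1.166, nodes, weights)
        grid = np.linspace(-6, 6, 10_001)
        dx = grid[1] - grid[0]
        dens = np.exp(-0.5 * grid**2) / np.sqrt(2 * np.pi)
        p = cabat.prob_correct_cabat(grid[:, None], np.linspace(-1.5, 1.5, 8)[None, :], 1.166)
        logp, logq = np.log(p), np.log1p(-p)
        a_mat = matrix.scores @ logp.T + (1 - matrix.scores) @ logq.T
        dense = np.log((np.exp(a_mat) * dens[None, :] * dx).sum(axis=1))
        np.testing.assert_allclose(quad, dense, atol=1e-6)


class TestConstrained3PL:
    def test_parameter_recovery(self):
        true_a, true_b = 1.6, np.linspace(-2, 2, 27)
        matrix = _simulated_matrix(true_b, true_a, 500, seed=7)
        fit = fit_constrained_3pl(matrix)
        assert fit.converged
        assert np.abs(fit.item_difficulties - true_b).mean() < 0.25
        assert abs(fit.discrimination - true_a) / true_a < 0.15
        assert fit.discrimination_se > 0

    def test_identical_columns_identical_difficulties(self):
        matrix = _simulated_matrix([0.0, 1.0], 1.2, 80, seed=3)
        scores = np.column_stack([matrix.scores, matrix.scores[:, 0]])
        m = ResponseMatrix(matrix.persons, ["a", "b", "a2"], scores)
        fit = fit_constrained_3pl(m)
        assert fit.item_difficulties[0] == pytest.approx(fit.item_difficulties[2], abs=1e-5)

    def test_optimum_beats_random_parameter_vectors(self, rng):
        matrix = _simulated_matrix(np.linspace(-1, 1, 6), 1.3, 120, seed=11)
        fit = fit_constrained_3pl(matrix)
        nodes, weights = gauss_hermite_prior(61)
        for _ in range(100):
            a = rng.uniform(0.3, 3.0)
            b = rng.uniform(-3, 3, size=6)
            ll = marginal_loglik_per_person(matrix.scores, b, a, nodes, weights).sum()
            assert fit.log_likelihood >= ll - 1e-6

    def test_degenerate_columns_flagged(self):
        matrix = _simulated_matrix([0.0, 0.5], 1.2, 40, seed=1)
        scores = matrix.scores.copy()
        scores[:, 1] = 1.0
        m = ResponseMatrix(matrix.persons, matrix.items, scores)
        with pytest.warns(UserWarning, match="all-correct"):
            fit = fit_constrained_3pl(m)
        assert fit.flagged_items == ["i1"]

    def test_difficulty_shift_equivariance(self):
        base = np.linspace(-1, 1, 10)
        f0 = fit_constrained_3pl(_simulated_matrix(base, 1.166, 400, seed=21))
        f1 = fit_constrained_3pl(_simulated_matrix(base + 0.5, 1.166, 400, seed=21))
        shift = (f1.item_difficulties - f0.item_difficulties).mean()
        assert shift == pytest.approx(0.5, abs=0.15)


class TestDifficultyRegression:
    def test_exact_linear_relation(self):
        acc = np.linspace(0.5, 0.99, 16)
        diffs = -5.0 + 7.0 * acc
        res = regress_difficulty_on_features(diffs, pd.DataFrame({"accuracy": acc}))
        assert res["coefficients"]["accuracy"] == pytest.approx(7.0, abs=1e-8)
        assert res["adj_r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert np.abs(res["residuals"]).max() < 1e-8

    def test_slope_recovery_under_noise(self):
        """Difficulties linear in accuracy (slope 10.025) plus sd-0.5 noise."""
        hits = 0
        acc = np.linspace(0.55, 0.99, 16)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            diffs = -8.388 + 10.025 * acc + rng.normal(0, 0.5, size=16)
            res = regress_difficulty_on_features(diffs, pd.DataFrame({"accuracy": acc}))
            slope, se = res["coefficients"]["accuracy"], res["standard_errors"]["accuracy"]
            hits += abs(slope - 10.025) <= 2 * se
        assert hits >= 18

    def test_intercept_only_gives_mean(self):
        diffs = [0.2, 0.8, -0.4]
        res = regress_difficulty_on_features(diffs, pd.DataFrame(index=range(3)))
        assert res["coefficients"]["const"] == pytest.approx(np.mean(diffs), abs=1e-10)

    def test_standardized_coefficient(self):
        acc = np.linspace(0.5, 0.99, 20)
        rng = np.random.default_rng(0)
        diffs = 2.0 * acc + rng.normal(0, 0.1, 20)
        res = regress_difficulty_on_features(diffs, pd.DataFrame({"accuracy": acc}))
        expected = res["coefficients"]["accuracy"] * acc.std(ddof=1) / np.std(diffs, ddof=1)
        assert res["standardized_coefficients"]["accuracy"] == pytest.approx(expected, abs=1e-9)


class TestExplanatoryModel:
    def test_recovers_published_coefficients(self):
        matrix, truth = make_balanced_assignment_matrix(
            MatrixFixtureSpec(n_persons=300, seed=42), n_levels=27
        )
        fit = fit_explanatory_model(matrix)
        assert fit.converged
        true_vals = np.array([-5.393, 7.247, -0.576])
        for est, se, true in zip(fit.irt_effects, fit.irt_effect_ses, true_vals):
            tol = max(0.20 * abs(true), 2 * se)
            assert abs(est - true) <= tol
        assert abs(fit.discrimination - 1.166) <= max(0.20 * 1.166,
                                                      2 * fit.discrimination_se)

    def test_raw_and_irt_scales_linked(self):
        matrix, _ = make_balanced_assignment_matrix(
            MatrixFixtureSpec(n_persons=100, seed=2), n_levels=9
        )
        fit = fit_explanatory_model(matrix)
        np.testing.assert_allclose(
            -fit.raw_effects / fit.discrimination, fit.irt_effects, atol=1e-9
        )

    def test_null_direction_effect_recovered(self):
        from cabat.item_bank import DifficultyCoefficients

        coeffs = DifficultyCoefficients(direction_effect=0.0)
        hits = 0
        for seed in range(10):
            matrix, _ = make_balanced_assignment_matrix(
                MatrixFixtureSpec(n_persons=120, seed=seed),
                n_levels=15, coefficients=coeffs,
            )
            fit = fit_explanatory_model(matrix)
            hits += abs(fit.irt_effects[2]) <= 2 * fit.irt_effect_ses[2]
        assert hits >= 9

    def test_two_stage_agrees_with_one_stage_on_balanced_design(self):
        """3PL + feature regression vs direct explanatory fit, complete data."""
        from cabat.item_bank import accuracy_grid, build_bank

        bank = build_bank(["tA", "tB"], accuracy_grid(9, 0.55, 0.95),
                          ["ahead", "behind"], ["target_first"], seed=0)
        rng = np.random.default_rng(31)
        theta = rng.standard_normal(600)
        diffs = bank.difficulties
        p = cabat.prob_correct_cabat(theta[:, None], diffs[None, :], 1.166)
        scores = (rng.random((600, len(bank))) < p).astype(float)
        feats = pd.DataFrame(
            {
                "accuracy": [it.accuracy for it in bank],
                "direction": [it.direction for it in bank],
            },
            index=[it.item_id for it in bank],
        )
        matrix = ResponseMatrix(
            [f"p{i}" for i in range(600)], [it.item_id for it in bank], scores,
            item_features=feats,
        )
        two_stage_fit = fit_constrained_3pl(matrix)
        reg = regress_difficulty_on_features(
            two_stage_fit.item_difficulties,
            pd.DataFrame({
                "accuracy": feats["accuracy"].to_numpy(),
                "behind": (feats["direction"] == "behind").astype(float).to_numpy(),
            }),
        )
        one_stage = fit_explanatory_model(matrix)
        assert reg["coefficients"]["accuracy"] == pytest.approx(
            one_stage.irt_effects[1], abs=1.5
        )
        assert reg["coefficients"]["behind"] == pytest.approx(
            one_stage.irt_effects[2], abs=0.5
        )

    def test_sign_structure(self):
        matrix, _ = make_balanced_assignment_matrix(
            MatrixFixtureSpec(n_persons=200, seed=9), n_levels=15
        )
        fit = fit_explanatory_model(matrix)
        assert fit.irt_effects[1] > 0  # higher accuracy -> harder
        assert fit.irt_effects[2] < 0  # behind-the-beat -> easier
        # per-item route on a complete design shows the same accuracy slope
        from cabat.item_bank import PUBLISHED_COEFFICIENTS, accuracy_grid, predict_difficulty

        acc = accuracy_grid(12, 0.55, 0.99)
        diffs = predict_difficulty(acc, "ahead", PUBLISHED_COEFFICIENTS)
        complete = _simulated_matrix(diffs, 1.166, 400, seed=9)
        three_pl = fit_constrained_3pl(complete, standard_errors=False)
        reg = regress_difficulty_on_features(
            three_pl.item_difficulties, pd.DataFrame({"accuracy": acc})
        )
        assert reg["coefficients"]["accuracy"] > 0

    def test_missing_features_error(self):
        matrix = _simulated_matrix([0.0, 1.0], 1.2, 30, seed=0)
        with pytest.raises(ValueError):
            fit_explanatory_model(matrix)
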
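"""Objective values, lambda_max, and solver correctness against oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from plps.optimize import (
    PenaltySpec,
    default_lambda_grid,
    lambda_max,
    negloglik,
    objective,
    predict_prob,
    solve_l1_logistic,
    solve_path,
)
from plps.patterns import CONSTANT, BinaryDataset, Pattern, build_design
from tests.conftest import random_binary_dataset


def oracle_solve(design, y, weights):
    """High-accuracy reference minimizer: L-BFGS-B on the split c = a - b."""
    A = np.asarray(design.values.todense())
    m = A.shape[1]

    def obj(z):
        c = z[:m] - z[m:]
        return negloglik(y, A @ c) + float(weights @ np.abs(c))

    res = minimize(
        obj, np.zeros(2 * m), method="L-BFGS-B",
        bounds=[(0, None)] * (2 * m),
        options=dict(maxiter=50_000, maxfun=200_000, ftol=1e-16, gtol=1e-12),
    )
    return res.fun


class TestNegloglik:
    def test_zero_predictor_gives_log2(self):
        y = np.array([0, 1, 1, 0, 1.0])
        assert negloglik(y, np.zeros(5)) == pytest.approx(math.log(2), abs=1e-12)

    def test_saturated_predictions_vanish(self):
        assert negloglik([1.0, 0.0], [50.0, -50.0]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_termwise_sum(self):
        y = np.array([1, 1, 0.0])
        f = np.array([1.0, -1.0, 0.5])
        expected = np.mean([-yi * fi + math.log(1 + math.exp(fi))
                            for yi, fi in zip(y, f)])
        assert negloglik(y, f) == pytest.approx(expected, rel=1e-12)

    def test_stable_at_extreme_predictors(self):
        val = negloglik([1.0], [-1000.0])
        assert np.isfinite(val) and val == pytest.approx(1000.0, rel=1e-9)


class TestObjective:
    def test_zero_coefficients_reduce_to_likelihood(self, toy_design, toy_data):
        pen = PenaltySpec.single(toy_design, 0.3)
        c = np.zeros(toy_design.n_columns)
        assert objective(c, toy_design, toy_data.y, pen) == pytest.approx(
            negloglik(toy_data.y, np.zeros(toy_data.n))
        )

    def test_penalty_term_hand_value(self, toy_design, toy_data):
        c = np.zeros(toy_design.n_columns)
        c[1], c[2] = 0.5, -0.2
        pen = PenaltySpec.single(toy_design, 0.1)
        f = toy_design.values @ c
        assert objective(c, toy_design, toy_data.y, pen) == pytest.approx(
            negloglik(toy_data.y, f) + 0.07
        )

    def test_two_penalty_degenerates_to_single(self, toy_design):
        lam = 0.17
        w_single = PenaltySpec.single(toy_design, lam).weights
        w_two = PenaltySpec.two(toy_design, lam, lam).weights
        assert np.array_equal(w_single, w_two)


class TestLambdaMax:
    def test_attained_by_response_aligned_column(self, rng):
        n = 60
        y = (rng.random(n) < 0.5).astype(float)
        X = (rng.random((n, 3)) < 0.5).astype(int)
        X[:, 1] = y.astype(int)  # perfectly aligned column
        data = BinaryDataset(y=y, X=X)
        d = build_design(data, [CONSTANT] + [Pattern((j,)) for j in range(3)])
        ybar = y.mean()
        scores = np.abs(np.asarray(d.values.todense()).T @ (y - ybar)) / n
        assert lambda_max(d, y) == pytest.approx(scores[2])

    def test_solution_empty_at_lambda_max(self, toy_design, toy_data):
        lam = 1.01 * lambda_max(toy_design, toy_data.y)
        fit = solve_l1_logistic(
            toy_design, toy_data.y, PenaltySpec.single(toy_design, lam)
        )
        assert fit.active.size == 0
        ybar = toy_data.y.mean()
        assert fit.intercept == pytest.approx(math.log(ybar / (1 - ybar)), abs=1e-5)

    def test_near_zero_for_orthogonal_noise(self, rng):
        # independent noise columns: scores scale like n^{-1/2}
        n = 20_000
        data = random_binary_dataset(rng, n, 5, prevalence=0.5)
        d = build_design(
            data, [CONSTANT] + [Pattern((j,)) for j in range(5)]
        )
        assert lambda_max(d, data.y) < 0.02


class TestSolver:
    def test_matches_unpenalized_mle(self, rng):
        data = random_binary_dataset(rng, 50, 3)
        d = build_design(data, [CONSTANT] + [Pattern((j,)) for j in range(3)])
        fit = solve_l1_logistic(d, data.y, PenaltySpec.single(d, 0.0))
        A = np.asarray(d.values.todense())

        res = minimize(
            lambda c: negloglik(data.y, A @ c), np.zeros(4), method="BFGS",
            options=dict(gtol=1e-12, maxiter=10000),
        )
        assert np.abs(fit.coef - res.x).max() < 1e-4

    def test_oracle_equivalence_random_instances(self, rng):
        """Objective within 1e-6 of a tight generic solver, 50 instances."""
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(15, 61))
            p = int(rng.integers(2, 10))
            data = random_binary_dataset(rng, n, p, prevalence=0.4)
            pats = [CONSTANT] + [Pattern((j,)) for j in range(p)]
            if p >= 3:
                pats.append(Pattern((0, 1)))
                pats.append(Pattern((1, 2)))
            d = build_design(data, pats)
            lam = float(rng.uniform(0.005, 0.2))
            pen = PenaltySpec.single(d, lam)
            fit = solve_l1_logistic(d, data.y, pen)
            worst = max(worst, fit.objective - oracle_solve(d, data.y, pen.weights))
        assert worst <= 1e-6

    def test_two_penalty_with_equal_lambdas_matches_single(self, rng):
        data = random_binary_dataset(rng, 60, 4)
        pats = [CONSTANT] + [Pattern((j,)) for j in range(4)] + [Pattern((0, 2))]
        d = build_design(data, pats)
        lam = 0.04
        fit1 = solve_l1_logistic(d, data.y, PenaltySpec.single(d, lam))
        fit2 = solve_l1_logistic(d, data.y, PenaltySpec.two(d, lam, lam))
        assert np.abs(fit1.coef - fit2.coef).max() <= 1e-6

    def test_objective_convex_on_segment(self, rng, toy_design, toy_data):
        pen = PenaltySpec.single(toy_design, 0.05)
        for _ in range(10):
            a = rng.normal(size=toy_design.n_columns)
            b = rng.normal(size=toy_design.n_columns)
            mid = objective((a + b) / 2, toy_design, toy_data.y, pen)
            ends = (objective(a, toy_design, toy_data.y, pen)
                    + objective(b, toy_design, toy_data.y, pen)) / 2
            assert mid <= ends + 1e-12

    def test_degenerate_response_flagged(self, rng):
        X = (rng.random((10, 2)) < 0.5).astype(int)
        data = BinaryDataset(y=np.ones(10), X=X)
        d = build_design(data, [CONSTANT, Pattern((0,))])
        fit = solve_l1_logistic(d, data.y, PenaltySpec.single(d, 0.1))
        assert "degenerate-response" in fit.flags
        assert fit.active.size == 0


class TestPath:
    def test_above_lambda_max_all_intercept_only(self, toy_design, toy_data):
        lm = lambda_max(toy_design, toy_data.y)
        fits = solve_path(toy_design, toy_data.y, np.array([2 * lm, lm]))
        assert all(f.active.size == 0 for f in fits)

    def test_warm_start_agrees_with_cold_start(self, rng):
        data = random_binary_dataset(rng, 70, 5)
        d = build_design(data, [CONSTANT] + [Pattern((j,)) for j in range(5)])
        lm = lambda_max(d, data.y)
        grid = default_lambda_grid(lm, n_lambda=8, min_ratio=0.05)
        path = solve_path(d, data.y, grid)
        for lam, warm_fit in zip(grid, path):
            cold = solve_l1_logistic(d, data.y, PenaltySpec.single(d, lam))
            assert np.abs(cold.coef - warm_fit.coef).max() < 1e-5

    def test_singleton_grid_is_single_solve(self, toy_design, toy_data):
        lam = 0.03
        path = solve_path(toy_design, toy_data.y, np.array([lam]))
        direct = solve_l1_logistic(
            toy_design, toy_data.y, PenaltySpec.single(toy_design, lam)
        )
        assert np.array_equal(path[0].coef, direct.coef)

    def test_rejects_ascending_grid(self, toy_design, toy_data):
        with pytest.raises(ValueError):
            solve_path(toy_design, toy_data.y, np.array([0.1, 0.2]))

    def test_shrinkage_toward_zero_as_lambda_grows(self, rng):
        data = random_binary_dataset(rng, 400, 3, prevalence=0.5)
        d = build_design(data, [CONSTANT] + [Pattern((j,)) for j in range(3)])
        lm = lambda_max(d, data.y)
        grid = default_lambda_grid(lm, n_lambda=10, min_ratio=0.01)
        path = solve_path(d, data.y, grid)
        norms = [np.abs(f.coef[f.active]).sum() for f in path]
        assert all(a <= b + 1e-8 for a, b in zip(norms, norms[1:]))


class TestPredictProb:
    def test_zero_logit_gives_half(self):
        X = np.zeros((3, 2), dtype=int)
        assert predict_prob(X, 0.0, []) == pytest.approx([0.5] * 3)

    def test_all_genes_unexpressed_uses_intercept_only(self):
        # interaction-only model: with every variable 0 the linear predictor
        # is just the intercept
        X = np.zeros((1, 10), dtype=int)
        terms = [((0, 1), 3.58), ((2, 3), 1.93), ((4, 5), 3.29),
                 ((6, 7), 3.75), ((8, 3), 2.34)]
        prob = predict_prob(X, -8.15, terms)
        assert prob[0] == pytest.approx(1 / (1 + math.exp(8.15)), rel=1e-12)

    def test_positive_coefficient_is_monotone(self):
        X0 = np.array([[0, 1]]); X1 = np.array([[1, 1]])
        terms = [((0,), 1.2)]
        assert predict_prob(X1, -0.3, terms)[0] > predict_prob(X0, -0.3, terms)[0]
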
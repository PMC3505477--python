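"""Balance-factor identities and criterion-driven penalty selection."""

import math

import numpy as np
import pytest

from plps.optimize import PenaltySpec, default_lambda_grid, lambda_max, solve_l1_logistic, solve_path
from plps.patterns import CONSTANT, BinaryDataset, Pattern, build_design
from plps.tuning import (
    balance_factor2,
    balance_factor3,
    bgacv,
    bgacv2,
    select_lambda,
    select_lambda_pair,
)
from tests.conftest import random_binary_dataset


class TestBalanceFactors:
    def test_factor2_direct_substitutions(self):
        assert balance_factor2(3, 3) == 1.0
        assert balance_factor2(4, 0) == 1.5
        assert balance_factor2(3, 1) == 1.25
        assert balance_factor2(0, 0) == 1.0

    def test_factor3_direct_substitutions(self):
        assert balance_factor3(2, 2, 2) == 1.0
        assert balance_factor3(3, 0, 0) == pytest.approx(5 / 3)
        assert balance_factor3(0, 0, 0) == 1.0

    def test_factor2_matches_formula_all_counts(self):
        for nb1 in range(21):
            for nb2 in range(21):
                expected = (1.0 if nb1 + nb2 == 0
                            else 1 + 0.5 * abs(nb1 - nb2) / (nb1 + nb2))
                assert balance_factor2(nb1, nb2) == pytest.approx(expected)
                # factor equals 1 exactly when the counts are balanced
                assert (balance_factor2(nb1, nb2) == 1.0) == (nb1 == nb2)

    def test_factor3_matches_formula_and_range(self):
        for nb1 in range(21):
            for nb2 in range(21):
                for nb3 in range(21):
                    tot = nb1 + nb2 + nb3
                    na = tot / 3
                    expected = (1.0 if tot == 0 else
                                1 + 0.5 * (abs(nb1 - na) + abs(nb2 - na)
                                           + abs(nb3 - na)) / tot)
                    got = balance_factor3(nb1, nb2, nb3)
                    assert got == pytest.approx(expected)
                    assert 1.0 <= got < 2.0
                    if tot:
                        assert (got == 1.0) == (nb1 == nb2 == nb3)

    def test_counts_scale_free(self, toy_design, toy_data):
        lam = 0.02
        fit = solve_l1_logistic(
            toy_design, toy_data.y, PenaltySpec.single(toy_design, lam)
        )
        score = bgacv2(fit, toy_design, toy_data.y)
        scaled = fit
        scaled.coef[scaled.active] *= 3.0
        rescored = bgacv2(scaled, toy_design, toy_data.y)
        assert rescored.balance == score.balance
        assert (rescored.nb1, rescored.nb2) == (score.nb1, score.nb2)


class TestBgacv:
    def test_intercept_only_closed_form(self, rng):
        n = 64
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        X = (rng.random((n, 2)) < 0.5).astype(int)
        data = BinaryDataset(y=y, X=X)
        d = build_design(data, [CONSTANT, Pattern((0,)), Pattern((1,))])
        lam = 2 * lambda_max(d, y)
        fit = solve_l1_logistic(d, y, PenaltySpec.single(d, lam))
        score = bgacv(fit, d, y)
        assert score.s == 1
        assert score.obs == pytest.approx(math.log(2), abs=1e-6)
        phi = math.log(n) / 2
        assert score.total == pytest.approx(math.log(2) + phi / n, abs=1e-6)

    def test_bgacv_at_least_gacv(self, toy_design, toy_data):
        fit = solve_l1_logistic(
            toy_design, toy_data.y, PenaltySpec.single(toy_design, 0.02)
        )
        strict = bgacv(fit, toy_design, toy_data.y)
        lax = bgacv(fit, toy_design, toy_data.y, stringent=False)
        assert strict.stringency == pytest.approx(math.log(toy_data.n) / 2)
        assert strict.total >= lax.total

    def test_balanced_counts_make_criteria_coincide(self, rng):
        # plant one main and one pair so both survive at moderate lambda
        n = 300
        X = (rng.random((n, 4)) < 0.5).astype(int)
        logit = -1 + 2.0 * X[:, 0] + 2.0 * X[:, 2] * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        data = BinaryDataset(y=y, X=X)
        pats = [CONSTANT] + [Pattern((j,)) for j in range(4)] + [Pattern((2, 3))]
        d = build_design(data, pats)
        fit = solve_l1_logistic(d, y, PenaltySpec.two(d, 0.02, 0.02))
        s2 = bgacv2(fit, d, y)
        if s2.nb1 == s2.nb2:
            assert s2.total == pytest.approx(bgacv(fit, d, y).total)
        else:
            assert s2.total > bgacv(fit, d, y).total

    def test_pure_function_of_inputs(self, toy_design, toy_data):
        fit = solve_l1_logistic(
            toy_design, toy_data.y, PenaltySpec.single(toy_design, 0.03)
        )
        a = bgacv(fit, toy_design, toy_data.y)
        b = bgacv(fit, toy_design, toy_data.y)
        assert a == b

    def test_stringent_selection_is_sparser(self, rng):
        """BGACV-selected active set nested in GACV's on most instances."""
        nested = 0
        total = 0
        for _ in range(60):
            data = random_binary_dataset(rng, 90, 8, prevalence=0.45)
            d = build_design(
                data, [CONSTANT] + [Pattern((j,)) for j in range(8)]
            )
            lm = lambda_max(d, data.y)
            if lm == 0:
                continue
            path = solve_path(d, data.y, default_lambda_grid(lm, 20, 0.01))
            strict, _ = select_lambda(path, d, data.y, bgacv)
            lax, _ = select_lambda(
                path, d, data.y,
                lambda f, de, yy: bgacv(f, de, yy, stringent=False),
            )
            total += 1
            if set(strict.active) <= set(lax.active):
                nested += 1
        assert nested / total >= 0.9


class TestSelectLambda:
    def test_singleton_path(self, toy_design, toy_data):
        fit = solve_l1_logistic(
            toy_design, toy_data.y, PenaltySpec.single(toy_design, 0.05)
        )
        best, _ = select_lambda([fit], toy_design, toy_data.y)
        assert best is fit

    def test_planted_signal_selected(self, rng):
        n = 700
        X = (rng.random((n, 10)) < 0.5).astype(int)
        logit = -1 + 1.5 * X[:, 4]
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        data = BinaryDataset(y=y, X=X)
        d = build_design(data, [CONSTANT] + [Pattern((j,)) for j in range(10)])
        lm = lambda_max(d, y)
        path = solve_path(d, y, default_lambda_grid(lm, 30, 1e-3))
        best, _ = select_lambda(path, d, y, bgacv)
        assert 4 in {d.columns[j].variables[0] for j in best.active}

    def test_ties_break_to_larger_lambda(self, toy_design, toy_data):
        lm = lambda_max(toy_design, toy_data.y)
        # both fits intercept-only => identical scores; larger lambda wins
        path = solve_path(toy_design, toy_data.y, np.array([3 * lm, 2 * lm]))
        best, _ = select_lambda(path, toy_design, toy_data.y)
        assert best.lambdas[0] == pytest.approx(3 * lm)


class TestSelectLambdaPair:
    def _grid(self, design, y, lams):
        fits = []
        for l1 in lams:
            for l2 in lams:
                fits.append(
                    solve_l1_logistic(
                        design, y, PenaltySpec.two(design, l1, l2),
                        lambdas=(l1, l2),
                    )
                )
        return fits

    def test_diagonal_reduces_to_single_penalty_selection(self, rng):
        data = random_binary_dataset(rng, 120, 5)
        pats = [CONSTANT] + [Pattern((j,)) for j in range(5)] + [Pattern((0, 1))]
        d = build_design(data, pats)
        lams = [0.08, 0.04, 0.02, 0.01]
        diag = [
            solve_l1_logistic(d, data.y, PenaltySpec.two(d, l, l), lambdas=(l, l))
            for l in lams
        ]
        best, _ = select_lambda_pair(
            diag, d, data.y, criterion=lambda f, de, yy: bgacv(f, de, yy)
        )
        path = [
            solve_l1_logistic(d, data.y, PenaltySpec.single(d, l), lambdas=(l,))
            for l in lams
        ]
        best1, _ = select_lambda(path, d, data.y, bgacv)
        assert best.lambdas[0] == best1.lambdas[0]
        assert np.abs(best.coef - best1.coef).max() < 1e-6

    def test_balancing_recovers_main_and_pair(self, rng):
        hits = 0
        for _ in range(30):
            n = 400
            X = (rng.random((n, 6)) < 0.5).astype(int)
            logit = -1 + 1.8 * X[:, 0] + 1.8 * X[:, 3] * X[:, 4]
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            data = BinaryDataset(y=y, X=X)
            pats = ([CONSTANT] + [Pattern((j,)) for j in range(6)]
                    + [Pattern((a, b)) for a in range(6) for b in range(a + 1, 6)])
            d = build_design(data, pats)
            fits = self._grid(d, data.y, [0.06, 0.03, 0.015, 0.0075])
            best, score = select_lambda_pair(fits, d, data.y, bgacv2)
            if score.nb1 >= 1 and score.nb2 >= 1:
                hits += 1
        assert hits >= 0.8 * 30

    def test_null_data_selects_nearly_empty_model(self, rng):
        small = 0
        for _ in range(25):
            data = random_binary_dataset(rng, 300, 6, prevalence=0.4)
            pats = ([CONSTANT] + [Pattern((j,)) for j in range(6)]
                    + [Pattern((a, b)) for a in range(6) for b in range(a + 1, 6)])
            d = build_design(data, pats)
            fits = self._grid(d, data.y, [0.08, 0.04, 0.02, 0.01])
            best, score = select_lambda_pair(fits, d, data.y, bgacv2)
            if best.active.size <= 2:
                small += 1
        assert small >= 0.8 * 25
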
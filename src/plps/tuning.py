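"""GACV-family tuning criteria and penalty-parameter selection.

GACV approximates leave-one-out comparative Kullback-Leibler distance for
the penalized Bernoulli likelihood; BGACV is its more stringent variant,
related to GACV the way BIC is related to AIC.  Both are computed here
with an active-set complexity surrogate: the degrees of freedom of an l1
fit are estimated by ``s``, the number of nonzero coefficients including
the intercept (the standard unbiased estimate for the lasso), and the
optimism of the training likelihood is charged per degree of freedom:

    GACV  = OBS + s/n
    BGACV = OBS + (log(n)/2) * (s/n)

where OBS is the average negative log likelihood at the fit.  These are
the AIC and BIC penalties on the per-observation likelihood scale, with
the lasso active-set size in place of the parameter count; the l1
shrinkage of the path fits provides the additional guard against
selection noise at this stage, which is deliberately permissive — the
screen is meant to pass candidates on, and the parametric refit prunes.

For *unpenalized* refits (backward elimination) the likelihood gains are
unshrunk, and a term kept as the best of ``m`` candidate patterns has its
apparent deviance inflated by about ``log m``; there each term carries the
extended-BIC charge ``log(n)/2 + 0.5 log(m_v)`` with ``m_v`` the number of
candidate patterns of its order — see ``lps_unit.parametric_score``.

(Leave-one-out optimism estimates of the form ``sum_i y_i (y_i - p_i)``
collapse to zero as a path fit saturates and would make the criterion
prefer near-saturated models; the per-degree-of-freedom charge keeps the
documented behavior — BGACV stringent and sparse, GACV more permissive.)

The aggregation stage tunes two penalties and would otherwise drift to
all-mains or all-interactions solutions; the balanced criteria multiply
BGACV by a factor that penalizes disparity between the counts of selected
mains (nb1), size-two patterns (nb2) and, for third-order models, size-three
patterns (nb3):

    BGACV2 = BGACV * (1 + 0.5 |nb1 - nb2| / (nb1 + nb2))
    BGACV3 = BGACV * (1 + 0.5 (|nb1-na| + |nb2-na| + |nb3-na|) / (nb1+nb2+nb3))

with ``na = (nb1 + nb2 + nb3)/3``.  The factor is 1 when the counts are
balanced (or all zero, taken as the balanced limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .optimize import PenalizedFit, negloglik
from .patterns import DesignMatrix

__all__ = [
    "TuningScore",
    "bgacv",
    "bgacv2",
    "bgacv3",
    "balance_factor2",
    "balance_factor3",
    "score_from_counts",
    "select_lambda",
    "select_lambda_pair",
]


@dataclass(frozen=True)
class TuningScore:
    obs: float
    optimism: float
    stringency: float  # 1 for GACV, log(n)/2 for BGACV
    balance: float  # 1 for plain (B)GACV
    total: float
    nb1: int
    nb2: int
    nb3: int
    na: float
    s: int  # active coefficients including the intercept


def _nonzero_counts(fit: PenalizedFit, design: DesignMatrix) -> tuple[int, int, int]:
    active = fit.active
    orders = design.orders[active]
    return int((orders == 1).sum()), int((orders == 2).sum()), int((orders == 3).sum())


def score_from_counts(
    obs: float,
    optimism: float,
    stringency: float,
    nb1: int,
    nb2: int,
    nb3: int = 0,
    order: int = 2,
) -> TuningScore:
    """Assemble a balanced score from precomputed parts (shared core)."""
    if order == 2:
        balance = balance_factor2(nb1, nb2)
    elif order == 3:
        balance = balance_factor3(nb1, nb2, nb3)
    else:
        balance = 1.0
    na = (nb1 + nb2 + nb3) / 3.0
    total = (obs + stringency * optimism) * balance
    return TuningScore(
        obs=obs,
        optimism=optimism,
        stringency=stringency,
        balance=balance,
        total=total,
        nb1=nb1,
        nb2=nb2,
        nb3=nb3,
        na=na,
        s=-1,
    )


def balance_factor2(nb1: int, nb2: int) -> float:
    """``1 + 0.5 |nb1 - nb2| / (nb1 + nb2)``; 1 when both counts are zero."""
    if nb1 < 0 or nb2 < 0:
        raise ValueError("counts must be non-negative")
    tot = nb1 + nb2
    if tot == 0:
        return 1.0
    return 1.0 + 0.5 * abs(nb1 - nb2) / tot


def balance_factor3(nb1: int, nb2: int, nb3: int) -> float:
    """``1 + 0.5 (|nb1-na|+|nb2-na|+|nb3-na|) / (nb1+nb2+nb3)``, na the mean."""
    if min(nb1, nb2, nb3) < 0:
        raise ValueError("counts must be non-negative")
    tot = nb1 + nb2 + nb3
    if tot == 0:
        return 1.0
    na = tot / 3.0
    return 1.0 + 0.5 * (abs(nb1 - na) + abs(nb2 - na) + abs(nb3 - na)) / tot


def _base_score(
    fit: PenalizedFit, design: DesignMatrix, y: np.ndarray, stringent: bool
) -> tuple[float, float, float, int]:
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    obs = negloglik(y, fit.linear_predictor)
    s = int(fit.active.shape[0]) + 1  # + intercept
    phi = math.log(n) / 2.0 if stringent else 1.0
    if s >= n:
        return obs, math.inf, phi, s
    return obs, s / n, phi, s


def _assemble(
    fit: PenalizedFit,
    design: DesignMatrix,
    y: np.ndarray,
    stringent: bool,
    balance_order: int | None,
) -> TuningScore:
    obs, optimism, phi, s = _base_score(fit, design, y, stringent)
    nb1, nb2, nb3 = _nonzero_counts(fit, design)
    if balance_order == 2:
        balance = balance_factor2(nb1, nb2)
    elif balance_order == 3:
        balance = balance_factor3(nb1, nb2, nb3)
    else:
        balance = 1.0
    total = math.inf if math.isinf(optimism) else (obs + phi * optimism) * balance
    return TuningScore(
        obs=obs,
        optimism=optimism,
        stringency=phi,
        balance=balance,
        total=total,
        nb1=nb1,
        nb2=nb2,
        nb3=nb3,
        na=(nb1 + nb2 + nb3) / 3.0,
        s=s,
    )


def bgacv(
    fit: PenalizedFit, design: DesignMatrix, y: np.ndarray, stringent: bool = True
) -> TuningScore:
    """BGACV of a penalized fit (``stringent=False`` gives plain GACV)."""
    return _assemble(fit, design, y, stringent, balance_order=None)


def bgacv2(fit: PenalizedFit, design: DesignMatrix, y: np.ndarray) -> TuningScore:
    """BGACV times the main/size-two balance factor."""
    return _assemble(fit, design, y, True, balance_order=2)


def bgacv3(fit: PenalizedFit, design: DesignMatrix, y: np.ndarray) -> TuningScore:
    """BGACV times the three-way balance factor over pattern orders."""
    return _assemble(fit, design, y, True, balance_order=3)


def select_lambda(
    path: list[PenalizedFit],
    design: DesignMatrix,
    y: np.ndarray,
    criterion=bgacv,
) -> tuple[PenalizedFit, TuningScore]:
    """Fit along the path minimizing the criterion; ties go to larger lambda.

    The path is ordered by descending penalty, so keeping the first strict
    minimum prefers the sparser model on ties.  If every score is infinite
    the first (most penalized, intercept-only) fit is returned.
    """
    if not path:
        raise ValueError("empty path")
    best_fit: PenalizedFit | None = None
    best_score: TuningScore | None = None
    for fit in path:
        if "predictor-cap" in fit.flags:
            # (near-)separated fit: the df-based criterion is not valid
            continue
        score = criterion(fit, design, y)
        if best_score is None or score.total < best_score.total - 1e-12:
            best_fit, best_score = fit, score
    if best_fit is None or best_score is None or math.isinf(best_score.total):
        return path[0], criterion(path[0], design, y)
    return best_fit, best_score


def select_lambda_pair(
    grid_fits: list[PenalizedFit],
    design: DesignMatrix,
    y: np.ndarray,
    criterion=bgacv2,
) -> tuple[PenalizedFit, TuningScore]:
    """Minimizer of a balanced criterion on a two-penalty grid.

    Ties break toward larger ``lambda1 + lambda2``, then larger
    ``lambda2``; each fit must carry its ``(lambda1, lambda2)`` in
    ``fit.lambdas``.
    """
    if not grid_fits:
        raise ValueError("empty grid")
    ranked = sorted(
        range(len(grid_fits)),
        key=lambda i: (-sum(grid_fits[i].lambdas), -grid_fits[i].lambdas[-1]),
    )
    best_fit: PenalizedFit | None = None
    best_score: TuningScore | None = None
    for i in ranked:
        fit = grid_fits[i]
        if "predictor-cap" in fit.flags:
            continue
        score = criterion(fit, design, y)
        if best_score is None or score.total < best_score.total - 1e-12:
            best_fit, best_score = fit, score
    if best_fit is None or best_score is None or math.isinf(best_score.total):
        return grid_fits[0], criterion(grid_fits[0], design, y)
    return best_fit, best_score
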
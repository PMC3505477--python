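"""Penalized Bernoulli likelihood objectives and the l1 solver.

The model is ``f(x) = mu + sum_l c_l B_l(x)`` over binary pattern columns,
fitted by minimizing

    (1/n) sum_i [ -y_i f_i + log(1 + exp(f_i)) ]  +  sum_l w_l |c_l|,

where ``w_l`` are per-column penalty weights.  The constant column always
has weight 0, so the intercept is never penalized.  A single penalty
parameter uses weight ``lambda`` on every non-constant column; the
aggregation stage uses ``lambda1`` on main-effect columns and ``lambda2``
on interaction columns.  Per-column weights make both cases one solver.

The solver is coordinate-wise proximal Newton descent with an active-set
outer loop: a full-gradient Karush-Kuhn-Tucker (KKT) screen adds violating
columns, and cyclic coordinate updates run over the active set only.
Binary columns are exploited throughout — a column's gradient is a sum of
residuals over its supporting rows, taken straight from the sparse
column-index structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

from .patterns import DesignMatrix

logger = logging.getLogger("plps")

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "SolverError",
    "negloglik",
    "objective",
    "lambda_max",
    "lambda_max_blocks",
    "solve_l1_logistic",
    "solve_path",
    "default_lambda_grid",
    "predict_prob",
]

#: KKT stationarity tolerance (absolute, on the gradient scale).
KKT_TOL = 1e-6
#: Maximum coordinate sweeps per solve.
MAX_SWEEPS = 10_000
#: Linear predictors are capped at this magnitude in unpenalized refits.
PREDICTOR_CAP = 30.0


class SolverError(RuntimeError):
    """Raised when the solver fails to converge; carries the last iterate."""

    def __init__(self, message: str, last_fit: "PenalizedFit | None" = None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class PenaltySpec:
    """Non-negative per-column penalty weights; constant column weight 0."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.ascontiguousarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("penalty weights must be non-negative")

    @classmethod
    def single(cls, design: DesignMatrix, lam: float) -> "PenaltySpec":
        w = np.full(design.n_columns, float(lam))
        w[design.orders == 0] = 0.0
        return cls(w)

    @classmethod
    def two(cls, design: DesignMatrix, lam1: float, lam2: float) -> "PenaltySpec":
        """lam1 on main-effect columns, lam2 on interaction columns."""
        w = np.where(design.orders == 1, float(lam1), float(lam2))
        w[design.orders == 0] = 0.0
        return cls(w)


@dataclass
class PenalizedFit:
    """One penalized fit: coefficients aligned to the design columns."""

    coef: np.ndarray  # includes the constant column's entry (the intercept)
    linear_predictor: np.ndarray
    penalty: PenaltySpec
    objective: float
    converged: bool
    n_sweeps: int
    constant_index: int
    lambdas: tuple[float, ...] = ()
    flags: list[str] = field(default_factory=list)

    @property
    def intercept(self) -> float:
        return float(self.coef[self.constant_index])

    @property
    def active(self) -> np.ndarray:
        """Indices of non-constant columns with nonzero coefficient."""
        nz = np.flatnonzero(self.coef != 0.0)
        return nz[nz != self.constant_index]

    @property
    def probabilities(self) -> np.ndarray:
        return _sigmoid(self.linear_predictor)


def _sigmoid(f: np.ndarray) -> np.ndarray:
    out = np.empty_like(f, dtype=np.float64)
    pos = f >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-f[pos]))
    ef = np.exp(f[~pos])
    out[~pos] = ef / (1.0 + ef)
    return out


def negloglik(y: np.ndarray, f: np.ndarray) -> float:
    """Average Bernoulli negative log likelihood at linear predictor f.

    ``(1/n) sum_i [-y_i f_i + log(1 + exp(f_i))]``, evaluated stably via
    ``log(1+exp(f)) = max(f, 0) + log1p(exp(-|f|))``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    f = np.asarray(f, dtype=np.float64).ravel()
    if y.shape != f.shape:
        raise ValueError("y and f must have the same length")
    log1pexp = np.maximum(f, 0.0) + np.log1p(np.exp(-np.abs(f)))
    return float(np.mean(-y * f + log1pexp))


def objective(
    coef: np.ndarray, design: DesignMatrix, y: np.ndarray, penalty: PenaltySpec
) -> float:
    """Penalized objective: negloglik + sum_l w_l |c_l|."""
    f = design.values @ coef
    return negloglik(y, f) + float(penalty.weights @ np.abs(coef))


def lambda_max(design: DesignMatrix, y: np.ndarray) -> float:
    """Smallest single penalty at which the intercept-only model is optimal.

    The zero solution (with the intercept at ``logit(mean(y))``) is
    stationary iff every penalized column's score ``|(1/n) B_l'(y - ybar)|``
    is at most its weight; the maximum of those scores is lambda_max.
    """
    scores = _block_scores(design, y)
    mask = design.orders > 0
    return float(scores[mask].max()) if mask.any() else 0.0


def lambda_max_blocks(design: DesignMatrix, y: np.ndarray) -> tuple[float, float]:
    """(lambda1_max, lambda2_max) for the main / interaction blocks."""
    scores = _block_scores(design, y)
    mains = design.orders == 1
    inter = design.orders >= 2
    l1 = float(scores[mains].max()) if mains.any() else 0.0
    l2 = float(scores[inter].max()) if inter.any() else 0.0
    return l1, l2


def _block_scores(design: DesignMatrix, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return np.zeros(design.n_columns)
    r = y - ybar
    return np.abs(design.values.T @ r) / y.shape[0]


@njit(cache=False)
def _cd_sweeps(indptr, indices, y, w, c, f, active, n, tol, max_sweeps):
    """Cyclic coordinate-wise proximal Newton sweeps over ``active`` columns.

    Exploits binary columns: for column j with support rows I,
    grad_j = (1/n) sum_{i in I} (p_i - y_i) and the curvature is
    (1/n) sum_{i in I} p_i (1 - p_i).  Returns (sweeps_used, converged).
    """
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for t in range(active.shape[0]):
            j = active[t]
            lo, hi = indptr[j], indptr[j + 1]
            if hi == lo:
                c[j] = 0.0
                continue
            g = 0.0
            h = 0.0
            for idx in range(lo, hi):
                i = indices[idx]
                fi = f[i]
                if fi >= 0.0:
                    pi = 1.0 / (1.0 + np.exp(-fi))
                else:
                    e = np.exp(fi)
                    pi = e / (1.0 + e)
                g += pi - y[i]
                h += pi * (1.0 - pi)
            g /= n
            h /= n
            if h < 1e-10:
                h = 1e-10
            z = c[j] * h - g
            wj = w[j]
            if z > wj:
                cnew = (z - wj) / h
            elif z < -wj:
                cnew = (z + wj) / h
            else:
                cnew = 0.0
            delta = cnew - c[j]
            if delta > 5.0:
                delta = 5.0
                cnew = c[j] + delta
            elif delta < -5.0:
                delta = -5.0
                cnew = c[j] + delta
            if delta != 0.0:
                c[j] = cnew
                for idx in range(lo, hi):
                    f[indices[idx]] += delta
                ad = abs(delta)
                if ad > max_delta:
                    max_delta = ad
        if max_delta <= tol:
            return sweep + 1, True
    return max_sweeps, False


def _kkt_residuals(g: np.ndarray, w: np.ndarray, c: np.ndarray) -> np.ndarray:
    r = np.maximum(np.abs(g) - w, 0.0)
    nz = c != 0.0
    r[nz] = np.abs(g[nz] + w[nz] * np.sign(c[nz]))
    return r


def solve_l1_logistic(
    design: DesignMatrix,
    y: np.ndarray,
    penalty: PenaltySpec,
    warm_start: np.ndarray | None = None,
    tol: float = KKT_TOL,
    max_sweeps: int = MAX_SWEEPS,
    lambdas: tuple[float, ...] = (),
) -> PenalizedFit:
    """Minimize the penalized objective to KKT stationarity ``tol``.

    On the active set the absolute stationarity residual
    ``|grad_j + w_j sign(c_j)|`` is driven below ``tol``; off it the
    subgradient bound ``|grad_j| <= w_j + tol`` holds.  The intercept is
    never penalized.
    """
    y = np.ascontiguousarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    ncols = design.n_columns
    if penalty.weights.shape[0] != ncols:
        raise ValueError("penalty weights do not match design columns")
    A: sp.csc_matrix = design.values
    const = design.constant_index
    if warm_start is not None:
        c = np.array(warm_start, dtype=np.float64).copy()
        if c.shape[0] != ncols:
            raise ValueError("warm start does not match design columns")
    else:
        c = np.zeros(ncols)
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        # Degenerate response: likelihood has no interior optimum.
        c[:] = 0.0
        c[const] = PREDICTOR_CAP if ybar == 1.0 else -PREDICTOR_CAP
        f = A @ c
        return PenalizedFit(
            coef=c,
            linear_predictor=f,
            penalty=penalty,
            objective=objective(c, design, y, penalty),
            converged=True,
            n_sweeps=0,
            constant_index=const,
            lambdas=lambdas,
            flags=["degenerate-response"],
        )
    f = np.ascontiguousarray(A @ c)
    indptr = A.indptr
    indices = A.indices
    w = penalty.weights
    total_sweeps = 0
    inner_tol = min(tol, 1e-7)
    converged = False
    flags: list[str] = []
    active_mask = c != 0.0
    active_mask[const] = True
    for outer in range(200):
        active = np.flatnonzero(active_mask).astype(np.int64)
        # chunked so the predictor-cap / KKT checks run regularly even
        # when the inner loop is converging slowly
        sweeps, inner_done = _cd_sweeps(
            indptr, indices, y, w, c, f, active, float(n), inner_tol,
            min(500, max_sweeps - total_sweeps),
        )
        total_sweeps += sweeps
        if np.abs(f).max() > PREDICTOR_CAP:
            # The fit is running off to a (near-)separating solution; any
            # optimism/df-based criterion is meaningless there, so the
            # capped iterate is returned flagged instead of polished.
            flags.append("predictor-cap")
            converged = True
            break
        p = _sigmoid(f)
        g = (A.T @ (p - y)) / n
        resid = _kkt_residuals(g, w, c)
        resid[const] = abs(g[const])
        if resid.max() <= tol:
            converged = True
            break
        if total_sweeps >= max_sweeps:
            break
        new_violators = (~active_mask) & (resid > tol)
        if new_violators.any():
            active_mask |= new_violators
        elif inner_done:
            # Active set is right but not yet tight enough: tighten inner tol.
            inner_tol *= 0.1
        # Keep the active set lean: drop columns that went (and stayed) zero.
        active_mask &= (c != 0.0) | new_violators
        active_mask[const] = True
    fit = PenalizedFit(
        coef=c,
        linear_predictor=f,
        penalty=penalty,
        objective=negloglik(y, f) + float(w @ np.abs(c)),
        converged=converged,
        n_sweeps=total_sweeps,
        constant_index=const,
        lambdas=lambdas,
        flags=flags,
    )
    if not converged:
        raise SolverError(
            f"coordinate descent did not reach tol={tol} in {max_sweeps} sweeps",
            last_fit=fit,
        )
    return fit


def default_lambda_grid(
    lam_max: float, n_lambda: int = 50, min_ratio: float = 1e-3
) -> np.ndarray:
    """Descending geometric grid from lambda_max down 3 decades."""
    if lam_max <= 0:
        return np.array([0.0])
    return lam_max * np.geomspace(1.0, min_ratio, n_lambda)


def solve_path(
    design: DesignMatrix,
    y: np.ndarray,
    lam_grid: np.ndarray,
    tol: float = KKT_TOL,
    max_sweeps: int = MAX_SWEEPS,
    stop=None,
) -> list[PenalizedFit]:
    """One fit per penalty value, warm-started down the descending grid.

    ``stop``, if given, is called with each completed fit; a truthy return
    truncates the path after that fit (used by the screening stage to skip
    the saturated small-penalty tail that no criterion can select).
    """
    lam_grid = np.asarray(lam_grid, dtype=np.float64)
    if (np.diff(lam_grid) > 0).any():
        raise ValueError("lambda grid must be sorted descending")
    fits: list[PenalizedFit] = []
    warm = None
    for i, lam in enumerate(lam_grid):
        penalty = PenaltySpec.single(design, lam)
        try:
            fit = solve_l1_logistic(
                design, y, penalty, warm_start=warm, tol=tol,
                max_sweeps=max_sweeps, lambdas=(float(lam),),
            )
        except SolverError as err:
            raise SolverError(f"path failed at grid index {i} (lambda={lam})",
                              last_fit=err.last_fit) from err
        fits.append(fit)
        warm = fit.coef
        logger.debug(
            "path %d/%d: lambda=%.5g active=%d sweeps=%d obj=%.6f",
            i + 1, lam_grid.shape[0], lam, fit.active.shape[0],
            fit.n_sweeps, fit.objective,
        )
        if stop is not None and stop(fit):
            break
    return fits


def predict_prob(
    X: np.ndarray, intercept: float, terms: list[tuple[tuple[int, ...], float]]
) -> np.ndarray:
    """Per-row probability 1/(1+exp(-f)) of a fitted pattern model.

    ``terms`` holds (variable-index tuple, coefficient) pairs; each pattern
    contributes its coefficient when all of its variables equal 1.
    """
    X = np.asarray(X)
    f = np.full(X.shape[0], float(intercept))
    for variables, coef in terms:
        if variables:
            v = X[:, variables[0]].astype(np.float64)
            for j in variables[1:]:
                v = v * X[:, j]
            f += coef * v
        else:
            f += coef
    return _sigmoid(f)
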
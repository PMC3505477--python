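"""One complete LASSO-Patternsearch pass.

The LPS template: (i) fit the l1-penalized logistic model over the pattern
basis along a penalty path and keep the active set of the BGACV-selected
fit; (ii) refit an unpenalized logistic regression on the survivors;
(iii) greedily delete terms by backward elimination under BGACV, refitting
the maximum-likelihood model after each deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optimize import (
    PREDICTOR_CAP,
    _sigmoid,
    default_lambda_grid,
    lambda_max,
    negloglik,
    solve_path,
)
from .patterns import CONSTANT, BinaryDataset, DesignMatrix, Pattern, build_design
from .tuning import TuningScore, bgacv, select_lambda

__all__ = [
    "SelectedModel",
    "screen_lasso",
    "fit_parametric",
    "backward_eliminate",
    "run_lps",
]


@dataclass
class SelectedModel:
    """Final pattern model with unpenalized coefficients."""

    patterns: list[Pattern]
    intercept: float
    coefficients: np.ndarray  # aligned with patterns
    std_errors: np.ndarray | None = None
    provenance: str = ""
    criterion: float = math.nan
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.patterns)) != len(self.patterns):
            raise ValueError("duplicate patterns in model")
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape[0] != len(self.patterns):
            raise ValueError("coefficient length does not match patterns")

    @property
    def n_terms(self) -> int:
        return len(self.patterns)

    @property
    def order(self) -> int:
        return max((pat.order for pat in self.patterns), default=0)

    def variables(self) -> set[int]:
        out: set[int] = set()
        for pat in self.patterns:
            out.update(pat.variables)
        return out

    def terms(self) -> list[tuple[tuple[int, ...], float]]:
        return [
            (pat.variables, float(c))
            for pat, c in zip(self.patterns, self.coefficients)
        ]

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        from .optimize import predict_prob

        return predict_prob(X, self.intercept, self.terms())

    def summary(self) -> str:
        rows = [f"intercept  {self.intercept:+.4f}"]
        for i, (pat, c) in enumerate(zip(self.patterns, self.coefficients)):
            se = ""
            if self.std_errors is not None and np.isfinite(self.std_errors[i]):
                se = f"  (se {self.std_errors[i]:.4f})"
            rows.append(f"{pat.label():<20s} {c:+.4f}{se}")
        return "\n".join(rows)


def screen_lasso(
    design: DesignMatrix,
    y: np.ndarray,
    criterion=bgacv,
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
) -> list[Pattern]:
    """Active patterns of the criterion-selected fit on the penalty path.

    The path is cut short once no later fit can beat the best criterion
    value seen so far: every score is bounded below by
    ``stringency * balance * s/n`` (the observed likelihood term is
    non-negative), so once that bound exceeds the running minimum the
    saturating tail of the path cannot contain the selected fit.
    """
    lam_max = lambda_max(design, y)
    grid = default_lambda_grid(lam_max, n_lambda, lambda_min_ratio)
    if grid[0] == 0.0:
        return []
    n = np.asarray(y).shape[0]
    best_total = math.inf

    def saturated(fit) -> bool:
        nonlocal best_total
        if "predictor-cap" in fit.flags:
            return True
        score = criterion(fit, design, y)
        if score.total < best_total:
            best_total = score.total
        s = fit.active.shape[0] + 1
        return s >= n or score.stringency * score.balance * s / n >= best_total

    path = solve_path(design, y, grid, stop=saturated)
    best, _ = select_lambda(path, design, y, criterion)
    return [design.columns[j] for j in best.active]


def _newton_logistic(
    A: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Unpenalized logistic MLE by damped Newton iterations.

    Returns (coefficients, covariance diagonal estimate, flags).  If the
    linear predictor magnitude exceeds PREDICTOR_CAP the data are treated
    as quasi-separated: iteration stops at the capped iterate with a flag.
    """
    n, m = A.shape
    c = np.zeros(m)
    flags: list[str] = []
    f = A @ c
    nll = negloglik(y, f)
    cov_diag = np.full(m, np.nan)
    for _ in range(max_iter):
        p = _sigmoid(f)
        grad = A.T @ (p - y) / n
        if np.abs(grad).max() <= tol:
            break
        W = p * (1.0 - p)
        H = (A.T * W) @ A / n
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(m), grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(H, grad, rcond=None)
            if "singular-hessian" not in flags:
                flags.append("singular-hessian")
        # Backtracking line search on the likelihood.
        t = 1.0
        for _ in range(40):
            c_new = c - t * step
            f_new = A @ c_new
            nll_new = negloglik(y, f_new)
            if nll_new <= nll + 1e-14:
                break
            t *= 0.5
        else:
            break
        if np.abs(f_new).max() > PREDICTOR_CAP:
            if "quasi-separation" not in flags:
                flags.append("quasi-separation")
            c, f, nll = c_new, f_new, nll_new
            break
        c, f, nll = c_new, f_new, nll_new
    if (np.abs(f).max() > PREDICTOR_CAP or (m and np.abs(c).max() > PREDICTOR_CAP)) \
            and "quasi-separation" not in flags:
        flags.append("quasi-separation")
    p = _sigmoid(f)
    W = p * (1.0 - p)
    H = (A.T * W) @ A
    try:
        cov = np.linalg.inv(H)
        cov_diag = np.diag(cov).copy()
        cov_diag[cov_diag < 0] = np.nan
    except np.linalg.LinAlgError:
        pass
    return c, cov_diag, flags


def fit_parametric(
    data: BinaryDataset,
    patterns: list[Pattern],
    provenance: str = "",
    pools: dict[int, int] | None = None,
) -> SelectedModel:
    """Maximum-likelihood logistic fit on a pattern design (no penalty).

    ``pools`` maps a pattern order to the number of candidate patterns of
    that order the model was searched over; it only affects the stored
    BGACV criterion value (see ``parametric_score``).
    """
    patterns = [pat for pat in patterns if not pat.is_constant]
    if len(set(patterns)) != len(patterns):
        raise ValueError("duplicate patterns")
    if len(patterns) >= data.n:
        raise ValueError("more patterns than subjects; cannot refit unpenalized")
    design = build_design(data, [CONSTANT] + patterns)
    A = np.asarray(design.values.todense(), dtype=np.float64)
    c, cov_diag, flags = _newton_logistic(A, data.y)
    se = np.sqrt(cov_diag[1:]) if len(patterns) else np.empty(0)
    model = SelectedModel(
        patterns=patterns,
        intercept=float(c[0]),
        coefficients=c[1:],
        std_errors=se,
        provenance=provenance,
        flags=flags,
    )
    model.criterion = parametric_score(data.y, A @ c, patterns, pools).total
    return model


def parametric_score(
    y: np.ndarray,
    f: np.ndarray,
    patterns: list[Pattern] | int,
    pools: dict[int, int] | None = None,
) -> TuningScore:
    """BGACV of an unpenalized refit, with per-term search-pool charges.

    Each selected term carries the extended-BIC cost
    ``(log n)/2 + 0.5 log(m_v)`` where ``m_v`` is the number of candidate
    patterns of the term's order in the pool it was screened from (the
    intercept costs ``(log n)/2`` alone).  The pool share matters: an
    interaction picked as the best of tens of thousands of candidate pairs
    has its apparent deviance inflated by about ``log m``, far more than a
    main effect picked among a few hundred variables, and charging both
    equally lets spurious best-of-pool interactions displace genuine main
    effects.  ``patterns`` may be an integer term count when no pattern
    list applies (pools are then ignored beyond their default).
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = y.shape[0]
    obs = negloglik(y, f)
    half_log_n = math.log(n) / 2.0
    if isinstance(patterns, int):
        orders = [1] * patterns
    else:
        orders = [pat.order for pat in patterns]
    s = len(orders) + 1
    if s >= n:
        return TuningScore(obs, math.inf, 1.0, 1.0, math.inf, 0, 0, 0, 0.0, s)
    charge = half_log_n  # intercept
    for order in orders:
        m = (pools or {}).get(order, 1)
        charge += half_log_n + 0.5 * math.log(max(m, 1))
    optimism = charge / n
    nb = [orders.count(1), orders.count(2), orders.count(3)]
    return TuningScore(
        obs=obs,
        optimism=optimism,
        stringency=1.0,
        balance=1.0,
        total=obs + optimism,
        nb1=nb[0],
        nb2=nb[1],
        nb3=nb[2],
        na=sum(nb) / 3.0,
        s=s,
    )


def candidate_pools(orders: np.ndarray) -> dict[int, int]:
    """Per-order candidate counts of a design (excluding the constant)."""
    orders = np.asarray(orders)
    return {
        int(v): int((orders == v).sum())
        for v in np.unique(orders)
        if v > 0
    }


def _elimination_order(patterns: list[Pattern]) -> list[int]:
    """Preference order for tie-breaks: higher order first, then later lex."""
    return sorted(
        range(len(patterns)),
        key=lambda i: (
            -patterns[i].order,
            tuple(-v for v in patterns[i].variables),
        ),
    )


def backward_eliminate(
    model: SelectedModel,
    data: BinaryDataset,
    tol: float = 1e-12,
    pools: dict[int, int] | None = None,
) -> SelectedModel:
    """Greedy backward elimination under BGACV with full refits.

    Two deterministic descent paths are followed and the lower-scoring end
    point is returned:

    * *best-first*: repeatedly delete the single term whose removal gives
      the lowest criterion (ties prefer the higher-order term, then the
      lexicographically later pattern);
    * *interactions-first*: in the same preference order, take the first
      deletion that lowers the criterion.

    The two paths cover complementary traps of greedy deletion.  When a
    true interaction sits beside its (null) constituent mains, best-first
    correctly strips the redundant mains.  When a true main effect has
    been paired with noise partners, the spurious pairs absorb its signal
    and best-first deletes the main — locking the pairs in — while
    interactions-first removes the pairs and keeps the main.  Whichever
    end point the criterion itself prefers is the answer; both stop when
    no single deletion lowers the score.
    """
    current = model
    if math.isnan(current.criterion):
        current = fit_parametric(data, current.patterns, current.provenance,
                                 pools)

    def descend(best_first: bool) -> SelectedModel:
        state = current
        improved = True
        while state.patterns and improved:
            improved = False
            chosen: SelectedModel | None = None
            for i in _elimination_order(state.patterns):
                reduced = [p for j, p in enumerate(state.patterns) if j != i]
                cand = fit_parametric(data, reduced, state.provenance,
                                      pools)
                if cand.criterion < state.criterion - tol and (
                    chosen is None or cand.criterion < chosen.criterion - tol
                ):
                    chosen = cand
                    if not best_first:
                        break
            if chosen is not None:
                state = chosen
                improved = True
        return state

    a = descend(best_first=True)
    b = descend(best_first=False)
    if abs(a.criterion - b.criterion) <= tol:
        # tie: prefer the smaller, lower-order model
        key = lambda m: (m.n_terms, m.order, sorted(m.patterns))  # noqa: E731
        return min((a, b), key=key)
    return a if a.criterion < b.criterion else b


def run_lps(
    data: BinaryDataset,
    patterns: list[Pattern],
    criterion=bgacv,
    provenance: str = "",
    n_lambda: int = 50,
    lambda_min_ratio: float = 1e-3,
) -> SelectedModel:
    """screen_lasso -> fit_parametric -> backward_eliminate."""
    design = build_design(data, patterns)
    pools = candidate_pools(design.orders)
    survivors = screen_lasso(design, data.y, criterion, n_lambda, lambda_min_ratio)
    if not survivors:
        return fit_parametric(data, [], provenance, pools)
    # The unpenalized refit requires fewer terms than subjects; if the
    # screen kept too many, keep the largest-magnitude penalized effects.
    if len(survivors) >= data.n:
        survivors = survivors[: data.n - 1]
    model = fit_parametric(data, survivors, provenance, pools)
    return backward_eliminate(model, data, pools=pools)
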
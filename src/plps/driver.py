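"""The two-stage pLPS / pLPS3 pipeline.

Stage 1 (screening) runs one LPS pass per subproblem; the subproblems are
pure functions of the data slice and the subproblem spec, so they run serially or
on any pool — results are merged as an order-independent set union.
Stage 2 (aggregation) takes the unique variables appearing in any
surviving pattern, builds the full pattern basis on just those variables,
fits the two-penalty problem over a (lambda1, lambda2) grid selected by
BGACV2 (order 2) or BGACV3 (order 3), and finishes with the parametric
refit and backward elimination.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .lps_unit import (
    SelectedModel,
    backward_eliminate,
    candidate_pools,
    fit_parametric,
    run_lps,
)
from .optimize import PenaltySpec, SolverError, lambda_max_blocks, solve_l1_logistic
from .patterns import (
    CONSTANT,
    BinaryDataset,
    DesignMatrix,
    Pattern,
    PartitionScheme,
    SubproblemSpec,
    build_design,
    enumerate_subproblems,
    make_partition,
    patterns_for_subproblem,
)
from .tuning import bgacv, bgacv2, bgacv3, select_lambda_pair

logger = logging.getLogger("plps")

__all__ = [
    "RunConfig",
    "ScreeningResult",
    "run_screening_stage",
    "aggregate_variables",
    "run_aggregation_stage",
    "run_plps",
    "read_survivors",
    "write_survivors",
]


@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs of a pLPS run.

    ``g`` is the partition size (defaults to 200 for order 2 and 35 for
    order 3, sized for a commodity machine); ``order`` is the highest
    pattern order ``q``.  The penalty path uses ``n_lambda`` geometric
    points spanning ``lambda_min_ratio`` decades below lambda_max; the
    aggregation grid has ``grid2`` points per axis spanning
    ``grid2_min_ratio`` below each block's lambda_max.
    """

    order: int = 2
    g: int | None = None
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3
    grid2: int = 12
    grid2_min_ratio: float = 1e-3
    workers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.order not in (2, 3):
            raise ValueError("order must be 2 or 3")
        if self.g is not None and self.g < 1:
            raise ValueError("g must be >= 1")

    @property
    def group_size(self) -> int:
        return self.g if self.g is not None else (200 if self.order == 2 else 35)


@dataclass
class ScreeningResult:
    models: dict[str, SelectedModel]  # keyed by subproblem id
    survivors: set[Pattern]
    p_star: set[int]

    @property
    def n_subproblems(self) -> int:
        return len(self.models)


def _screen_one(
    data: BinaryDataset,
    spec: SubproblemSpec,
    scheme: PartitionScheme,
    config: RunConfig,
) -> tuple[str, SelectedModel]:
    pats = patterns_for_subproblem(spec, scheme)
    logger.info("subproblem %s: %d patterns", spec.id(), len(pats))
    model = run_lps(
        data,
        pats,
        criterion=bgacv,
        provenance=spec.id(),
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    logger.info("subproblem %s: %d terms survive", spec.id(), model.n_terms)
    return spec.id(), model


def _batched_schedule(specs: list[SubproblemSpec]) -> list[list[SubproblemSpec]]:
    """Group pairs of within-partition subproblems into one task.

    A within subproblem has about half the patterns of a cross-pair one,
    so batching two of them balances task sizes.  Scheduling only: the
    merged results are identical to running each spec alone.
    """
    singles = [s for s in specs if not _is_small(s)]
    smalls = [s for s in specs if _is_small(s)]
    tasks: list[list[SubproblemSpec]] = [[s] for s in singles]
    for i in range(0, len(smalls), 2):
        tasks.append(smalls[i : i + 2])
    return tasks


def _is_small(spec: SubproblemSpec) -> bool:
    return spec.order == 2 and spec.type_tag == "within"


def run_screening_stage(data: BinaryDataset, config: RunConfig) -> ScreeningResult:
    """Run every screening subproblem and union the surviving patterns."""
    scheme = make_partition(data.p, config.group_size)
    specs = enumerate_subproblems(scheme, config.order)
    tasks = _batched_schedule(specs)
    logger.info(
        "screening: k=%d partitions, %d subproblems in %d tasks",
        scheme.k, len(specs), len(tasks),
    )

    def run_task(task: list[SubproblemSpec]) -> list[tuple[str, SelectedModel]]:
        return [_screen_one(data, spec, scheme, config) for spec in task]

    if config.workers > 1:
        chunks = Parallel(n_jobs=config.workers, backend="threading")(
            delayed(run_task)(task) for task in tasks
        )
    else:
        chunks = [run_task(task) for task in tasks]
    models = dict(itertools.chain.from_iterable(chunks))
    survivors: set[Pattern] = set()
    for model in models.values():
        survivors.update(model.patterns)
    return ScreeningResult(
        models=models, survivors=survivors, p_star=aggregate_variables(survivors)
    )


def aggregate_variables(survivors: set[Pattern]) -> set[int]:
    """p*: unique variables appearing in any surviving pattern."""
    out: set[int] = set()
    for pat in survivors:
        out.update(pat.variables)
    return out


def _aggregation_patterns(p_star: set[int], order: int) -> list[Pattern]:
    """Constant + mains + all interactions up to ``order`` on p*."""
    variables = sorted(p_star)
    pats: list[Pattern] = [CONSTANT]
    for nu in range(1, order + 1):
        pats.extend(Pattern(t) for t in itertools.combinations(variables, nu))
    return pats


def _two_penalty_grid(
    design: DesignMatrix, y: np.ndarray, config: RunConfig, criterion
) -> list:
    """Fits over a geometric (lambda1, lambda2) grid, warm-started per row.

    Each row holds lambda1 fixed and descends lambda2.  A row is cut short
    once no denser fit can beat the best criterion value seen so far: the
    balanced score is bounded below by ``stringency * s/n`` (the observed
    term is non-negative and the balance factor is >= 1), so the
    near-saturated corner of the grid — where the fits are also the most
    expensive — cannot contain the selected model.  A grid point whose
    solve does not converge is skipped with a warning.
    """
    l1max, l2max = lambda_max_blocks(design, y)
    l1max = max(l1max, 1e-12)
    l2max = max(l2max, 1e-12)
    g1 = l1max * np.geomspace(1.0, config.grid2_min_ratio, config.grid2)
    g2 = l2max * np.geomspace(1.0, config.grid2_min_ratio, config.grid2)
    n = y.shape[0]
    fits = []
    best_total = math.inf
    for lam1 in g1:
        warm = None
        for lam2 in g2:
            penalty = PenaltySpec.two(design, lam1, lam2)
            try:
                fit = solve_l1_logistic(
                    design, y, penalty, warm_start=warm,
                    lambdas=(float(lam1), float(lam2)),
                )
            except SolverError:
                # Non-convergence happens in the near-saturated corner;
                # deeper lambda2 on this row would only be harder.
                logger.warning(
                    "aggregation grid point (%.3g, %.3g) did not converge; "
                    "row truncated", lam1, lam2,
                )
                break
            if "predictor-cap" in fit.flags:
                # (near-)separated; deeper lambda2 only more so
                break
            fits.append(fit)
            warm = fit.coef
            score = criterion(fit, design, y)
            if score.total < best_total:
                best_total = score.total
            s = fit.active.shape[0] + 1
            if s >= n or score.stringency * s / n >= best_total:
                break
    if not fits:
        raise SolverError("no aggregation grid point converged")
    return fits


def run_aggregation_stage(
    data: BinaryDataset, p_star: set[int], config: RunConfig
) -> SelectedModel:
    """Two-penalty LPS on the surviving variables, then refit + elimination."""
    if not p_star:
        logger.info("aggregation: empty p*, intercept-only model")
        return fit_parametric(data, [], provenance="aggregation")
    if len(p_star) >= data.n:
        logger.warning(
            "aggregation: %d surviving variables with only %d subjects",
            len(p_star), data.n,
        )
    pats = _aggregation_patterns(p_star, config.order)
    design = build_design(data, pats)
    logger.info("aggregation: |p*|=%d, %d patterns", len(p_star), len(pats))
    criterion = bgacv2 if config.order == 2 else bgacv3
    fits = _two_penalty_grid(design, data.y, config, criterion)
    best, score = select_lambda_pair(fits, design, data.y, criterion)
    logger.info(
        "aggregation: selected (lambda1, lambda2)=%s, %d active, score %.6f",
        best.lambdas, best.active.shape[0], score.total,
    )
    survivors = [design.columns[j] for j in best.active]
    if len(survivors) >= data.n:
        survivors = survivors[: data.n - 1]
    pools = candidate_pools(design.orders)
    model = fit_parametric(data, survivors, provenance="aggregation",
                           pools=pools)
    return backward_eliminate(model, data, pools=pools)


def run_plps(data: BinaryDataset, config: RunConfig) -> SelectedModel:
    """Full pipeline: screening -> variable aggregation -> aggregation LPS."""
    screening = run_screening_stage(data, config)
    logger.info(
        "screening done: %d surviving patterns, |p*|=%d",
        len(screening.survivors), len(screening.p_star),
    )
    return run_aggregation_stage(data, screening.p_star, config)


def write_survivors(patterns: set[Pattern] | list[Pattern], path) -> None:
    """One pattern label per line, e.g. ``X50`` or ``X150*X250``."""
    with open(path, "w") as fh:
        for pat in sorted(set(patterns)):
            fh.write(pat.label() + "\n")


def read_survivors(path) -> set[Pattern]:
    out: set[Pattern] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.add(Pattern.from_label(line))
    return out
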
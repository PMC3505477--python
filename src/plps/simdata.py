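"""Synthetic-data generators for the four simulation designs.

Covariates are binary.  Independent blocks draw iid Bernoulli(0.5);
correlated blocks draw a latent Gaussian vector with a banded Toeplitz
correlation (rho1 at lag 1, rho2 at lag 2, independent beyond lag 2) and
threshold it at zero, so every marginal is Bernoulli(0.5) and the binary
lag-1 correlation is ``(2/pi) arcsin(rho1)``.  The response is Bernoulli
with logit equal to a sparse signed combination of patterns.

The four built-in scenarios:

1. n=700, p=400 iid;     f = -2 + 1.5 X50 + 1.5 X150*X250 + 1.5 X251*X252
2. n=1000, p=8000 banded (2/3, 1/3);
   f = -4 + 2 X500 + 3 X5000 + 2 X1000*X3000 + 3 X7000*X7002
3. n=1000, p=500 banded (2/3, 1/3);
   f = -4 + 2 X100 + 3 X200 + 2 X300*X400 + 3 X150*X450*X451
4. n=700, p=400; variables 1-200 banded (2/3, 1/3), 201-400 banded
   (-1/3, -1/6);  f = -1 + 2.5 (X1 - X3 + X10 - X201 + X220 - X230)
                        + 3 (X100*X102 - X300*X302 + X50*X250)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .driver import RunConfig, run_plps
from .lps_unit import SelectedModel
from .patterns import BinaryDataset, Pattern

logger = logging.getLogger("plps")

__all__ = [
    "CovariateBlock",
    "LogitSpec",
    "SimulationScenario",
    "ReplicateRun",
    "gen_covariates",
    "gen_response",
    "make_scenario",
    "make_dataset",
    "run_replicates",
]

#: Ridge added to the banded latent correlation before factorization; the
#: stated bands sit on the positive-semidefinite boundary.
BAND_JITTER = 1e-8

#: Offset separating the covariate and response seed streams per replicate.
RESPONSE_SEED_OFFSET = 10**6


@dataclass(frozen=True)
class CovariateBlock:
    """A run of variables sharing one law: iid or banded latent Gaussian."""

    size: int
    rho1: float = 0.0
    rho2: float = 0.0
    iid: bool = True

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("block size must be >= 1")
        if not self.iid and abs(self.rho1) >= 1:
            raise ValueError("|rho1| must be < 1")

    @classmethod
    def bernoulli(cls, size: int) -> "CovariateBlock":
        return cls(size=size, iid=True)

    @classmethod
    def banded(cls, size: int, rho1: float, rho2: float) -> "CovariateBlock":
        return cls(size=size, rho1=rho1, rho2=rho2, iid=False)


@dataclass(frozen=True)
class LogitSpec:
    intercept: float
    terms: tuple[tuple[Pattern, float], ...]

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        f = np.full(X.shape[0], self.intercept)
        for pat, weight in self.terms:
            v = np.ones(X.shape[0])
            for j in pat.variables:
                v = v * X[:, j]
            f += weight * v
        return f

    def truth_patterns(self) -> set[Pattern]:
        return {pat for pat, _ in self.terms}


@dataclass(frozen=True)
class SimulationScenario:
    name: str
    n: int
    p: int
    blocks: tuple[CovariateBlock, ...]
    logit: LogitSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(b.size for b in self.blocks) != self.p:
            raise ValueError("block sizes must sum to p")
        for pat, w in self.logit.terms:
            if pat.variables and pat.variables[-1] >= self.p:
                raise ValueError(f"pattern {pat.label()} out of range")
            if not np.isfinite(w):
                raise ValueError("weights must be finite")


def _banded_block(rng: np.random.Generator, n: int, block: CovariateBlock) -> np.ndarray:
    """Latent band-correlated Gaussians thresholded at zero.

    Builds the banded Cholesky factor of the (jittered) Toeplitz band
    matrix once and applies it to iid normals column-block-wise.
    """
    m = block.size
    bw = 2 if m >= 3 else m - 1
    ab = np.zeros((bw + 1, m))
    ab[0, :] = 1.0 + BAND_JITTER
    if bw >= 1:
        ab[1, : m - 1] = block.rho1
    if bw >= 2:
        ab[2, : m - 2] = block.rho2
    try:
        L = scipy.linalg.cholesky_banded(ab, lower=True)
    except scipy.linalg.LinAlgError as err:
        raise ValueError(
            f"banded correlation (rho1={block.rho1}, rho2={block.rho2}) "
            f"is not positive definite for block of size {m}"
        ) from err
    z = rng.standard_normal((m, n))
    latent = np.zeros((m, n))
    for d in range(bw + 1):
        latent[d:, :] += L[d, : m - d, None] * z[: m - d, :]
    return (latent.T > 0.0).astype(np.uint8)


def gen_covariates(scenario: SimulationScenario, seed: int | None = None) -> np.ndarray:
    """Simulate the n-by-p binary predictor matrix of a scenario."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    cols: list[np.ndarray] = []
    for block in scenario.blocks:
        if block.iid:
            cols.append(
                (rng.random((scenario.n, block.size)) < 0.5).astype(np.uint8)
            )
        else:
            cols.append(_banded_block(rng, scenario.n, block))
    return np.concatenate(cols, axis=1)


def gen_response(X: np.ndarray, logit: LogitSpec, seed: int) -> np.ndarray:
    """y_i ~ Bernoulli(sigmoid(f(x_i))) independently across subjects."""
    rng = np.random.default_rng(seed)
    f = logit.evaluate(X)
    prob = 1.0 / (1.0 + np.exp(-f))
    return (rng.random(X.shape[0]) < prob).astype(np.float64)


def _pat(*one_based: int) -> Pattern:
    return Pattern(tuple(sorted(i - 1 for i in one_based)))


def make_scenario(example: int, seed: int = 0) -> SimulationScenario:
    """The exact (n, p, covariate law, logit) of simulation examples 1-4."""
    if example == 1:
        return SimulationScenario(
            name="example1",
            n=700,
            p=400,
            blocks=(CovariateBlock.bernoulli(400),),
            logit=LogitSpec(
                intercept=-2.0,
                terms=(
                    (_pat(50), 1.5),
                    (_pat(150, 250), 1.5),
                    (_pat(251, 252), 1.5),
                ),
            ),
            seed=seed,
        )
    if example == 2:
        return SimulationScenario(
            name="example2",
            n=1000,
            p=8000,
            blocks=(CovariateBlock.banded(8000, 2.0 / 3.0, 1.0 / 3.0),),
            logit=LogitSpec(
                intercept=-4.0,
                terms=(
                    (_pat(500), 2.0),
                    (_pat(5000), 3.0),
                    (_pat(1000, 3000), 2.0),
                    (_pat(7000, 7002), 3.0),
                ),
            ),
            seed=seed,
        )
    if example == 3:
        return SimulationScenario(
            name="example3",
            n=1000,
            p=500,
            blocks=(CovariateBlock.banded(500, 2.0 / 3.0, 1.0 / 3.0),),
            logit=LogitSpec(
                intercept=-4.0,
                terms=(
                    (_pat(100), 2.0),
                    (_pat(200), 3.0),
                    (_pat(300, 400), 2.0),
                    (_pat(150, 450, 451), 3.0),
                ),
            ),
            seed=seed,
        )
    if example == 4:
        return SimulationScenario(
            name="example4",
            n=700,
            p=400,
            blocks=(
                CovariateBlock.banded(200, 2.0 / 3.0, 1.0 / 3.0),
                CovariateBlock.banded(200, -1.0 / 3.0, -1.0 / 6.0),
            ),
            logit=LogitSpec(
                intercept=-1.0,
                terms=(
                    (_pat(1), 2.5),
                    (_pat(3), -2.5),
                    (_pat(10), 2.5),
                    (_pat(201), -2.5),
                    (_pat(220), 2.5),
                    (_pat(230), -2.5),
                    (_pat(100, 102), 3.0),
                    (_pat(300, 302), -3.0),
                    (_pat(50, 250), 3.0),
                ),
            ),
            seed=seed,
        )
    raise ValueError(f"unknown simulation example {example!r}")


def make_dataset(scenario: SimulationScenario, replicate: int = 0) -> BinaryDataset:
    """One seeded replicate: covariates and response on separate streams."""
    base = scenario.seed
    X = gen_covariates(scenario, seed=base + replicate)
    y = gen_response(X, scenario.logit, seed=base + RESPONSE_SEED_OFFSET + replicate)
    return BinaryDataset(y=y, X=X)


@dataclass
class ReplicateRun:
    replicate: int
    seed: int
    model: SelectedModel | None
    error: str | None = None


def run_replicates(
    scenario: SimulationScenario,
    config: RunConfig,
    reps: int,
    base_seed: int | None = None,
) -> list[ReplicateRun]:
    """Fit pLPS on independent replicates of a scenario.

    Per-replicate failures are recorded in the output rather than raised.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if base_seed is not None:
        scenario = SimulationScenario(
            name=scenario.name, n=scenario.n, p=scenario.p,
            blocks=scenario.blocks, logit=scenario.logit, seed=base_seed,
        )
    runs: list[ReplicateRun] = []
    for r in range(reps):
        data = make_dataset(scenario, replicate=r)
        try:
            model = run_plps(data, config)
            runs.append(ReplicateRun(replicate=r, seed=scenario.seed + r, model=model))
        except Exception as err:  # noqa: BLE001 - recorded, not fatal
            logger.exception("replicate %d failed", r)
            runs.append(
                ReplicateRun(replicate=r, seed=scenario.seed + r, model=None,
                             error=str(err))
            )
    return runs
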
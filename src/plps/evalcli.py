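"""Evaluation metrics, prevalence filtering, file I/O and the CLI.

Selection performance over simulation replicates is summarized the way the
simulation tables are read: a *pattern count* is the number of replicates
whose final model contains a given pattern exactly, a *variable count* is
the number of replicates in which a variable appears anywhere in the model
(as a main effect or inside any interaction), and the *false-pattern
total* counts every selected pattern outside the truth set, summed over
replicates.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .driver import RunConfig, run_aggregation_stage, run_plps, run_screening_stage, \
    read_survivors, write_survivors
from .lps_unit import SelectedModel
from .patterns import BinaryDataset, Pattern
from .simdata import make_dataset, make_scenario

logger = logging.getLogger("plps")

__all__ = [
    "EvaluationReport",
    "CvSummary",
    "count_patterns",
    "prevalence_filter",
    "auc",
    "cross_validate",
    "read_dataset",
    "write_model",
    "read_model",
    "main",
]


@dataclass
class EvaluationReport:
    reps: int
    pattern_counts: dict[Pattern, int]
    variable_counts: dict[int, int]
    false_pattern_total: int
    false_variable_total: int

    def as_table(self) -> pd.DataFrame:
        rows = []
        for pat, count in self.pattern_counts.items():
            vc = ", ".join(
                str(self.variable_counts[v]) for v in pat.variables
            )
            rows.append({"pattern": pat.label(), "pattern_count": count,
                         "variable_counts": vc})
        return pd.DataFrame(rows)


def count_patterns(
    models: list[SelectedModel], truth: set[Pattern]
) -> EvaluationReport:
    """Tally exact-pattern and variable appearances against a truth set."""
    if not models:
        raise ValueError("need at least one model")
    truth = {pat for pat in truth if not pat.is_constant}
    truth_vars = {v for pat in truth for v in pat.variables}
    pattern_counts = {pat: 0 for pat in truth}
    variable_counts = {v: 0 for v in truth_vars}
    false_pattern_total = 0
    false_variable_total = 0
    for model in models:
        selected = set(model.patterns)
        for pat in truth:
            if pat in selected:
                pattern_counts[pat] += 1
        model_vars = model.variables()
        for v in truth_vars:
            if v in model_vars:
                variable_counts[v] += 1
        false_pattern_total += sum(1 for pat in selected if pat not in truth)
        false_variable_total += sum(1 for v in model_vars if v not in truth_vars)
    return EvaluationReport(
        reps=len(models),
        pattern_counts=pattern_counts,
        variable_counts=variable_counts,
        false_pattern_total=false_pattern_total,
        false_variable_total=false_variable_total,
    )


def prevalence_filter(
    X: np.ndarray, low: float = 0.10, high: float = 0.90
) -> np.ndarray:
    """Indices of columns whose mean lies in [low, high] inclusive.

    Variables expressed in fewer than 10% or more than 90% of subjects
    carry little predictive signal and are dropped upstream of the fit.
    """
    X = np.asarray(X)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("X must be binary")
    means = X.mean(axis=0)
    return np.flatnonzero((means >= low) & (means <= high))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic, tie-corrected)."""
    labels = np.asarray(labels, dtype=np.float64).ravel()
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, scores))


@dataclass
class CvSummary:
    """Five-fold cross-validation summary, averaged over folds.

    ``n_gene`` is the number of distinct variables in the model, ``n_para``
    the number of non-intercept coefficients, ``q`` the highest interaction
    order present, and ``total`` their sum — all per fold, then averaged.
    """

    folds: int
    n_gene: float
    n_para: float
    q: float
    total: float
    auc: float
    per_fold: list[dict] = field(default_factory=list)


def cross_validate(
    data: BinaryDataset, config: RunConfig, folds: int = 5, seed: int = 0
) -> CvSummary:
    """Stratified k-fold CV of the full pLPS pipeline."""
    if data.n < folds:
        raise ValueError("fewer subjects than folds")
    counts = np.bincount(data.y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError("a class has fewer members than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for fold, (train, test) in enumerate(skf.split(data.X, data.y)):
        train_data = BinaryDataset(
            y=data.y[train], X=data.X[train], names=list(data.names)
        )
        model = run_plps(train_data, config)
        scores = model.predict_prob(data.X[test])
        fold_auc = auc(scores, data.y[test])
        record = {
            "fold": fold,
            "n_gene": len(model.variables()),
            "n_para": model.n_terms,
            "q": model.order,
            "auc": fold_auc,
        }
        record["total"] = record["n_gene"] + record["n_para"] + record["q"]
        per_fold.append(record)
        logger.info("fold %d: %s", fold, record)
    return CvSummary(
        folds=folds,
        n_gene=float(np.mean([r["n_gene"] for r in per_fold])),
        n_para=float(np.mean([r["n_para"] for r in per_fold])),
        q=float(np.mean([r["q"] for r in per_fold])),
        total=float(np.mean([r["total"] for r in per_fold])),
        auc=float(np.mean([r["auc"] for r in per_fold])),
        per_fold=per_fold,
    )


# ---------------------------------------------------------------------------
# File I/O


def read_dataset(
    path, response: str | None = None, response_path=None
) -> BinaryDataset:
    """Read a TSV/CSV of binary predictors (header row of variable names).

    The response is either a named column of the table or a separate
    single-column file.  Any non-binary entry is reported with its row and
    column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if response is not None:
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not in {path}")
        y = df[response].to_numpy()
        df = df.drop(columns=[response])
    elif response_path is not None:
        y = pd.read_csv(response_path, header=None).to_numpy().ravel()
    else:
        raise ValueError("a response column or response file is required")
    X = df.to_numpy()
    bad = np.argwhere(~np.isin(X, (0, 1)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-binary entry {X[i, j]!r} at row {i + 1}, column {df.columns[j]!r}"
        )
    if not np.isin(np.asarray(y), (0, 1)).all():
        raise ValueError("non-binary response entry")
    return BinaryDataset(y=y, X=X, names=[str(c) for c in df.columns])


def model_to_dict(model: SelectedModel, tuning: dict | None = None) -> dict:
    return {
        "order": model.order,
        "intercept": float(model.intercept),
        "terms": [
            {
                "variables": [f"X{v + 1}" for v in pat.variables],
                "coefficient": float(c),
            }
            for pat, c in zip(model.patterns, model.coefficients)
        ],
        "tuning": tuning or {"criterion": "BGACV", "lambdas": []},
        "provenance": model.provenance,
    }


def model_from_dict(payload: dict) -> SelectedModel:
    patterns = []
    coefs = []
    for term in payload["terms"]:
        idx = tuple(sorted(int(v[1:]) - 1 for v in term["variables"]))
        patterns.append(Pattern(idx))
        coefs.append(float(term["coefficient"]))
    return SelectedModel(
        patterns=patterns,
        intercept=float(payload["intercept"]),
        coefficients=np.array(coefs, dtype=np.float64),
        provenance=payload.get("provenance", ""),
    )


def write_model(model: SelectedModel, path, tuning: dict | None = None) -> None:
    payload = model_to_dict(model, tuning)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path) -> SelectedModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Command-line interface


def _setup_logging(verbose: bool) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        stream=sys.stderr,
    )


def _config_from_options(order, group_size, seed, workers) -> RunConfig:
    return RunConfig(order=order, g=group_size, seed=seed, workers=workers)



def _load(data_path, response, response_file):
    if response is None and response_file is None:
        raise click.UsageError("provide --response or --response-file")
    return read_dataset(data_path, response=response, response_path=response_file)


@click.group()
@click.option("--verbose", is_flag=True, help="Per-path trace logging.")
def main(verbose: bool) -> None:
    """Partitioned LASSO-Patternsearch for binary risk-factor patterns."""
    _setup_logging(verbose)


_common = [
    click.option("--data", "data_path", required=True, type=click.Path(exists=True)),
    click.option("--response", default=None, help="Response column name."),
    click.option("--response-file", "response_file", default=None,
                 type=click.Path(exists=True),
                 help="Single-column response file (alternative to --response)."),
    click.option("--group-size", type=int, default=None, help="Partition size g."),
    click.option("--order", type=click.Choice(["2", "3"]), default="2"),
    click.option("--seed", type=int, default=0),
    click.option("--workers", type=int, default=1),
]


def _add_options(options):
    def wrap(func):
        for option in reversed(options):
            func = option(func)
        return func
    return wrap


@main.command()
@_add_options(_common)
@click.option("--out", required=True, type=click.Path())
def run(data_path, response, response_file, group_size, order, seed, workers, out):
    """Run the full two-stage pipeline and write the model JSON."""
    data = _load(data_path, response, response_file)
    config = _config_from_options(int(order), group_size, seed, workers)
    model = run_plps(data, config)
    write_model(model, out)
    click.echo(model.summary())


@main.command()
@_add_options(_common)
@click.option("--out", required=True, type=click.Path())
def screen(data_path, response, response_file, group_size, order, seed, workers, out):
    """Run the screening stage only and write the survivors file."""
    data = _load(data_path, response, response_file)
    config = _config_from_options(int(order), group_size, seed, workers)
    result = run_screening_stage(data, config)
    write_survivors(result.survivors, out)
    click.echo(f"{len(result.survivors)} surviving patterns, "
               f"|p*|={len(result.p_star)}")


@main.command()
@_add_options(_common)
@click.option("--survivors", "survivors_path", required=True,
              type=click.Path(exists=True))
@click.option("--out", required=True, type=click.Path())
def aggregate(data_path, response, response_file, group_size, order, seed,
              workers, survivors_path, out):
    """Run the aggregation stage from a survivors file."""
    data = _load(data_path, response, response_file)
    config = _config_from_options(int(order), group_size, seed, workers)
    survivors = read_survivors(survivors_path)
    p_star = {v for pat in survivors for v in pat.variables}
    model = run_aggregation_stage(data, p_star, config)
    write_model(model, out)
    click.echo(model.summary())


@main.command()
@click.option("--example", type=click.Choice(["1", "2", "3", "4"]), required=True)
@click.option("--reps", type=int, default=1)
@click.option("--seed", type=int, default=0)
@click.option("--out", "out_dir", required=True, type=click.Path())
def simulate(example, reps, seed, out_dir):
    """Write one TSV per simulated replicate plus a truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scenario = make_scenario(int(example), seed=seed)
    for r in range(reps):
        data = make_dataset(scenario, replicate=r)
        df = pd.DataFrame(data.X, columns=data.names)
        df.insert(0, "y", data.y.astype(int))
        df.to_csv(out_dir / f"replicate{r:03d}.tsv", sep="\t", index=False)
    truth = {
        "intercept": scenario.logit.intercept,
        "terms": [
            {"variables": [f"X{v + 1}" for v in pat.variables], "weight": w}
            for pat, w in scenario.logit.terms
        ],
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    click.echo(f"wrote {reps} replicates to {out_dir}")


@main.command()
@click.option("--models", "models_dir", required=True, type=click.Path(exists=True))
@click.option("--truth", "truth_path", required=True, type=click.Path(exists=True))
def evaluate(models_dir, truth_path):
    """Tally selection counts of model JSONs against a truth file."""
    with open(truth_path) as fh:
        truth_payload = json.load(fh)
    truth = {
        Pattern(tuple(sorted(int(v[1:]) - 1 for v in term["variables"])))
        for term in truth_payload["terms"]
    }
    models = [read_model(p) for p in sorted(Path(models_dir).glob("*.json"))
              if p.name != "truth.json"]
    report = count_patterns(models, truth)
    click.echo(report.as_table().to_string(index=False))
    click.echo(f"false patterns total: {report.false_pattern_total}")


@main.command()
@_add_options(_common)
@click.option("--folds", type=int, default=5)
def cv(data_path, response, response_file, group_size, order, seed, workers, folds):
    """Five-fold cross-validation of the full pipeline."""
    data = _load(data_path, response, response_file)
    config = _config_from_options(int(order), group_size, seed, workers)
    summary = cross_validate(data, config, folds=folds, seed=seed)
    click.echo(
        f"#Gene {summary.n_gene:.1f}  #Para {summary.n_para:.1f}  "
        f"q {summary.q:.1f}  Total {summary.total:.1f}  AUC {summary.auc:.3f}"
    )


if __name__ == "__main__":  # pragma: no cover
    main()
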
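"""Budgeted automated pipeline search for score and C-BARQ prediction.

A seeded evolutionary search (population 20, tournament selection,
single-gene mutation) over scikit-learn pipelines of the form

    {optional scaler} -> {optional feature selector} -> {estimator},

capped at a fixed number of evaluated pipelines (default cap 10,000;
the study-scale runs here use a budget of a few hundred).  Candidates
are scored by mean cross-validation accuracy (classification) or
negative mean squared error (regression); the winner is refit and
reported with the standard metric panels: accuracy / macro precision /
macro recall / macro F1, or MAE / MSE / R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.feature_selection import SelectKBest, f_classif, f_regression
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.metrics import (
    accuracy_score,
    mean_absolute_error,
    mean_squared_error,
    precision_recall_fscore_support,
    r2_score,
)
from sklearn.model_selection import (
    KFold,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
)
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, RobustScaler, StandardScaler
from sklearn.svm import SVC, SVR

MAX_BUDGET = 10_000

SCALERS = (None, "standard", "minmax", "robust")
SELECT_K = (None, 10, 25, 50, 100)

CLASSIFIER_GRID: dict[str, dict[str, tuple]] = {
    "logreg": {"C": (0.01, 0.1, 1.0, 10.0)},
    "svc": {"C": (0.1, 1.0, 10.0), "kernel": ("linear", "rbf")},
    "rf": {"n_estimators": (100, 200), "max_depth": (None, 5)},
    "knn": {"n_neighbors": (3, 5, 7)},
    "gb": {"n_estimators": (50, 100), "learning_rate": (0.05, 0.1)},
}

REGRESSOR_GRID: dict[str, dict[str, tuple]] = {
    "ridge": {"alpha": (0.1, 1.0, 10.0, 100.0)},
    "lasso": {"alpha": (0.001, 0.01, 0.1)},
    "svr": {"C": (0.1, 1.0, 10.0), "kernel": ("linear", "rbf")},
    "rf": {"n_estimators": (100, 200), "max_depth": (None, 5)},
    "knn": {"n_neighbors": (3, 5, 7)},
    "gb": {"n_estimators": (50, 100), "learning_rate": (0.05, 0.1)},
}


@dataclass
class SearchConfig:
    """Configuration of one pipeline search."""

    task: str = "classification"  # or "regression"
    budget: int = 200
    cv_folds: int = 5
    seed: int = 0
    population: int = 20
    tournament: int = 3

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        if not 1 <= self.budget <= MAX_BUDGET:
            raise ValueError(f"budget must lie in [1, {MAX_BUDGET}]")
        if self.cv_folds < 2:
            raise ValueError("cv needs at least 2 folds")


@dataclass
class ModelReport:
    """Winning pipeline plus its cross-validated metric panel."""

    task: str
    pipeline_description: dict
    cv_score: float
    n_evaluated: int
    metrics: dict[str, float]
    search_log: pd.DataFrame = field(repr=False, default=None)


def _make_estimator(task: str, name: str, params: dict, seed: int):
    if task == "classification":
        if name == "logreg":
            return LogisticRegression(max_iter=5000, random_state=seed, **params)
        if name == "svc":
            return SVC(random_state=seed, **params)
        if name == "rf":
            return RandomForestClassifier(random_state=seed, **params)
        if name == "knn":
            return KNeighborsClassifier(**params)
        if name == "gb":
            return GradientBoostingClassifier(random_state=seed, **params)
    else:
        if name == "ridge":
            return Ridge(**params)
        if name == "lasso":
            return Lasso(max_iter=20000, **params)
        if name == "svr":
            return SVR(**params)
        if name == "rf":
            return RandomForestRegressor(random_state=seed, **params)
        if name == "knn":
            return KNeighborsRegressor(**params)
        if name == "gb":
            return GradientBoostingRegressor(random_state=seed, **params)
    raise ValueError(f"unknown estimator {name!r} for task {task!r}")


def _build_pipeline(genome: dict, task: str, n_features: int, seed: int) -> Pipeline:
    steps = []
    if genome["scaler"] == "standard":
        steps.append(("scale", StandardScaler()))
    elif genome["scaler"] == "minmax":
        steps.append(("scale", MinMaxScaler()))
    elif genome["scaler"] == "robust":
        steps.append(("scale", RobustScaler()))
    if genome["select_k"] is not None:
        score_fn = f_classif if task == "classification" else f_regression
        steps.append(("select", SelectKBest(score_fn,
                                            k=min(genome["select_k"], n_features))))
    steps.append(("est", _make_estimator(task, genome["estimator"],
                                         genome["est_params"], seed)))
    return Pipeline(steps)


def _random_genome(rng: np.random.Generator, grid: dict) -> dict:
    est = list(grid)[rng.integers(len(grid))]
    params = {p: vals[rng.integers(len(vals))] for p, vals in grid[est].items()}
    return {
        "scaler": SCALERS[rng.integers(len(SCALERS))],
        "select_k": SELECT_K[rng.integers(len(SELECT_K))],
        "estimator": est,
        "est_params": params,
    }


def _mutate(genome: dict, rng: np.random.Generator, grid: dict) -> dict:
    g = {**genome, "est_params": dict(genome["est_params"])}
    gene = ("scaler", "select_k", "estimator", "param")[rng.integers(4)]
    if gene == "scaler":
        g["scaler"] = SCALERS[rng.integers(len(SCALERS))]
    elif gene == "select_k":
        g["select_k"] = SELECT_K[rng.integers(len(SELECT_K))]
    elif gene == "estimator":
        est = list(grid)[rng.integers(len(grid))]
        g["estimator"] = est
        g["est_params"] = {p: vals[rng.integers(len(vals))]
                           for p, vals in grid[est].items()}
    else:
        params = grid[g["estimator"]]
        p = list(params)[rng.integers(len(params))]
        g["est_params"][p] = params[p][rng.integers(len(params[p]))]
    return g


def pipeline_search(X, y, config: SearchConfig) -> tuple[Pipeline, ModelReport]:
    """Evolutionary search over ML pipelines under an evaluation budget.

    Every candidate is scored by mean CV score; the best evaluated
    candidate wins (its score is >= every other candidate's by
    construction).  Fully reproducible given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must be row-aligned")
    if len(X) < 10:
        raise ValueError("need at least 10 samples for cross-validation")
    if config.task == "classification" and len(np.unique(y)) < 2:
        raise ValueError("classification needs at least 2 classes in y")

    grid = CLASSIFIER_GRID if config.task == "classification" else REGRESSOR_GRID
    rng = np.random.default_rng(config.seed)
    if config.task == "classification":
        cv = StratifiedKFold(config.cv_folds, shuffle=True, random_state=config.seed)
        scoring = "accuracy"
    else:
        cv = KFold(config.cv_folds, shuffle=True, random_state=config.seed)
        scoring = "neg_mean_squared_error"

    cache: dict[str, float] = {}

    def evaluate(genome: dict) -> float:
        # duplicate genomes (evolution revisits them) count toward the
        # budget but are not refit
        key = repr(sorted(_describe(genome).items())[:-1])
        if key in cache:
            return cache[key]
        pipe = _build_pipeline(genome, config.task, X.shape[1], config.seed)
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores = cross_val_score(pipe, X, y, cv=cv, scoring=scoring,
                                         error_score=-np.inf)
            score = float(np.mean(scores))
        except Exception:
            score = -np.inf
        cache[key] = score
        return score

    log_rows: list[dict] = []
    population: list[tuple[float, dict]] = []
    n_eval = 0
    pop_size = min(config.population, config.budget)
    while n_eval < pop_size:
        g = _random_genome(rng, grid)
        s = evaluate(g)
        n_eval += 1
        population.append((s, g))
        log_rows.append({"eval": n_eval, "score": s, **_describe(g)})

    while n_eval < config.budget:
        idx = rng.integers(len(population), size=min(config.tournament, len(population)))
        parent = max((population[i] for i in idx), key=lambda t: t[0])[1]
        child = _mutate(parent, rng, grid)
        s = evaluate(child)
        n_eval += 1
        log_rows.append({"eval": n_eval, "score": s, **_describe(child)})
        worst = min(range(len(population)), key=lambda i: population[i][0])
        if s > population[worst][0]:
            population[worst] = (s, child)

    log = pd.DataFrame(log_rows)
    best_row = int(log["score"].idxmax())
    best_score = float(log.loc[best_row, "score"])
    best_genome = log_rows[best_row]["genome"]

    pipe = _build_pipeline(best_genome, config.task, X.shape[1], config.seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_pred = cross_val_predict(pipe, X, y, cv=cv)
        pipe.fit(X, y)
    if config.task == "classification":
        metrics = evaluate_classifier(y, y_pred)
    else:
        metrics = evaluate_regressor(y, y_pred)
    report = ModelReport(
        task=config.task,
        pipeline_description=_describe(best_genome),
        cv_score=best_score,
        n_evaluated=n_eval,
        metrics=metrics,
        search_log=log.drop(columns=["genome"]),
    )
    return pipe, report


def _describe(genome: dict) -> dict:
    return {
        "scaler": genome["scaler"],
        "select_k": genome["select_k"],
        "estimator": genome["estimator"],
        "est_params": str(genome["est_params"]),
        "genome": genome,
    }


def evaluate_classifier(y_true, y_pred) -> dict[str, float]:
    """Accuracy plus macro-averaged precision, recall and F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="macro", zero_division=0)
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
    }


def evaluate_regressor(y_true, y_pred) -> dict[str, float]:
    """MAE, MSE and R^2; R^2 is NaN (with a warning) for constant y_true."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    out = {
        "mae": float(mean_absolute_error(y_true, y_pred)),
        "mse": float(mean_squared_error(y_true, y_pred)),
    }
    if np.ptp(y_true) == 0:
        import warnings

        warnings.warn("R^2 undefined for zero-variance y_true", stacklevel=2)
        out["r2"] = float("nan")
    else:
        out["r2"] = float(r2_score(y_true, y_pred))
    return out


def regress_cbarq(
    X, cbarq: pd.DataFrame, config: SearchConfig | None = None
) -> pd.DataFrame:
    """One independent pipeline search per C-BARQ category.

    ``cbarq`` columns: trial_id plus the 8 categories, row-aligned with
    ``X``.  Returns one row per category with mae / mse / r2.
    """
    from .stats import CBARQ_CATEGORIES

    rows = []
    for cat in CBARQ_CATEGORIES:
        cfg = SearchConfig(task="regression",
                           **({} if config is None else {
                               "budget": config.budget, "cv_folds": config.cv_folds,
                               "seed": config.seed, "population": config.population,
                               "tournament": config.tournament}))
        _, rep = pipeline_search(X, cbarq[cat].to_numpy(dtype=float), cfg)
        rows.append({"category": cat, **rep.metrics,
                     "pipeline": rep.pipeline_description["estimator"]})
    return pd.DataFrame(rows)
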
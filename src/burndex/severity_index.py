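"""Wrapper variable selection and the %TBSA severity-index regression.

The index predicts burn extent (%TBSA) from a fixed-budget set of measured
variables.  Model quality is scored by relative absolute error,

    RAE = 100 * sum|y_hat - y| / sum|y_bar - y|,

with the mean of the training targets as the naive baseline ``y_bar``;
"average relative accuracy" is 100 - RAE.  Accuracy is estimated by
repeated (default five) 10-fold cross-validations in which both the fold
partition and every randomizable model component are re-randomized per
repetition; the report carries the mean and sd of accuracy across
repetitions.

Variable selection is a wrapper search: a genetic algorithm over variable
bitmasks with cross-validated accuracy as fitness, followed by a best-first
search (greedy forward steps with backtracking, stopped after a stale
limit) restricted to the GA-selected pool, which returns exactly the preset
number of variables.  The budget is normally the number of independent
dose-response patterns found upstream.

Five regressor families are provided: ordinary least squares, a normalized
Gaussian radial-basis-function network, a single-hidden-layer perceptron,
linear-kernel support vector regression, and a variance-reduction model
tree with linear leaf models (covering the piecewise-linear family; it is
not a re-implementation of any particular historical tool).  Hyperparameter
defaults are fixed and documented; no tuning is performed.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cluster import KMeans
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cohort_data import CohortError, CohortTable, VariableKey

REGRESSOR_KINDS = ("linear", "rbf_network", "mlp", "svr", "model_tree")


# ---------------------------------------------------------------------------
# Metric
# ---------------------------------------------------------------------------

def rae(predictions, actuals, baseline: float | None = None) -> float:
    """Relative absolute error (%) against a constant-baseline predictor.

    ``baseline`` defaults to the mean of ``actuals``; pass the training-set
    mean when scoring held-out data.  Errors on constant actuals with the
    default baseline (zero denominator).
    """
    y_hat = np.asarray(predictions, float)
    y = np.asarray(actuals, float)
    if y_hat.shape != y.shape or y.size == 0:
        raise ValueError("predictions and actuals must be equal-length, non-empty")
    b = float(np.mean(y)) if baseline is None else float(baseline)
    if not np.isfinite(b):
        raise ValueError("baseline must be finite")
    denom = np.abs(b - y).sum()
    if denom == 0:
        raise ValueError("constant actuals: RAE undefined (zero denominator)")
    return float(100.0 * np.abs(y_hat - y).sum() / denom)


def relative_accuracy(predictions, actuals, baseline: float | None = None) -> float:
    """Average relative accuracy = 100 - RAE (may be negative)."""
    return 100.0 - rae(predictions, actuals, baseline)


# ---------------------------------------------------------------------------
# Regressors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressorSpec:
    """A model family plus fixed hyperparameters and a seed."""

    kind: str
    params: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in REGRESSOR_KINDS:
            raise ValueError(f"unknown regressor kind {self.kind!r}")

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    def with_seed(self, seed: int) -> "RegressorSpec":
        return replace(self, seed=seed)


class RBFNetwork(BaseEstimator, RegressorMixin):
    """Normalized Gaussian radial-basis-function network.

    Basis centers come from k-means on the training inputs; each basis
    width is the distance to the nearest other center (floored for
    coincident centers).  The normalized activations feed a ridge readout.
    """

    def __init__(self, n_centers: int = 2, ridge: float = 1e-6, random_state: int = 0):
        self.n_centers = n_centers
        self.ridge = ridge
        self.random_state = random_state

    def _design(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centers_[None, :, :]) ** 2).sum(-1)
        phi = np.exp(-d2 / (2.0 * self.widths_**2))
        total = phi.sum(1, keepdims=True)
        total[total == 0] = 1.0
        return phi / total

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        k = min(self.n_centers, len(X))
        km = KMeans(n_clusters=k, n_init=5, random_state=self.random_state)
        km.fit(X)
        self.centers_ = km.cluster_centers_
        if k == 1:
            self.widths_ = np.array([1.0])
        else:
            d = np.linalg.norm(
                self.centers_[:, None, :] - self.centers_[None, :, :], axis=-1
            )
            np.fill_diagonal(d, np.inf)
            self.widths_ = np.maximum(d.min(1), 1e-6)
        self.readout_ = Ridge(alpha=self.ridge)
        self.readout_.fit(self._design(X), y)
        return self

    def predict(self, X):
        return self.readout_.predict(self._design(np.asarray(X, float)))


class ModelTree(BaseEstimator, RegressorMixin):
    """Variance-reduction regression tree with linear models in the leaves.

    Splits greedily maximize the reduction in target variance (the classic
    model-tree growing criterion); leaves hold ridge-stabilized linear
    models over all inputs.  Growth stops when a node holds fewer than
    ``2 * min_leaf`` cases or its target variance is negligible.
    """

    def __init__(self, min_leaf: int = 4, ridge: float = 1e-6, max_depth: int = 6):
        self.min_leaf = min_leaf
        self.ridge = ridge
        self.max_depth = max_depth

    def _leaf(self, X, y):
        model = Ridge(alpha=self.ridge)
        model.fit(X, y)
        return ("leaf", model)

    def _grow(self, X, y, depth):
        n = len(y)
        if depth >= self.max_depth or n < 2 * self.min_leaf or np.var(y) < 1e-12:
            return self._leaf(X, y)
        base = np.var(y) * n
        best = None
        for j in range(X.shape[1]):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys = X[order, j], y[order]
            for i in range(self.min_leaf, n - self.min_leaf + 1):
                if xs[i] == xs[i - 1]:
                    continue
                left, right = ys[:i], ys[i:]
                score = base - (np.var(left) * len(left) + np.var(right) * len(right))
                if best is None or score > best[0]:
                    best = (score, j, (xs[i] + xs[i - 1]) / 2.0)
        if best is None or best[0] <= 0:
            return self._leaf(X, y)
        _, j, thr = best
        mask = X[:, j] <= thr
        return (
            "split",
            j,
            thr,
            self._grow(X[mask], y[mask], depth + 1),
            self._grow(X[~mask], y[~mask], depth + 1),
        )

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        self.tree_ = self._grow(X, y, 0)
        return self

    def _predict_one(self, node, x):
        while node[0] == "split":
            _, j, thr, left, right = node
            node = left if x[j] <= thr else right
        return node[1].predict(x[None, :])[0]

    def predict(self, X):
        X = np.asarray(X, float)
        return np.array([self._predict_one(self.tree_, x) for x in X])


def make_regressor(spec: RegressorSpec, n_features: int):
    """Instantiate a fit/predict estimator from a spec.

    Era-inspired fixed defaults: the perceptron has one hidden layer of
    ceil((n_features + 1) / 2) logistic units trained by plain-momentum SGD
    (learning rate 0.3, momentum 0.2, 500 epochs) on standardized inputs
    with an identity output; SVR uses a linear kernel with C = 1 and
    epsilon = 1e-3; the RBF network defaults to 2 centers.
    """
    p = spec.param_dict
    if spec.kind == "linear":
        return LinearRegression()
    if spec.kind == "svr":
        return make_pipeline(
            StandardScaler(),
            SVR(kernel="linear", C=p.get("C", 1.0), epsilon=p.get("epsilon", 1e-3)),
        )
    if spec.kind == "mlp":
        hidden = p.get("hidden_units") or max(1, math.ceil((n_features + 1) / 2))
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=(hidden,),
                activation="logistic",
                solver="sgd",
                learning_rate_init=p.get("learning_rate", 0.3),
                momentum=p.get("momentum", 0.2),
                nesterovs_momentum=False,
                alpha=p.get("alpha", 1e-8),
                batch_size=p.get("batch_size", "auto"),
                max_iter=p.get("max_iter", 500),
                tol=0.0,
                n_iter_no_change=p.get("max_iter", 500),
                random_state=spec.seed,
            ),
        )
    if spec.kind == "rbf_network":
        return RBFNetwork(
            n_centers=p.get("n_centers", 2),
            ridge=p.get("ridge", 1e-6),
            random_state=spec.seed,
        )
    if spec.kind == "model_tree":
        return ModelTree(
            min_leaf=p.get("min_leaf", 4),
            ridge=p.get("ridge", 1e-6),
            max_depth=p.get("max_depth", 6),
        )
    raise ValueError(spec.kind)  # pragma: no cover - guarded in __post_init__


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Relative accuracy of one model/variable set under repeated k-fold CV."""

    per_rep_rae: list[float]

    @property
    def rae_mean(self) -> float:
        return float(np.mean(self.per_rep_rae))

    @property
    def rae_sd(self) -> float:
        return float(np.std(self.per_rep_rae, ddof=1)) if len(self.per_rep_rae) > 1 else 0.0

    @property
    def accuracy_mean(self) -> float:
        return 100.0 - self.rae_mean

    @property
    def accuracy_sd(self) -> float:
        return self.rae_sd

    def to_dict(self) -> dict:
        return {
            "per_rep_rae": self.per_rep_rae,
            "rae_mean": self.rae_mean,
            "rae_sd": self.rae_sd,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
        }


def _design(data: CohortTable, variables: Sequence[VariableKey]) -> tuple[np.ndarray, np.ndarray]:
    cols = [v.column for v in variables]
    missing = [c for c in cols if c not in data.values.columns]
    if missing:
        raise CohortError(f"cohort lacks variable(s) {missing}")
    X = data.values[cols].to_numpy(float)
    if not np.isfinite(X).all():
        raise CohortError("design matrix contains missing or non-finite cells; impute first")
    return X, data.tbsa.to_numpy(float)


def cross_validate(
    model: RegressorSpec,
    data: CohortTable,
    variables: Sequence[VariableKey],
    folds: int = 10,
    reps: int = 5,
    seed: int = 0,
) -> EvalReport:
    """Repeated k-fold cross-validated relative accuracy.

    Each repetition draws a fresh shuffled fold partition and a fresh model
    seed; the RAE of a repetition pools held-out absolute errors over all
    folds, with each fold's naive baseline being its training-target mean.
    """
    X, y = _design(data, variables)
    if len(y) < folds:
        raise ValueError(f"need at least {folds} instances for {folds}-fold CV")
    per_rep = []
    for rep in range(reps):
        rep_seed = (seed * 1_000_003 + rep) % (2**31)
        kf = KFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        num = den = 0.0
        for train, test in kf.split(X):
            est = make_regressor(model.with_seed(rep_seed), X.shape[1])
            est.fit(X[train], y[train])
            pred = est.predict(X[test])
            num += np.abs(pred - y[test]).sum()
            den += np.abs(y[train].mean() - y[test]).sum()
        if den == 0:
            raise ValueError("constant targets within every fold: RAE undefined")
        per_rep.append(float(100.0 * num / den))
    return EvalReport(per_rep)


# ---------------------------------------------------------------------------
# Wrapper variable selection (GA + best-first)
# ---------------------------------------------------------------------------

@dataclass
class GAParams:
    population: int = 20
    generations: int = 20
    crossover_rate: float = 0.6
    mutation_rate: float | None = None  # default 1 / n_candidates
    elitism: int = 1
    tournament: int = 2
    #: per-bit probability a variable is on in the initial population;
    #: None -> min(0.5, max(5, 2*budget)/n_candidates).  Sparse starts keep
    #: early fitness informative when candidates far outnumber instances.
    init_density: float | None = None
    fitness_folds: int = 10
    fitness_reps: int = 1
    stale_limit: int = 5  # best-first backtracking patience


@dataclass
class SelectionResult:
    model: RegressorSpec
    variables: list[VariableKey]
    cv: EvalReport
    log: dict = field(default_factory=dict)


class _FitnessCache:
    """Cross-validated accuracy of variable subsets, memoized."""

    def __init__(self, model, data, candidates, ga: GAParams, seed: int):
        self.model = model
        self.data = data
        self.candidates = list(candidates)
        self.ga = ga
        self.seed = seed
        self.cache: dict[frozenset[int], float] = {}
        self.evaluations = 0

    def __call__(self, subset: frozenset[int]) -> float:
        if not subset:
            return -np.inf
        hit = self.cache.get(subset)
        if hit is not None:
            return hit
        report = cross_validate(
            self.model,
            self.data,
            [self.candidates[i] for i in sorted(subset)],
            folds=self.ga.fitness_folds,
            reps=self.ga.fitness_reps,
            seed=self.seed,
        )
        self.evaluations += 1
        self.cache[subset] = report.accuracy_mean
        return report.accuracy_mean


def _ga_search(
    fitness: _FitnessCache,
    n: int,
    ga: GAParams,
    rng: np.random.Generator,
    init_density: float = 0.5,
) -> np.ndarray:
    """Genetic algorithm over variable bitmasks; returns the best mask found."""
    mut = ga.mutation_rate if ga.mutation_rate is not None else 1.0 / n

    def ensure_nonempty(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask[rng.integers(n)] = True
        return mask

    pop = [ensure_nonempty(rng.random(n) < init_density) for _ in range(ga.population)]
    scores = [fitness(frozenset(np.flatnonzero(m))) for m in pop]
    best_i = int(np.argmax(scores))
    best_mask, best_score = pop[best_i].copy(), scores[best_i]

    for generation in range(ga.generations):
        order = np.argsort(scores)[::-1]
        nxt = [pop[i].copy() for i in order[: ga.elitism]]
        while len(nxt) < ga.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, ga.tournament)
                parents.append(pop[max(contenders, key=lambda i: scores[i])])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < ga.crossover_rate:
                cut = int(rng.integers(1, n)) if n > 1 else 0
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(n) < mut
                child[flip] = ~child[flip]
                nxt.append(ensure_nonempty(child))
        pop = nxt[: ga.population]
        scores = [fitness(frozenset(np.flatnonzero(m))) for m in pop]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_mask, best_score = pop[gen_best].copy(), scores[gen_best]
    # pool = every variable the final generation retained, plus the best mask:
    # the GA-filtered candidate pool handed to the best-first ranking stage
    pool_mask = best_mask.copy()
    for m in pop:
        pool_mask |= m
    return best_mask, pool_mask


def _best_first(
    fitness: _FitnessCache,
    pool: Sequence[int],
    budget: int,
    stale_limit: int,
) -> list[int]:
    """Forward best-first search with backtracking over a candidate pool.

    States are variable subsets; the most promising open state is expanded
    by single-variable additions (never beyond ``budget``).  The search
    stops once ``stale_limit`` consecutive expansions fail to improve the
    best heuristic, and returns the best-scoring subset of exactly
    ``budget`` variables, ordered by its greedy construction path.
    """
    counter = itertools.count()
    open_heap: list[tuple[float, int, tuple[int, ...]]] = []
    heapq.heappush(open_heap, (0.0, next(counter), ()))
    closed: set[frozenset[int]] = set()
    best_full: tuple[float, tuple[int, ...]] | None = None
    best_heuristic = -np.inf
    stale = 0
    while open_heap and stale <= stale_limit:
        neg_score, _, path = heapq.heappop(open_heap)
        state = frozenset(path)
        if state in closed:
            continue
        closed.add(state)
        improved = False
        if len(path) < budget:
            for j in pool:
                if j in state:
                    continue
                child = path + (j,)
                child_set = frozenset(child)
                if child_set in closed:
                    continue
                score = fitness(child_set)
                if len(child) == budget and (
                    best_full is None or score > best_full[0]
                ):
                    best_full = (score, child)
                if score > best_heuristic:
                    best_heuristic = score
                    improved = True
                heapq.heappush(open_heap, (-score, next(counter), child))
        stale = 0 if improved else stale + 1
    if best_full is None:  # tiny pools: fall back to exhaustive budget subsets
        combos = itertools.combinations(pool, budget)
        best_full = max(
            ((fitness(frozenset(c)), c) for c in combos), key=lambda t: t[0]
        )
    return list(best_full[1])


def select_variables(
    model: RegressorSpec,
    data: CohortTable,
    budget: int,
    ga_params: GAParams | None = None,
    seed: int = 0,
    candidates: Sequence[VariableKey] | None = None,
    final_folds: int = 10,
    final_reps: int = 5,
) -> SelectionResult:
    """Wrapper selection of exactly ``budget`` variables for one model.

    A genetic algorithm over bitmasks (fitness = cross-validated accuracy)
    picks a promising pool; a best-first forward search with backtracking
    restricted to that pool returns the final set, which is then re-scored
    with the full repeated cross-validation.  Fully seeded.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    candidates = list(candidates) if candidates is not None else data.variables
    if budget > len(candidates):
        raise ValueError(f"budget {budget} exceeds {len(candidates)} candidates")
    ga = ga_params or GAParams()

    if budget == len(candidates):
        chosen = list(candidates)
        cv = cross_validate(model, data, chosen, final_folds, final_reps, seed)
        return SelectionResult(model, chosen, cv, {"search": "degenerate (budget = candidates)"})

    fitness = _FitnessCache(model, data, candidates, ga, seed)
    rng = np.random.default_rng(seed)
    density = (
        ga.init_density
        if ga.init_density is not None
        else min(0.5, max(5, 2 * budget) / len(candidates))
    )
    _, pool_mask = _ga_search(fitness, len(candidates), ga, rng, density)
    pool = list(np.flatnonzero(pool_mask))
    if len(pool) < budget:
        pool = list(range(len(candidates)))
    chosen_idx = _best_first(fitness, pool, budget, ga.stale_limit)
    chosen = [candidates[i] for i in chosen_idx]
    cv = cross_validate(model, data, chosen, final_folds, final_reps, seed)
    return SelectionResult(
        model,
        chosen,
        cv,
        {
            "ga_pool_size": len(pool),
            "fitness_evaluations": fitness.evaluations,
            "pool": [candidates[i].column for i in pool],
        },
    )


def compare_models(
    models: Sequence[RegressorSpec],
    data: CohortTable,
    budget: int,
    ga_params: GAParams | None = None,
    seed: int = 0,
    candidates: Sequence[VariableKey] | None = None,
) -> list[SelectionResult]:
    """Run selection per model; rank ascending by cross-validated accuracy."""
    if not models:
        raise ValueError("need at least one model")
    results = [
        select_variables(m, data, budget, ga_params, seed, candidates) for m in models
    ]
    return sorted(results, key=lambda r: r.cv.accuracy_mean)


def budget_sweep(
    model: RegressorSpec,
    data: CohortTable,
    budgets: Sequence[int] = (2, 3, 4, 5),
    ga_params: GAParams | None = None,
    seed: int = 0,
    candidates: Sequence[VariableKey] | None = None,
) -> dict[int, SelectionResult]:
    """Selection at each budget, exposing the cross-validation turn-over."""
    return {
        b: select_variables(model, data, b, ga_params, seed, candidates)
        for b in budgets
    }


# ---------------------------------------------------------------------------
# Final index
# ---------------------------------------------------------------------------

@dataclass
class IndexModel:
    """A trained severity index: rat record -> predicted %TBSA (unclipped)."""

    model: RegressorSpec
    variables: list[VariableKey]
    estimator: object
    training_rae: float
    n_train: int

    def predict(self, record) -> np.ndarray:
        """Predict %TBSA for a DataFrame, CohortTable, or single mapping."""
        cols = [v.column for v in self.variables]
        if isinstance(record, CohortTable):
            X = record.values[cols].to_numpy(float)
        elif isinstance(record, pd.DataFrame):
            X = record[cols].to_numpy(float)
        elif isinstance(record, Mapping):
            X = np.array([[float(record[c]) for c in cols]])
        else:
            X = np.atleast_2d(np.asarray(record, float))
        if not np.isfinite(X).all():
            raise CohortError("non-finite inputs to the severity index")
        return self.estimator.predict(X)


def train_index(
    model: RegressorSpec, data: CohortTable, variables: Sequence[VariableKey]
) -> IndexModel:
    """Fit the index on all provided data and report its training RAE."""
    X, y = _design(data, variables)
    est = make_regressor(model, X.shape[1])
    est.fit(X, y)
    training_rae = rae(est.predict(X), y)
    return IndexModel(model, list(variables), est, training_rae, len(y))
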
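"""Round-based progressive search over algorithms, feature-selection
techniques and hyper-parameter values.

The search proceeds in rounds on nested training samples that double in
size, with a fixed search-guidance test sample.  Round 1 tests each
algorithm's default configuration plus a fixed number of random ones
(plus top-up tests so every feature evaluator gets a minimum number of
trials); later rounds test surrogate-guided proposals.  The highest
quality reached by an algorithm (its *potential*) drives elimination:
survivor sets shrink weakly until the full-data round keeps only the
argmax.  Feature evaluators are eliminated the same way, one per round,
until at most a fixed number remain.  Overly slow candidate tests are
skipped by a multiplicative runtime model; a fraction of random-pool
candidates is screened on the cheap round-1 sample; the top survivors
are refined at the end along costly-but-better hyper-parameter
directions, and a forward-selection ensemble is built from the model
library.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesClassifier, ExtraTreesRegressor
from sklearn.impute import SimpleImputer
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.linear_model import LinearRegression

from .aggregation import information_gain, variance_reduction
from .data_model import ConfigError, InstanceTable, default_initial_size, \
    make_schedule
from .projection import AccuracyCurve
from .runtime import RuntimePredictor
from .space import Configuration, SearchSpace
from .surrogate import fit_surrogate, propose_candidates, top_ei_from_pool

MOD = 2 ** 31 - 1


def _child_seed(seed: int, *parts: int) -> int:
    s = seed % MOD
    for p in parts:
        s = (s * 104729 + p * 7919 + 17) % MOD
    return s


@dataclass
class TrialResult:
    """Outcome of testing one configuration at one training-sample size."""

    config: Configuration
    round_index: int
    size: int
    quality: float | None
    wall_time: float
    status: str                 # completed | skipped | failed | estimated
    seed: int
    screen: bool = False        # tested on the round-1 sample for screening

    @property
    def counts_for_potential(self) -> bool:
        return self.status == "completed"


# ---------------------------------------------------------------------------
# feature handling
# ---------------------------------------------------------------------------

def _encode_features(X) -> tuple[np.ndarray, list[str]]:
    """DataFrame -> float matrix; categorical columns become sorted-level
    integer codes, missing values become NaN."""
    if isinstance(X, np.ndarray):
        return np.asarray(X, dtype=float), [f"x{i}" for i in
                                            range(X.shape[1])]
    X = pd.DataFrame(X)
    cols = []
    names = list(X.columns.astype(str))
    for c in X.columns:
        col = X[c]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(pd.to_numeric(col).to_numpy(dtype=float))
        else:
            levels = sorted((v for v in col.dropna().unique()), key=str)
            code = {v: float(i) for i, v in enumerate(levels)}
            cols.append(np.asarray([code.get(v, np.nan) for v in col]))
    return np.column_stack(cols) if cols else np.empty((len(X), 0)), names


def _evaluator_scores(evaluator: str, X, y, task: str, seed: int
                      ) -> np.ndarray:
    rel = information_gain if task == "classification" else variance_reduction
    if evaluator == "infogain":
        return np.asarray([rel(X[:, j], y) for j in range(X.shape[1])])
    if evaluator == "correlation":
        yv = pd.factorize(y)[0] if task == "classification" else \
            np.asarray(y, dtype=float)
        out = []
        for j in range(X.shape[1]):
            x = X[:, j]
            sd = np.nanstd(x)
            if sd == 0 or np.std(yv) == 0:
                out.append(0.0)
            else:
                xm = np.where(np.isnan(x), np.nanmean(x), x)
                out.append(abs(float(np.corrcoef(xm, yv)[0, 1])))
        return np.asarray(out)
    if evaluator == "variance":
        return np.asarray([np.nanvar(X[:, j]) for j in range(X.shape[1])])
    if evaluator == "model_importance":
        cls = (ExtraTreesClassifier if task == "classification"
               else ExtraTreesRegressor)
        m = cls(n_estimators=25, random_state=seed)
        Xi = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
        m.fit(Xi, y)
        return m.feature_importances_
    if evaluator == "anova":
        from sklearn.feature_selection import f_classif, f_regression
        Xi = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
        fn = f_classif if task == "classification" else f_regression
        with np.errstate(invalid="ignore", divide="ignore"):
            f, _ = fn(Xi, y)
        return np.nan_to_num(f)
    if evaluator == "mutual_info":
        from sklearn.feature_selection import (mutual_info_classif,
                                               mutual_info_regression)
        Xi = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
        fn = (mutual_info_classif if task == "classification"
              else mutual_info_regression)
        return fn(Xi, y, random_state=seed)
    raise ConfigError(f"unknown evaluator {evaluator!r}")


def select_features(X, y, config: Configuration, task: str, seed: int,
                    mandatory: np.ndarray | None = None) -> np.ndarray:
    """Column indices kept by the configuration's FS technique; mandatory
    columns are always kept and never submitted to selection."""
    d = X.shape[1]
    mandatory = (np.zeros(d, dtype=bool) if mandatory is None
                 else np.asarray(mandatory, dtype=bool))
    free = np.flatnonzero(~mandatory)
    if config.fs_evaluator == "none" or d == 0 or len(free) == 0:
        return np.arange(d)
    scores = _evaluator_scores(config.fs_evaluator, X[:, free], y, task,
                               seed)
    k_frac = config.fs_params_dict().get("k_frac", 0.5)
    k = max(1, int(round(k_frac * len(free))))
    if config.fs_search == "greedy_forward":
        chosen = _greedy_forward(X[:, free], y, scores, min(k, 8), task,
                                 seed)
    else:  # top_k ranker
        chosen = np.argsort(-scores, kind="stable")[:k]
    keep = np.concatenate([np.flatnonzero(mandatory), free[chosen]])
    return np.sort(keep.astype(int))


def _greedy_forward(X, y, scores, k, task, seed):
    """Forward selection over the 12 best-ranked columns, scored by a fast
    proxy model on an internal split."""
    pool = list(np.argsort(-scores, kind="stable")[:12])
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.permutation(n)
    cut = max(1, int(0.75 * n))
    tr, va = idx[:cut], idx[cut:]
    y_arr = np.asarray(y)
    Xi = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
    Xi = np.where(np.isnan(Xi), 0.0, Xi)

    def score(cols):
        if not cols or len(va) == 0:
            return -np.inf
        proxy = GaussianNB() if task == "classification" \
            else LinearRegression()
        try:
            proxy.fit(Xi[np.ix_(tr, cols)], y_arr[tr])
            pred = proxy.predict(Xi[np.ix_(va, cols)])
            if task == "classification":
                return float(np.mean(pred == y_arr[va]))
            return float(-np.mean((pred - y_arr[va]) ** 2))
        except Exception:
            return -np.inf

    chosen: list[int] = []
    current = -np.inf
    while pool and len(chosen) < k:
        cand = max(pool, key=lambda j: (score(chosen + [j]), -j))
        s = score(chosen + [cand])
        if s < current:
            break
        current = s
        chosen.append(cand)
        pool.remove(cand)
    return np.asarray(chosen if chosen else [int(np.argmax(scores))])


def prefilter_features(X, y, task: str, feature_names, mandatory=(),
                       top_k: int | None = None, threshold: float = 1e-12,
                       sample_size: int = 5000, seed: int = 0) -> list[str]:
    """Fast relevance pre-filter on a sizeable sample: mandatory features
    are always kept; the rest survive iff their information gain (or
    variance reduction) clears the threshold, or ranks in the top-k."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n > sample_size:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=sample_size, replace=False)
        X, y = X[idx], y[idx]
    rel = information_gain if task == "classification" else variance_reduction
    scores = np.asarray([rel(X[:, j], y) for j in range(X.shape[1])])
    mand = set(mandatory)
    kept = []
    if top_k is not None:
        order = set(np.argsort(-scores, kind="stable")[:top_k].tolist())
        for j, name in enumerate(feature_names):
            if name in mand or j in order:
                kept.append(name)
    else:
        for j, name in enumerate(feature_names):
            if name in mand or scores[j] > threshold:
                kept.append(name)
    return kept


# ---------------------------------------------------------------------------
# trained models and ensembling
# ---------------------------------------------------------------------------

class TrainedModel:
    """Imputer + FS column subset + fitted learner, with a uniform score
    surface: class-probability-like matrix for classifiers, predictions
    for regressors."""

    def __init__(self, config, estimator, imputer, fs_cols, classes, task):
        self.config = config
        self.estimator = estimator
        self.imputer = imputer
        self.fs_cols = fs_cols
        self.classes = classes
        self.task = task

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        return self.imputer.transform(X)[:, self.fs_cols]

    def score_matrix(self, X) -> np.ndarray:
        Z = self._prep(X)
        if self.task == "regression":
            return self.estimator.predict(Z)
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(Z)
        s = self.estimator.decision_function(Z)
        if s.ndim == 1:  # min-max to a [0,1] two-column surface
            lo, hi = float(s.min()), float(s.max())
            p1 = (s - lo) / (hi - lo) if hi > lo else np.full_like(s, 0.5)
            return np.column_stack([1 - p1, p1])
        e = np.exp(s - s.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X):
        if self.task == "regression":
            return self.score_matrix(X)
        return self.classes[np.argmax(self.score_matrix(X), axis=1)]


def quality_of(scores, y, task: str, classes=None) -> float:
    if task == "regression":
        return float(r2_score(y, scores))
    if scores.shape[1] == 2:
        return float(roc_auc_score(y, scores[:, 1]))
    return float(roc_auc_score(y, scores, multi_class="ovr",
                               average="macro", labels=classes))


def train_model(config: Configuration, space: SearchSpace, Xtr, ytr,
                task: str, seed: int, mandatory=None) -> TrainedModel:
    imputer = SimpleImputer(strategy="median", keep_empty_features=True)
    Xi = imputer.fit_transform(np.asarray(Xtr, dtype=float))
    cols = select_features(Xi, ytr, config, task, seed, mandatory=mandatory)
    est = space.algorithms[config.algorithm].make(config.params_dict(), seed)
    est.fit(Xi[:, cols], ytr)
    classes = getattr(est, "classes_", None)
    return TrainedModel(config, est, imputer, cols, classes, task)


@dataclass
class EnsembleModel:
    """Forward-selection-with-replacement ensemble; member weights are
    selection counts over total selections."""

    members: list            # TrainedModel
    counts: list
    task: str
    classes: object = None

    @property
    def weights(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()

    def score_matrix(self, X=None) -> np.ndarray:
        w = self.weights
        out = None
        for wi, m in zip(w, self.members):
            s = m.score_matrix(X)
            out = wi * s if out is None else out + wi * s
        return out

    def predict(self, X):
        if self.task == "regression":
            return self.score_matrix(X)
        return self.classes[np.argmax(self.score_matrix(X), axis=1)]


def build_ensemble(library, y_sel, task: str, iterations: int = 20,
                   cached_scores=None) -> EnsembleModel:
    """Caruana-style hillclimb on the selection sample, initialized with
    the single best model; the returned ensemble's selection quality is
    never below the best single model's."""
    if not library:
        raise ConfigError("empty model library")
    scores = (cached_scores if cached_scores is not None
              else [m.score_matrix(None) for m in library])
    classes = library[0].classes
    quals = [quality_of(s, y_sel, task, classes) for s in scores]
    best_i = int(np.argmax(quals))
    counts = np.zeros(len(library), dtype=int)
    counts[best_i] = 1
    total = scores[best_i].copy().astype(float)
    best_state = (counts.copy(), quals[best_i])
    for _ in range(iterations):
        cand_q = []
        for j in range(len(library)):
            mix = (total + scores[j]) / (counts.sum() + 1)
            cand_q.append(quality_of(mix, y_sel, task, classes))
        j = int(np.argmax(cand_q))
        counts[j] += 1
        total = total + scores[j]
        if cand_q[j] > best_state[1]:
            best_state = (counts.copy(), cand_q[j])
    counts, _ = best_state
    keep = np.flatnonzero(counts)
    return EnsembleModel([library[i] for i in keep],
                         [int(counts[i]) for i in keep], task, classes)


# ---------------------------------------------------------------------------
# elimination rules
# ---------------------------------------------------------------------------

def eliminate_algorithms(potentials: dict, delta: float,
                         min_survivors: int = 2,
                         final: bool = False) -> list[str]:
    """Survivors = algorithms within ``delta`` of the best potential; at
    least ``min_survivors`` are kept except for the full-data round, which
    keeps exactly the argmax.  Algorithms with no completed trial have
    potential -inf."""
    if not potentials:
        return []
    items = sorted(potentials.items(),
                   key=lambda kv: (-(kv[1] if kv[1] is not None
                                     else -np.inf), kv[0]))
    best = items[0][1]
    if final:
        return [items[0][0]]
    survivors = [a for a, p in items
                 if p is not None and p >= best - delta]
    i = len(survivors)
    while len(survivors) < min_survivors and i < len(items):
        survivors.append(items[i][0])
        i += 1
    return survivors


def eliminate_evaluators(ledger, evaluators: list[str],
                         max_keep: int = 4, min_tests: int = 20
                         ) -> list[str]:
    """Drop the lowest-potential feature evaluator (one per call) once
    every evaluator has at least ``min_tests`` completed-or-skipped trials
    and more than ``max_keep`` remain.  The pass-through technique
    ("none") is not an evaluator and is never dropped."""
    real = [e for e in evaluators if e != "none"]
    if len(real) <= max_keep:
        return list(evaluators)
    counts = {e: 0 for e in real}
    pot = {e: -np.inf for e in real}
    for t in ledger:
        e = t.config.fs_evaluator
        if e in counts and t.status in ("completed", "skipped", "failed"):
            counts[e] += 1
            if t.counts_for_potential and t.quality is not None:
                pot[e] = max(pot[e], t.quality)
    if any(counts[e] < min_tests for e in real):
        return list(evaluators)
    worst = min(real, key=lambda e: (pot[e], e))
    return [e for e in evaluators if e != worst]


def scale_accuracy(q_small: float, algorithm: str, ledger,
                   size_small: int, size_cur: int) -> float:
    """Rough estimate of a small-sample quality at the current size: add
    the mean uplift among configurations completed at both sizes (that
    algorithm first, then any algorithm), clipped to [0, 1]."""
    def uplifts(trials):
        by_cfg: dict = {}
        for t in trials:
            if t.status != "completed" or t.quality is None:
                continue
            by_cfg.setdefault(t.config.key(), {})[t.size] = t.quality
        out = []
        for sizes in by_cfg.values():
            if size_small in sizes and size_cur in sizes:
                out.append(sizes[size_cur] - sizes[size_small])
        return out

    ups = uplifts([t for t in ledger if t.config.algorithm == algorithm])
    if not ups:
        ups = uplifts(ledger)
    est = q_small + (float(np.mean(ups)) if ups else 0.0)
    return float(np.clip(est, 0.0, 1.0))


def screen_random_group(candidates, round1_qualities, group_size: int = 10,
                        seed: int = 0):
    """Split screened candidates into the top ``group_size`` by round-1
    quality (ties broken by a seeded shuffle) and the remainder, which
    will only contribute scaled estimates."""
    rng = np.random.default_rng(seed)
    jitter = rng.permutation(len(candidates))
    order = sorted(range(len(candidates)),
                   key=lambda i: (-(round1_qualities[i]
                                    if round1_qualities[i] is not None
                                    else -np.inf), jitter[i]))
    top = [candidates[i] for i in order[:group_size]]
    rest = [(candidates[i], round1_qualities[i])
            for i in order[group_size:]]
    return top, rest


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    best_config: Configuration
    best_quality: float
    ledger: list
    curve: AccuracyCurve
    ensemble: EnsembleModel | None
    holdout_quality: float | None
    surviving_algorithms: list
    surviving_evaluators: list
    n_full_size_trials: int


class ProgressiveSearchCV(BaseEstimator):
    """Automatic joint selection of algorithm, feature-selection technique
    and hyper-parameter values by progressive sampling.

    Parameters largely mirror the method's quoted defaults: 20 random
    configurations per algorithm in round 1, candidate groups of 10 + 10
    from local search and a 10,000-point random pool, screening of 30
    random-pool candidates on the round-1 sample from round 3 on, at most
    4 surviving feature evaluators judged only after 20 tests each, skip
    factor ``f = 2`` over the per-test time limit ``T`` (doubling each
    round), and an elimination margin ``delta_1 = 0.10`` halving each
    round.

    After ``fit``, ``best_config_``, ``best_model_``, ``ensemble_``,
    ``ledger_``, ``curve_`` and ``holdout_quality_`` describe the search.
    ``predict`` / ``predict_proba`` use the final (ensemble) model.
    """

    def __init__(self, space=None, task=None, seed=0, workers=1,
                 deterministic=True, n_random=20, group_size=10,
                 random_pool_size=10_000, screen_from_round=3,
                 screen_count=30, delta1=0.10, min_survivors=2,
                 max_keep_evaluators=4, min_evaluator_tests=20,
                 f=2.0, T0=10.0, m=3, g=20, initial_size=None,
                 test_fraction=0.2, holdout_fraction=0.2, max_rounds=None,
                 mandatory_features=(), prefilter=False, prefilter_top_k=None,
                 refine_budget=8, refine_eps=1e-3, ensemble_iterations=20,
                 model_library_size=20, retrain_top_k=0, final_top_k=3,
                 algorithms=None, fs_evaluators=None):
        self.space = space
        self.task = task
        self.seed = seed
        self.workers = workers
        self.deterministic = deterministic
        self.n_random = n_random
        self.group_size = group_size
        self.random_pool_size = random_pool_size
        self.screen_from_round = screen_from_round
        self.screen_count = screen_count
        self.delta1 = delta1
        self.min_survivors = min_survivors
        self.max_keep_evaluators = max_keep_evaluators
        self.min_evaluator_tests = min_evaluator_tests
        self.f = f
        self.T0 = T0
        self.m = m
        self.g = g
        self.initial_size = initial_size
        self.test_fraction = test_fraction
        self.holdout_fraction = holdout_fraction
        self.max_rounds = max_rounds
        self.mandatory_features = mandatory_features
        self.prefilter = prefilter
        self.prefilter_top_k = prefilter_top_k
        self.refine_budget = refine_budget
        self.refine_eps = refine_eps
        self.ensemble_iterations = ensemble_iterations
        self.model_library_size = model_library_size
        self.retrain_top_k = retrain_top_k
        self.final_top_k = final_top_k
        self.algorithms = algorithms
        self.fs_evaluators = fs_evaluators

    # -- public API ---------------------------------------------------------

    def fit(self, X, y, feature_names=None):
        t_start = time.perf_counter()
        Xm, names = _encode_features(X)
        if feature_names is not None:
            names = list(feature_names)
        y = np.asarray(y)
        task = self.task or ("regression" if np.issubdtype(
            y.dtype, np.floating) and len(np.unique(y)) > 20
            else "classification")
        space = self.space or SearchSpace(task=task)
        if self.algorithms is not None:
            space = space.restrict(self.algorithms)
        if self.fs_evaluators is not None:
            space = SearchSpace(list(space.algorithms.values()),
                                self.fs_evaluators,
                                space.fs_search_methods, task)
        if not space.algorithms:
            raise ConfigError("empty search space")

        if self.prefilter:
            kept = prefilter_features(
                Xm, y, task, names, mandatory=self.mandatory_features,
                top_k=self.prefilter_top_k, seed=self.seed)
            keep_idx = [i for i, nm in enumerate(names) if nm in set(kept)]
            Xm, names = Xm[:, keep_idx], [names[i] for i in keep_idx]
        mandatory_mask = np.asarray(
            [nm in set(self.mandatory_features) for nm in names], bool)

        n = len(y)
        ids = np.arange(n)
        labels = ({i: y[i] for i in ids} if task == "classification"
                  else None)
        schedule = make_schedule(
            ids, self.initial_size or default_initial_size(
                n, len(np.unique(y)) if task == "classification" else 2),
            self.test_fraction, _child_seed(self.seed, 1),
            stratify_labels=labels)
        # carve an untouched holdout out of the guidance test sample
        rng = np.random.default_rng(_child_seed(self.seed, 2))
        test_ids = np.asarray(schedule.test_ids)
        rng.shuffle(test_ids)
        k_hold = int(round(self.holdout_fraction * len(test_ids)))
        holdout_ids, guide_ids = test_ids[:k_hold], test_ids[k_hold:]
        Xg, yg = Xm[guide_ids], y[guide_ids]
        Xh, yh = Xm[holdout_ids], y[holdout_ids]

        R = schedule.n_rounds
        if self.max_rounds is not None:
            R = min(R, self.max_rounds)
        ledger: list[TrialResult] = []
        curve = AccuracyCurve(g=self.g)
        models: dict[int, TrainedModel] = {}      # trial index -> model
        guide_scores: dict[int, np.ndarray] = {}  # trial index -> scores
        evaluators = list(space.fs_evaluators)
        surviving = sorted(space.algorithms)
        predictors = {a: RuntimePredictor(
            space.algorithms[a], space.encoder(a, evaluators), f=self.f)
            for a in surviving}
        T = self.T0
        classes = np.unique(y) if task == "classification" else None

        def run_one(config, size, rnd, seed, screen=False):
            tr_ids = schedule.train_ids(rnd)[:size] if not screen else \
                schedule.train_ids(0)
            t0 = time.perf_counter()
            try:
                mdl = train_model(config, space, Xm[tr_ids], y[tr_ids],
                                  task, seed, mandatory=mandatory_mask)
                sc = mdl.score_matrix(Xg)
                q = quality_of(sc, yg, task, classes)
                if not np.isfinite(q):
                    raise ValueError("non-finite quality")
                wall = time.perf_counter() - t0
                return TrialResult(config, rnd, len(tr_ids), q, wall,
                                   "completed", seed, screen), mdl, sc
            except Exception:
                wall = time.perf_counter() - t0
                return TrialResult(config, rnd, size, None, wall,
                                   "failed", seed, screen), None, None

        def execute(cands, rnd, size, screen=False):
            """Work-queue execution: candidates fully generated first, then
            dispatched over ``workers``; results keep submission order so
            the ledger replays identically for any worker count."""
            todo = []
            for i, cfg in enumerate(cands):
                pred = predictors[cfg.algorithm]
                seed_i = _child_seed(self.seed, rnd + 3, i)
                if not screen and pred.baseline_time is not None and \
                        pred.should_skip(cfg, size, T):
                    ledger.append(TrialResult(cfg, rnd, size, None, 0.0,
                                              "skipped", seed_i))
                    continue
                todo.append((cfg, seed_i))
            if self.workers > 1 and len(todo) > 1:
                results = Parallel(n_jobs=self.workers,
                                   backend="threading")(
                    delayed(run_one)(cfg, size, rnd, sd, screen)
                    for cfg, sd in todo)
            else:
                results = [run_one(cfg, size, rnd, sd, screen)
                           for cfg, sd in todo]
            out = []
            for trial, mdl, sc in results:
                idx = len(ledger)
                ledger.append(trial)
                is_default = trial.config.provenance == "default"
                if trial.status == "completed":
                    predictors[trial.config.algorithm].record(
                        trial.config, trial.size, trial.wall_time,
                        is_default=is_default)
                    if not trial.screen:
                        tc = time.perf_counter() - t_start
                        if curve.t and tc <= curve.t[-1]:
                            tc = curve.t[-1] * (1 + 1e-9) + 1e-9
                        curve.record_point(tc, trial.quality)
                    models[idx] = mdl
                    guide_scores[idx] = sc
                out.append((idx, trial))
            return out

        def potentials():
            pot = {a: None for a in surviving}
            for t in ledger:
                a = t.config.algorithm
                if a in pot and t.counts_for_potential and \
                        t.quality is not None and not t.screen:
                    pot[a] = t.quality if pot[a] is None else \
                        max(pot[a], t.quality)
            return pot

        executed_rounds = 0
        round_history: list[dict] = []
        for rnd in range(R):
            size = schedule.sizes[rnd]
            is_final_round = rnd == R - 1
            if rnd == 0:
                cands = []
                for a in surviving:
                    cands.append(space.default_configuration(a))
                    cands += space.sample_random(
                        a, self.n_random, _child_seed(self.seed, 100, rnd,
                                                      hash(a) % MOD),
                        evaluators=evaluators)
                # evaluator top-up: every evaluator gets min_tests trials
                counts = {e: 0 for e in evaluators if e != "none"}
                for c in cands:
                    if c.fs_evaluator in counts:
                        counts[c.fs_evaluator] += 1
                for e, cnt in sorted(counts.items()):
                    need = self.min_evaluator_tests - cnt
                    j = 0
                    while need > 0:
                        a = surviving[j % len(surviving)]
                        extra = space.sample_random(
                            a, 1, _child_seed(self.seed, 200, j,
                                              hash(e) % MOD),
                            evaluators=[e])[0]
                        if extra.fs_evaluator == e:
                            cands.append(extra)
                            need -= 1
                        j += 1
            elif is_final_round:
                # full-data round: re-test only the best few configurations
                # found so far for the surviving algorithm(s)
                ranked = sorted(
                    (t for t in ledger if t.status == "completed"
                     and not t.screen and t.quality is not None
                     and t.config.algorithm in surviving),
                    key=lambda t: -t.quality)
                cands, seen = [], set()
                for t in ranked:
                    if t.config.key() not in seen:
                        seen.add(t.config.key())
                        cands.append(t.config)
                    if len(cands) >= self.final_top_k:
                        break
            else:
                cands = []
                for a in surviving:
                    enc = space.encoder(a, evaluators)
                    alg_trials = [t for t in ledger
                                  if t.config.algorithm == a
                                  and t.config.fs_evaluator in evaluators
                                  and t.status in ("completed", "estimated")]
                    sm = fit_surrogate(a, alg_trials, enc,
                                       seed=_child_seed(self.seed, 300, rnd))
                    pot = potentials().get(a)
                    best = pot if pot is not None else 0.0
                    random_group = None
                    if rnd + 1 >= self.screen_from_round and sm.defined:
                        pool30 = top_ei_from_pool(
                            sm, space, alg_trials, best, size,
                            _child_seed(self.seed, 400, rnd), self.screen_count,
                            evaluators=evaluators,
                            n_random_pool=self.random_pool_size)
                        screened = execute(pool30, rnd, schedule.sizes[0],
                                           screen=True)
                        quals = [t.quality for _, t in screened]
                        cfgs = [t.config for _, t in screened]
                        top, rest = screen_random_group(
                            cfgs, quals, self.group_size,
                            _child_seed(self.seed, 500, rnd))
                        for cfg, q_small in rest:
                            if q_small is None:
                                continue
                            est = scale_accuracy(q_small, a, ledger,
                                                 schedule.sizes[0], size)
                            ledger.append(TrialResult(
                                cfg, rnd, size, est, 0.0, "estimated",
                                _child_seed(self.seed, 600, rnd)))
                        random_group = top
                        alg_trials = [t for t in ledger
                                      if t.config.algorithm == a
                                      and t.config.fs_evaluator in evaluators
                                      and t.status in ("completed",
                                                       "estimated")]
                        sm = fit_surrogate(a, alg_trials, enc,
                                           seed=_child_seed(self.seed, 300,
                                                            rnd))
                    cands += propose_candidates(
                        sm, space, alg_trials, best, size,
                        _child_seed(self.seed, 700, rnd), evaluators=evaluators,
                        n_random_pool=self.random_pool_size,
                        group_size=self.group_size,
                        random_group=random_group)
            tested_keys = {t.config.key() for t in ledger
                           if t.status == "completed" and t.size == size}
            cands = [c for c in cands if (c.key(), size) not in
                     {(t.config.key(), t.size) for t in ledger
                      if t.status == "completed"}]
            del tested_keys
            execute(cands, rnd, size)
            executed_rounds += 1

            # prune the model library to the best recent trials
            if len(models) > self.model_library_size:
                order = sorted(models, key=lambda i: -(
                    ledger[i].quality if ledger[i].quality is not None
                    else -np.inf))
                for i in order[self.model_library_size:]:
                    models.pop(i)
                    guide_scores.pop(i, None)

            pot_snapshot = dict(potentials())
            evaluators = eliminate_evaluators(
                ledger, evaluators, self.max_keep_evaluators,
                self.min_evaluator_tests)
            if not is_final_round:
                delta = self.delta1 * 2.0 ** (-rnd)
                final_next = rnd + 1 == R - 1
                pot = potentials()
                surviving = eliminate_algorithms(
                    {a: pot[a] for a in surviving}, delta,
                    min_survivors=(1 if final_next else self.min_survivors),
                    final=final_next)
            round_history.append({"round": rnd, "size": size,
                                  "potentials": pot_snapshot,
                                  "survivors": list(surviving),
                                  "evaluators": list(evaluators)})
            T *= 2.0

        completed = [(i, t) for i, t in enumerate(ledger)
                     if t.status == "completed" and not t.screen]
        if not completed:
            raise ConfigError("every trial failed; no model available")
        best_idx, best_trial = max(completed,
                                   key=lambda it: (it[1].quality, -it[0]))

        # retrain the winner on the full training pool (already done if the
        # winning trial ran at full size)
        full_ids = schedule.train_ids(min(executed_rounds,
                                          schedule.n_rounds) - 1)
        n_full = sum(1 for t in ledger if t.status == "completed"
                     and t.size == len(full_ids))
        if best_trial.size == len(full_ids) and best_idx in models:
            best_model = models[best_idx]
            best_quality = best_trial.quality
        else:
            best_model = train_model(best_trial.config, space, Xm[full_ids],
                                     y[full_ids], task,
                                     _child_seed(self.seed, 900),
                                     mandatory=mandatory_mask)
            best_quality = quality_of(best_model.score_matrix(Xg), yg, task,
                                      classes)
            n_full += 1
            if best_quality < best_trial.quality and best_idx in models:
                # keep the better of retrained vs searched model
                best_model = models[best_idx]
                best_quality = best_trial.quality

        # refinement along costly-but-better hyper-parameter directions
        best_model, best_quality, n_ref = self._refine(
            space, surviving, ledger, best_model, best_quality,
            Xm, y, full_ids, Xg, yg, task, classes, mandatory_mask)
        n_full += n_ref

        # ensemble from the model library
        lib_idx = sorted(models)
        library = [models[i] for i in lib_idx]
        scores = [guide_scores[i] for i in lib_idx]
        library.append(best_model)
        scores.append(best_model.score_matrix(Xg))
        if self.retrain_top_k:
            order = np.argsort([-quality_of(s, yg, task, classes)
                                for s in scores])[:self.retrain_top_k]
            for j in order:
                mdl = train_model(library[j].config, space, Xm[full_ids],
                                  y[full_ids], task,
                                  _child_seed(self.seed, 950, int(j)),
                                  mandatory=mandatory_mask)
                library[j] = mdl
                scores[j] = mdl.score_matrix(Xg)
                n_full += 1
        ensemble = build_ensemble(library, yg, task,
                                  iterations=self.ensemble_iterations,
                                  cached_scores=scores)
        ens_quality = quality_of(ensemble.score_matrix(Xg), yg, task,
                                 classes)
        final_model = ensemble if ens_quality >= best_quality else best_model
        holdout_q = (quality_of(final_model.score_matrix(Xh), yh, task,
                                classes) if len(yh) else None)

        self.task_ = task
        self.space_ = space
        self.schedule_ = schedule
        self.guide_ids_ = np.asarray(guide_ids)
        self.holdout_ids_ = np.asarray(holdout_ids)
        self.round_history_ = round_history
        self.feature_names_ = names
        self.ledger_ = ledger
        self.curve_ = curve
        self.best_config_ = best_model.config
        self.best_model_ = best_model
        self.best_quality_ = max(best_quality, ens_quality)
        self.ensemble_ = ensemble
        self.final_model_ = final_model
        self.holdout_quality_ = holdout_q
        self.surviving_algorithms_ = list(surviving)
        self.surviving_evaluators_ = list(evaluators)
        self.n_full_size_trials_ = n_full
        self.classes_ = classes
        self.result_ = SearchResult(
            self.best_config_, self.best_quality_, ledger, curve, ensemble,
            holdout_q, list(surviving), list(evaluators), n_full)
        return self

    def _refine(self, space, surviving, ledger, best_model, best_quality,
                Xm, y, full_ids, Xg, yg, task, classes, mandatory_mask):
        """Second search along expensive-monotone hyper-parameters for the
        top algorithms: geometric moves in the flagged direction until two
        consecutive improvements fall below epsilon or the budget runs
        out; the incumbent is replaced only by a strictly better model."""
        flagged = {a: [d for d in space.algorithms[a].hyperparams
                       if d.expensive]
                   for a in space.algorithms}
        pot: dict[str, float] = {}
        for t in ledger:
            if t.status == "completed" and t.quality is not None:
                a = t.config.algorithm
                pot[a] = max(pot.get(a, -np.inf), t.quality)
        tops = [a for a in sorted(pot, key=lambda a: -pot[a])
                if flagged.get(a)][:2]
        budget = self.refine_budget
        n_trained = 0
        for a in tops:
            best_a = max((t for t in ledger if t.config.algorithm == a
                          and t.status == "completed"
                          and t.quality is not None),
                         key=lambda t: t.quality)
            cfg, q_cur = best_a.config, best_a.quality
            for d in flagged[a]:
                v = cfg.params_dict()[d.name]
                stale = 0
                while budget > 0 and stale < 2:
                    v = d.clip(v * 2 if d.direction == "up" else v / 2)
                    if v == cfg.params_dict()[d.name]:
                        break
                    cand = replace(cfg.with_params(**{d.name: v}),
                                   provenance="refined")
                    mdl = train_model(cand, space, Xm[full_ids], y[full_ids],
                                      task, _child_seed(self.seed, 960,
                                                        budget),
                                      mandatory=mandatory_mask)
                    q = quality_of(mdl.score_matrix(Xg), yg, task, classes)
                    ledger.append(TrialResult(cand, -1, len(full_ids), q,
                                              0.0, "completed",
                                              self.seed))
                    budget -= 1
                    n_trained += 1
                    if q - q_cur < self.refine_eps:
                        stale += 1
                    else:
                        stale = 0
                    if q > q_cur:
                        q_cur, cfg = q, cand
                        if q > best_quality:
                            best_quality, best_model = q, mdl
        return best_model, best_quality, n_trained

    # -- prediction ---------------------------------------------------------

    def predict(self, X):
        Xm, _ = _encode_features(X)
        return self.final_model_.predict(Xm)

    def predict_proba(self, X):
        if self.task_ != "classification":
            raise ConfigError("predict_proba needs a classification task")
        Xm, _ = _encode_features(X)
        return self.final_model_.score_matrix(Xm)

    def score(self, X, y):
        Xm, _ = _encode_features(X)
        return quality_of(self.final_model_.score_matrix(Xm), np.asarray(y),
                          self.task_, self.classes_)


def search(instances: InstanceTable, **params) -> ProgressiveSearchCV:
    """Run the progressive search on a wide instance table."""
    if instances.target is None:
        raise ConfigError("instance table has no target column")
    frame = instances.frame
    feats = [c for c in instances.feature_columns if c != "patient_id"]
    if not feats:
        raise ConfigError("no feature columns")
    task = ("classification" if instances.target_type == "categorical"
            else "regression")
    est = ProgressiveSearchCV(task=task, **params)
    y = frame[instances.target]
    y = y.to_numpy() if task == "classification" else \
        y.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(frame[feats], y, feature_names=feats)
    return est
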
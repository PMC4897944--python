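"""Joint search space over learning algorithms, feature-selection
techniques and hyper-parameter values.

A :class:`Configuration` is one point of the joint space: an algorithm, a
full hyper-parameter assignment, and a feature-selection technique (search
method x evaluator) — the technique choice is itself treated as a
hyper-parameter.  The space supports default/random/neighbor generation and
a per-algorithm numeric encoding for the regression surrogate; each
algorithm's encoding excludes every other algorithm's hyper-parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import (GradientBoostingClassifier,
                              GradientBoostingRegressor,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.linear_model import LogisticRegression, Ridge
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import LinearSVC, LinearSVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .data_model import ConfigError

FS_SEARCH_METHODS = ["none", "top_k", "greedy_forward"]
FS_EVALUATORS = ["none", "infogain", "correlation", "variance",
                 "model_importance"]
GRID_STEPS = 20


@dataclass(frozen=True)
class HyperparameterDef:
    name: str
    kind: str                      # continuous | integer | categorical
    range: tuple = ()              # (lo, hi) or value list
    default: object = None
    log: bool = False
    expensive: bool = False        # costly-but-better in one direction
    direction: str | None = None   # "up" or "down"
    capped_range: tuple | None = None  # range used during the main search

    def __post_init__(self):
        if self.kind == "categorical":
            if self.default not in self.range:
                raise ConfigError(f"{self.name}: default not in values")
        else:
            lo, hi = self.range
            if not (lo <= self.default <= hi):
                raise ConfigError(f"{self.name}: default outside range")
            if self.expensive and self.kind == "categorical":
                raise ConfigError("expensive flag needs a numeric kind")

    def search_range(self, capped: bool) -> tuple:
        if capped and self.capped_range is not None:
            return self.capped_range
        return self.range

    def grid(self, capped: bool = False) -> np.ndarray:
        """20-step grid over the (possibly capped) range; log-spaced when
        flagged.  Used for neighbor perturbation and encoding round-trip."""
        lo, hi = self.search_range(capped)
        if self.log:
            pts = np.geomspace(lo, hi, GRID_STEPS)
        else:
            pts = np.linspace(lo, hi, GRID_STEPS)
        if self.kind == "integer":
            pts = np.unique(np.round(pts).astype(int))
        return pts

    def clip(self, v):
        lo, hi = self.range
        v = min(max(v, lo), hi)
        return int(round(v)) if self.kind == "integer" else float(v)

    def sample(self, rng: np.random.Generator, capped: bool):
        if self.kind == "categorical":
            return self.range[rng.integers(len(self.range))]
        lo, hi = self.search_range(capped)
        if self.log:
            v = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            v = float(rng.uniform(lo, hi))
        return int(round(v)) if self.kind == "integer" else v

    def scale01(self, v) -> float:
        if self.kind == "categorical":
            raise ConfigError("categoricals are one-hot encoded")
        lo, hi = self.range
        if self.log:
            return float((np.log(v) - np.log(lo)) /
                         (np.log(hi) - np.log(lo)))
        return float((v - lo) / (hi - lo))

    def unscale01(self, u: float):
        lo, hi = self.range
        if self.log:
            v = float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        else:
            v = float(lo + u * (hi - lo))
        return int(round(v)) if self.kind == "integer" else v


@dataclass(frozen=True)
class AlgorithmSpec:
    """A learner family: an adapter building the host estimator from a
    hyper-parameter assignment, plus the training-time complexity exponent
    ``p`` (time ∝ n^p) when known."""

    id: str
    make: object                  # callable(params: dict, seed: int) -> estimator
    hyperparams: tuple = ()
    complexity_p: float | None = 1.0
    time_linear_params: tuple = ()  # params whose cost ratio is value/default

    def defs(self) -> dict:
        return {d.name: d for d in self.hyperparams}


@dataclass(frozen=True)
class Configuration:
    """One candidate: algorithm + hyper-parameters + FS technique."""

    algorithm: str
    params: tuple = ()            # sorted (name, value) pairs
    fs_search: str = "none"
    fs_evaluator: str = "none"
    fs_params: tuple = ()
    provenance: str = "default"   # default | random | local | random-pool | refined

    def params_dict(self) -> dict:
        return dict(self.params)

    def fs_params_dict(self) -> dict:
        return dict(self.fs_params)

    def key(self) -> tuple:
        """Identity ignoring provenance (for dedup of tested candidates)."""
        return (self.algorithm, self.params, self.fs_search,
                self.fs_evaluator, self.fs_params)

    def with_params(self, **updates) -> "Configuration":
        d = self.params_dict()
        d.update(updates)
        return replace(self, params=tuple(sorted(d.items())))


def _cfg(algorithm, params, fs_search="none", fs_evaluator="none",
         fs_params=(), provenance="default"):
    return Configuration(algorithm, tuple(sorted(params.items())),
                         fs_search, fs_evaluator,
                         tuple(sorted(dict(fs_params).items())), provenance)


# ---------------------------------------------------------------------------
# the shipped roster
# ---------------------------------------------------------------------------

def _roster(task: str) -> list[AlgorithmSpec]:
    clf = task == "classification"

    def tree(p, seed):
        cls = DecisionTreeClassifier if clf else DecisionTreeRegressor
        return cls(max_depth=p["max_depth"],
                   min_samples_leaf=p["min_samples_leaf"], random_state=seed)

    def forest(p, seed):
        cls = RandomForestClassifier if clf else RandomForestRegressor
        return cls(n_estimators=p["n_estimators"],
                   max_features=p["max_features"], random_state=seed,
                   n_jobs=1)

    def boost(p, seed):
        cls = GradientBoostingClassifier if clf else GradientBoostingRegressor
        return cls(n_estimators=p["n_estimators"],
                   learning_rate=p["learning_rate"],
                   max_depth=p["max_depth"], random_state=seed)

    def knn(p, seed):
        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        return cls(n_neighbors=p["n_neighbors"], weights=p["weights"])

    def linear(p, seed):
        if clf:
            return LogisticRegression(C=p["C"], max_iter=2000,
                                      random_state=seed)
        return Ridge(alpha=1.0 / p["C"], random_state=seed)

    def nb(p, seed):
        return GaussianNB(var_smoothing=p["var_smoothing"])

    def svm(p, seed):
        if clf:
            return LinearSVC(C=p["C"], random_state=seed, max_iter=5000)
        return LinearSVR(C=p["C"], random_state=seed, max_iter=5000)

    roster = [
        AlgorithmSpec("decision_tree", tree, (
            HyperparameterDef("max_depth", "integer", (1, 20), 5),
            HyperparameterDef("min_samples_leaf", "integer", (1, 50), 1,
                              log=True)), complexity_p=1.0),
        AlgorithmSpec("random_forest", forest, (
            HyperparameterDef("n_estimators", "integer", (10, 500), 100,
                              expensive=True, direction="up",
                              capped_range=(10, 100)),
            HyperparameterDef("max_features", "continuous", (0.1, 1.0),
                              0.5)), complexity_p=1.0,
            time_linear_params=("n_estimators",)),
        AlgorithmSpec("gradient_boosting", boost, (
            HyperparameterDef("n_estimators", "integer", (10, 500), 100,
                              expensive=True, direction="up",
                              capped_range=(10, 100)),
            HyperparameterDef("learning_rate", "continuous", (0.01, 1.0),
                              0.1, log=True),
            HyperparameterDef("max_depth", "integer", (1, 8), 3)),
            complexity_p=1.0, time_linear_params=("n_estimators",)),
        AlgorithmSpec("knn", knn, (
            HyperparameterDef("n_neighbors", "integer", (1, 50), 5,
                              log=True),
            HyperparameterDef("weights", "categorical",
                              ("uniform", "distance"), "uniform")),
            complexity_p=2.0),
        AlgorithmSpec("logistic" if clf else "ridge", linear, (
            HyperparameterDef("C", "continuous", (1e-4, 1e4), 1.0,
                              log=True),), complexity_p=1.0),
        AlgorithmSpec("linear_svm", svm, (
            HyperparameterDef("C", "continuous", (1e-4, 1e4), 1.0,
                              log=True),), complexity_p=1.0),
    ]
    if clf:
        roster.append(AlgorithmSpec("naive_bayes", nb, (
            HyperparameterDef("var_smoothing", "continuous",
                              (1e-12, 1e-6), 1e-9, log=True),),
            complexity_p=1.0))
    return roster


_FS_K_DEF = HyperparameterDef("k_frac", "continuous", (0.1, 1.0), 0.5)


class SearchSpace:
    """Registry of algorithms and FS techniques with generation and
    per-algorithm encoding."""

    def __init__(self, algorithms=None, fs_evaluators=None,
                 fs_search_methods=None, task: str = "classification"):
        self.task = task
        roster = algorithms if algorithms is not None else _roster(task)
        self.algorithms: dict[str, AlgorithmSpec] = {a.id: a for a in roster}
        self.fs_evaluators = list(fs_evaluators if fs_evaluators is not None
                                  else FS_EVALUATORS)
        self.fs_search_methods = list(
            fs_search_methods if fs_search_methods is not None
            else FS_SEARCH_METHODS)
        if "none" not in self.fs_evaluators:
            self.fs_evaluators.insert(0, "none")
        if "none" not in self.fs_search_methods:
            self.fs_search_methods.insert(0, "none")

    def register(self, spec: AlgorithmSpec) -> None:
        self.algorithms[spec.id] = spec

    def restrict(self, algorithm_ids) -> "SearchSpace":
        missing = [a for a in algorithm_ids if a not in self.algorithms]
        if missing:
            raise ConfigError(f"unknown algorithms {missing}")
        return SearchSpace([self.algorithms[a] for a in algorithm_ids],
                           self.fs_evaluators, self.fs_search_methods,
                           self.task)

    # -- generation ---------------------------------------------------------

    def default_configuration(self, algorithm: str) -> Configuration:
        spec = self._spec(algorithm)
        return _cfg(algorithm, {d.name: d.default for d in spec.hyperparams})

    def sample_random(self, algorithm: str, k: int, seed: int,
                      evaluators=None, capped: bool = True
                      ) -> list[Configuration]:
        """k uniform draws (log-uniform where flagged); expensive-monotone
        parameters stay inside their capped range during the main search."""
        spec = self._spec(algorithm)
        rng = np.random.default_rng(seed)
        evaluators = list(evaluators if evaluators is not None
                          else self.fs_evaluators)
        out = []
        for _ in range(k):
            params = {d.name: d.sample(rng, capped)
                      for d in spec.hyperparams}
            ev = evaluators[rng.integers(len(evaluators))]
            if ev == "none":
                sm, fs_params = "none", {}
            else:
                methods = [s for s in self.fs_search_methods if s != "none"]
                sm = methods[rng.integers(len(methods))] if methods else "none"
                fs_params = {"k_frac": _FS_K_DEF.sample(rng, False)}
            out.append(_cfg(algorithm, params, sm, ev, fs_params, "random"))
        return out

    def neighbors(self, config: Configuration, seed: int = 0,
                  evaluators=None, capped: bool = True
                  ) -> list[Configuration]:
        """One-parameter perturbations: numerics move ±1 step on a 20-step
        (log) grid, categoricals and the FS technique take each alternative
        value; duplicates and the origin are dropped."""
        spec = self._spec(config.algorithm)
        evaluators = list(evaluators if evaluators is not None
                          else self.fs_evaluators)
        out, seen = [], {config.key()}

        def push(c):
            if c.key() not in seen:
                seen.add(c.key())
                out.append(replace(c, provenance="local"))

        for d in spec.hyperparams:
            v = config.params_dict()[d.name]
            if d.kind == "categorical":
                for alt in d.range:
                    if alt != v:
                        push(config.with_params(**{d.name: alt}))
            else:
                grid = d.grid(capped)
                i = int(np.argmin(np.abs(grid.astype(float) - float(v))))
                for j in (i - 1, i + 1):
                    if 0 <= j < len(grid):
                        push(config.with_params(
                            **{d.name: d.clip(grid[j])}))
        for alt in evaluators:
            if alt != config.fs_evaluator:
                c = replace(config, fs_evaluator=alt)
                if alt == "none":
                    c = replace(c, fs_search="none", fs_params=())
                elif config.fs_evaluator == "none":
                    c = replace(c, fs_search="top_k",
                                fs_params=(("k_frac", 0.5),))
                push(c)
        if config.fs_evaluator != "none":
            for alt in self.fs_search_methods:
                if alt not in ("none", config.fs_search):
                    push(replace(config, fs_search=alt))
            kf = config.fs_params_dict().get("k_frac", 0.5)
            grid = _FS_K_DEF.grid()
            i = int(np.argmin(np.abs(grid - kf)))
            for j in (i - 1, i + 1):
                if 0 <= j < len(grid):
                    push(replace(config, fs_params=(
                        ("k_frac", float(grid[j])),)))
        return out

    # -- encoding -----------------------------------------------------------

    def encoder(self, algorithm: str, evaluators=None) -> "Encoder":
        return Encoder(self._spec(algorithm), self.fs_search_methods,
                       list(evaluators if evaluators is not None
                            else self.fs_evaluators))

    def _spec(self, algorithm: str) -> AlgorithmSpec:
        if algorithm not in self.algorithms:
            raise ConfigError(f"unknown algorithm {algorithm!r}")
        return self.algorithms[algorithm]


class Encoder:
    """Numeric encoding of one algorithm's configurations: min-max scaled
    numerics (log first where flagged) and one-hot categoricals, plus the
    FS technique dims.  Dropping an evaluator from ``evaluators`` shrinks
    the encoding."""

    def __init__(self, spec: AlgorithmSpec, fs_search_methods, evaluators):
        self.spec = spec
        self.fs_search_methods = list(fs_search_methods)
        self.evaluators = list(evaluators)
        self.dim_names: list[str] = []
        for d in spec.hyperparams:
            if d.kind == "categorical":
                self.dim_names += [f"{d.name}={v}" for v in d.range]
            else:
                self.dim_names.append(d.name)
        self.dim_names += [f"fs_search={s}" for s in self.fs_search_methods]
        self.dim_names += [f"fs_evaluator={e}" for e in self.evaluators]
        self.dim_names.append("fs_k_frac")

    @property
    def dim(self) -> int:
        return len(self.dim_names)

    def encode(self, config: Configuration) -> np.ndarray:
        if config.algorithm != self.spec.id:
            raise ConfigError("encoder is per-algorithm")
        x = []
        p = config.params_dict()
        for d in self.spec.hyperparams:
            if d.kind == "categorical":
                x += [1.0 if p[d.name] == v else 0.0 for v in d.range]
            else:
                x.append(d.scale01(p[d.name]))
        x += [1.0 if config.fs_search == s else 0.0
              for s in self.fs_search_methods]
        x += [1.0 if config.fs_evaluator == e else 0.0
              for e in self.evaluators]
        x.append(config.fs_params_dict().get("k_frac", 0.5))
        return np.asarray(x, dtype=float)

    def decode(self, x: np.ndarray) -> Configuration:
        x = list(np.asarray(x, dtype=float))
        params = {}
        for d in self.spec.hyperparams:
            if d.kind == "categorical":
                vals = [x.pop(0) for _ in d.range]
                params[d.name] = d.range[int(np.argmax(vals))]
            else:
                params[d.name] = d.unscale01(x.pop(0))
        sm = self.fs_search_methods[int(np.argmax(
            [x.pop(0) for _ in self.fs_search_methods]))]
        ev = self.evaluators[int(np.argmax(
            [x.pop(0) for _ in self.evaluators]))]
        kf = x.pop(0)
        fs_params = {} if ev == "none" else {"k_frac": float(kf)}
        if ev == "none":
            sm = "none"
        return _cfg(self.spec.id, params, sm, ev, fs_params, "random")
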
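"""Per-algorithm quality surrogate and expected-improvement proposals.

A separate bagged-regression-trees model is fitted per algorithm on its
completed trials, mapping encoded configurations (plus the training-sample
size) to observed quality.  Bagging gives a predictive mean and a
cross-bag variance, which feed the expected-improvement (EI) acquisition:
``EI = E[max(Y - best, 0)]`` under ``Y ~ N(mu, sigma^2)``.

Candidates for a round come in two interleaved groups: the best neighbor
of each of the 10 previously tested configurations with the largest EI
(local search), and the 10 largest-EI configurations among 10,000 random
draws.  Before the surrogate is defined (too few trials), proposals fall
back to pure random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .data_model import ConfigError
from .space import Configuration, Encoder, SearchSpace

RANDOM_POOL_SIZE = 10_000
GROUP_SIZE = 10


@dataclass
class SurrogateModel:
    algorithm: str
    encoder: Encoder
    regressor: BaggingRegressor | None
    n_trials: int

    @property
    def defined(self) -> bool:
        return self.regressor is not None


def fit_surrogate(algorithm: str, trials, encoder: Encoder,
                  seed: int = 0, n_bags: int = 25) -> SurrogateModel:
    """Fit the bagged-trees surrogate on one algorithm's completed trials.

    ``trials`` is a sequence of objects with ``.config``, ``.size`` and
    ``.quality``.  Until ``dim + 2`` trials exist the model is undefined
    and proposals fall back to random.
    """
    completed = [t for t in trials
                 if t.quality is not None and np.isfinite(t.quality)]
    if len(completed) < encoder.dim + 2:
        return SurrogateModel(algorithm, encoder, None, len(completed))
    X = np.stack([np.append(encoder.encode(t.config), float(t.size))
                  for t in completed])
    y = np.asarray([t.quality for t in completed], dtype=float)
    reg = BaggingRegressor(DecisionTreeRegressor(random_state=0),
                           n_estimators=n_bags, random_state=seed)
    reg.fit(X, y)
    return SurrogateModel(algorithm, encoder, reg, len(completed))


def predict_mean_var(model: SurrogateModel, config: Configuration,
                     size: int) -> tuple[float, float]:
    """Predictive mean and cross-bag variance for one configuration."""
    if not model.defined:
        raise ConfigError("surrogate undefined: too few trials")
    x = np.append(model.encoder.encode(config), float(size))[None, :]
    preds = np.asarray([est.predict(x[:, feats])[0] for est, feats in
                        zip(model.regressor.estimators_,
                            model.regressor.estimators_features_)])
    return float(preds.mean()), float(preds.var())


def expected_improvement(mu: float, sigma: float, best: float) -> float:
    """Closed-form EI over ``best`` for ``Y ~ N(mu, sigma^2)``; degenerates
    to ``max(mu - best, 0)`` at ``sigma = 0``."""
    if sigma <= 0:
        return max(mu - best, 0.0)
    z = (mu - best) / sigma
    return float((mu - best) * norm.cdf(z) + sigma * norm.pdf(z))


def predict_mean_var_batch(model: SurrogateModel, configs, size: int
                           ) -> tuple[np.ndarray, np.ndarray]:
    if not model.defined:
        raise ConfigError("surrogate undefined: too few trials")
    X = np.stack([np.append(model.encoder.encode(c), float(size))
                  for c in configs])
    preds = np.stack([est.predict(X[:, feats]) for est, feats in
                      zip(model.regressor.estimators_,
                          model.regressor.estimators_features_)])
    return preds.mean(axis=0), preds.var(axis=0)


def ei_batch(model: SurrogateModel, configs, size: int, best: float
             ) -> np.ndarray:
    mu, var = predict_mean_var_batch(model, configs, size)
    sigma = np.sqrt(var)
    out = np.maximum(mu - best, 0.0)
    pos = sigma > 0
    z = np.zeros_like(mu)
    z[pos] = (mu[pos] - best) / sigma[pos]
    out[pos] = (mu[pos] - best) * norm.cdf(z[pos]) + \
        sigma[pos] * norm.pdf(z[pos])
    return out


def _ei_for(model, config, size, best):
    mu, var = predict_mean_var(model, config, size)
    return expected_improvement(mu, float(np.sqrt(var)), best)


def propose_candidates(model: SurrogateModel, space: SearchSpace,
                       tested, best: float, size: int, seed: int,
                       evaluators=None, n_random_pool: int = RANDOM_POOL_SIZE,
                       group_size: int = GROUP_SIZE,
                       random_group: list | None = None
                       ) -> list[Configuration]:
    """Interleaved candidate list for one algorithm and round.

    Group 1: for each of the ``group_size`` previously tested
    configurations with the largest EI, its best-EI untested neighbor.
    Group 2: the ``group_size`` largest-EI configurations among
    ``n_random_pool`` random ones (or ``random_group`` when screening has
    already produced it).  With an undefined surrogate, 2x``group_size``
    pure-random candidates are returned instead.
    """
    tested = list(tested)
    tested_keys = {t.config.key() for t in tested}
    if not model.defined:
        k = 2 * group_size
        return space.sample_random(model.algorithm, k, seed,
                                   evaluators=evaluators)

    tested_ei = ei_batch(model, [t.config for t in tested], size, best)
    ranked = [tested[i] for i in np.argsort(-tested_ei, kind="stable")]
    group1 = []
    g1_keys = set()
    for t in ranked[:group_size]:
        nbrs = [c for c in space.neighbors(t.config, seed=seed,
                                           evaluators=evaluators)
                if c.key() not in tested_keys and c.key() not in g1_keys]
        if not nbrs:
            continue
        bst = nbrs[int(np.argmax(ei_batch(model, nbrs, size, best)))]
        g1_keys.add(bst.key())
        group1.append(bst)

    if random_group is not None:
        group2 = [replace(c, provenance="random-pool") for c in random_group]
    else:
        pool = space.sample_random(model.algorithm, n_random_pool, seed + 1,
                                   evaluators=evaluators)
        seen_pool = set()
        pool = [c for c in pool if c.key() not in tested_keys
                and not (c.key() in seen_pool or seen_pool.add(c.key()))]
        if pool:
            eis = ei_batch(model, pool, size, best)
            order = np.argsort(-eis, kind="stable")[:group_size]
            group2 = [replace(pool[i], provenance="random-pool")
                      for i in order]
        else:
            group2 = []

    out, seen = [], set()
    for i in range(max(len(group1), len(group2))):
        for grp in (group1, group2):
            if i < len(grp) and grp[i].key() not in seen:
                seen.add(grp[i].key())
                out.append(grp[i])
    return out


def top_ei_from_pool(model: SurrogateModel, space: SearchSpace, tested,
                     best: float, size: int, seed: int, k: int,
                     evaluators=None,
                     n_random_pool: int = RANDOM_POOL_SIZE) -> list:
    """The k largest-EI configurations among a fresh random pool (the
    screening front end: 30 are drawn this way from round 3 on)."""
    if not model.defined:
        return space.sample_random(model.algorithm, k, seed,
                                   evaluators=evaluators)
    tested_keys = {t.config.key() for t in tested}
    pool = space.sample_random(model.algorithm, n_random_pool, seed,
                               evaluators=evaluators)
    seen = set()
    pool = [c for c in pool if c.key() not in tested_keys
            and not (c.key() in seen or seen.add(c.key()))]
    if not pool:
        return []
    eis = ei_batch(model, pool, size, best)
    order = np.argsort(-eis, kind="stable")[:k]
    return [pool[i] for i in order]
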
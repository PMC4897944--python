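"""Predict a candidate test's training time and skip hopeless ones.

Predicted time is multiplicative:
``baseline x size_ratio x hp_ratio`` where the baseline is the measured
time of the algorithm's default configuration on the first-round sample,
the size ratio is ``(n_new / n_base)**p`` (known complexity exponent, or
fitted from the trial log), and the hyper-parameter ratio comes from one of
two per-algorithm approaches: (A) a random-forest regression on the
encoded configuration, or (B) a product of per-hyper-parameter ratio
functions.  The approach with the lower leave-one-out absolute log-error
wins per algorithm.  A candidate predicted to need more than ``f x T``
seconds is skipped instead of started.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .data_model import ConfigError
from .space import AlgorithmSpec, Configuration, Encoder


def should_skip(predicted_time: float, T: float, f: float) -> bool:
    """Skip iff predicted time strictly exceeds ``f x T`` (``f > 1``
    tolerates prediction imprecision; at exactly ``f x T`` the test runs)."""
    if f <= 1.0:
        raise ConfigError("tolerance factor f must be > 1")
    if T <= 0:
        raise ConfigError("per-test time limit T must be > 0")
    return predicted_time > f * T


def size_ratio(p: float | None, n_new: int, n_base: int,
               observed: list | None = None) -> float:
    """``(n_new/n_base)**p``.  Unknown ``p`` is fitted as the slope of
    log-time vs log-n over completed trials at >=3 distinct sizes, else 1."""
    if p is None:
        p = 1.0
        if observed:
            ns = np.asarray([n for n, _ in observed], dtype=float)
            ts = np.asarray([t for _, t in observed], dtype=float)
            ok = (ts > 0) & (ns > 0)
            if len(np.unique(ns[ok])) >= 3:
                p = float(np.polyfit(np.log(ns[ok]), np.log(ts[ok]), 1)[0])
    return float((n_new / n_base) ** p)


def _power_ratio_fit(vals, ratios):
    """Fit ratio(v) = (v/v_def)^alpha on observed (value-ratio, time-ratio)
    pairs; alpha by least squares in log space."""
    x = np.log(np.asarray(vals, dtype=float))
    y = np.log(np.asarray(ratios, dtype=float))
    ok = np.isfinite(x) & np.isfinite(y) & (x != 0)
    if ok.sum() < 2:
        return 0.0
    return float(np.sum(x[ok] * y[ok]) / np.sum(x[ok] ** 2))


@dataclass
class RuntimePredictor:
    """Per-algorithm multiplicative time model (see module docstring)."""

    spec: AlgorithmSpec
    encoder: Encoder
    f: float = 2.0
    baseline_time: float | None = None
    baseline_size: int | None = None
    baseline_config: Configuration | None = None
    observations: list = field(default_factory=list)  # (config, size, time)
    approach: str | None = None      # "A" or "B", chosen on evidence
    _rf: RandomForestRegressor | None = None
    _power_alphas: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.f <= 1.0:
            raise ConfigError("tolerance factor f must be > 1")

    # -- bookkeeping --------------------------------------------------------

    def record(self, config: Configuration, size: int, seconds: float,
               is_default: bool = False) -> None:
        if is_default and self.baseline_time is None:
            self.baseline_time = seconds
            self.baseline_size = size
            self.baseline_config = config
        self.observations.append((config, size, seconds))
        self._rf = None  # stale

    # -- components ---------------------------------------------------------

    def size_ratio(self, n_new: int) -> float:
        if self.baseline_size is None:
            return 1.0
        return size_ratio(self.spec.complexity_p, n_new, self.baseline_size,
                          observed=[(s, t) for _, s, t in self.observations])

    def _observed_hp_ratios(self):
        """(config, time-ratio at baseline scale) for each observation."""
        if self.baseline_time is None or self.baseline_time <= 0:
            return []
        out = []
        for cfg, size, t in self.observations:
            sr = self.size_ratio(size)
            if t > 0 and sr > 0:
                out.append((cfg, t / (self.baseline_time * sr)))
        return out

    def _hp_ratio_A(self, config: Configuration, obs) -> float:
        if self._rf is None:
            X = np.stack([self.encoder.encode(c) for c, _ in obs])
            y = np.log(np.asarray([r for _, r in obs]))
            self._rf = RandomForestRegressor(n_estimators=30, random_state=0)
            self._rf.fit(X, y)
        x = self.encoder.encode(config)[None, :]
        return float(np.exp(self._rf.predict(x)[0]))

    def _hp_ratio_B(self, config: Configuration, obs) -> float:
        """Product of per-hyper-parameter ratios: known-linear parameters
        use value/default; other numerics a fitted power function; the
        rest (known to matter little) are pinned at one."""
        defaults = {d.name: d.default for d in self.spec.hyperparams}
        ratio = 1.0
        p = config.params_dict()
        for d in self.spec.hyperparams:
            if d.kind == "categorical":
                continue
            rel = float(p[d.name]) / float(defaults[d.name])
            if d.name in self.spec.time_linear_params:
                ratio *= rel
            else:
                alpha = self._power_alphas.get(d.name)
                if alpha is None:
                    vals, rats = [], []
                    for cfg, r in obs:
                        vals.append(float(cfg.params_dict()[d.name]) /
                                    float(defaults[d.name]))
                        rats.append(r)
                    alpha = _power_ratio_fit(vals, rats)
                    self._power_alphas[d.name] = alpha
                ratio *= rel ** alpha
        return ratio

    def _choose_approach(self, obs) -> str:
        """Leave-one-out absolute log-error decides A vs B per algorithm."""
        errs = {"A": [], "B": []}
        for i in range(len(obs)):
            rest = obs[:i] + obs[i + 1:]
            cfg, true_r = obs[i]
            if true_r <= 0:
                continue
            for name in ("A", "B"):
                self._rf, self._power_alphas = None, {}
                try:
                    pred = (self._hp_ratio_A(cfg, rest) if name == "A"
                            else self._hp_ratio_B(cfg, rest))
                    if pred > 0:
                        errs[name].append(abs(np.log(pred) - np.log(true_r)))
                except Exception:
                    errs[name].append(np.inf)
        self._rf, self._power_alphas = None, {}
        mean = {k: (np.mean(v) if v else np.inf) for k, v in errs.items()}
        return "A" if mean["A"] < mean["B"] else "B"

    def hp_ratio(self, config: Configuration) -> float:
        """Ratio to the default configuration's time; 1 until at least five
        observations exist (no skipping pressure early)."""
        obs = self._observed_hp_ratios()
        if len(obs) < 5:
            return 1.0
        if self.approach is None:
            self.approach = self._choose_approach(obs)
        r = (self._hp_ratio_A(config, obs) if self.approach == "A"
             else self._hp_ratio_B(config, obs))
        return max(r, 1e-9)

    # -- the skip decision --------------------------------------------------

    def predict_time(self, config: Configuration, size: int) -> float:
        if self.baseline_time is None:
            return 0.0
        return self.baseline_time * self.size_ratio(size) * \
            self.hp_ratio(config)

    def should_skip(self, config: Configuration, size: int,
                    T: float) -> bool:
        return should_skip(self.predict_time(config, size), T, self.f)
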
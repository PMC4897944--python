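"""Real-time projection of model accuracy and expected outcome.

The best-so-far accuracy of an automated model search rises quickly and
then saturates, which an inverse power law captures well:
``f(t) = a - b * t**-c`` with ``0 < b < a < 1`` and ``c > 0`` for
increasing curves, and ``f(t) = a + b * t**-c`` (``b > 0``, not
necessarily < a) for decreasing ones.  Because late points carry more
information about the future than early ones, only the last
``n = min(g, h)`` recorded points are fitted (``g`` a window parameter,
``h`` the number of points so far) with weight ``i/n`` on the i-th of
those points.

Class-pair confusion fractions ``p[c1][c2](t)`` are fitted the same way —
diagonal pairs increasing, off-diagonal decreasing — and combined with the
class prevalences ``q`` and a user outcome matrix ``o`` into the projected
expected outcome ``sum(q[c1] * p[c1][c2] * o[c1][c2])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .data_model import ConfigError


@dataclass
class AccuracyCurve:
    """Best-so-far quality vs seconds since search start."""

    g: int = 20
    t: list = field(default_factory=list)
    y: list = field(default_factory=list)

    @property
    def h(self) -> int:
        return len(self.t)

    @property
    def n(self) -> int:
        return min(self.g, self.h)

    def record_point(self, t: float, quality: float) -> None:
        """Append ``(t, max(quality, best so far))``; t must increase."""
        if self.t and t <= self.t[-1]:
            raise ConfigError("time must be strictly increasing")
        best = max(quality, self.y[-1]) if self.y else quality
        self.t.append(float(t))
        self.y.append(float(best))

    def window(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Last-n points and their i/n weights."""
        n = self.n
        t = np.asarray(self.t[-n:], dtype=float)
        y = np.asarray(self.y[-n:], dtype=float)
        w = np.arange(1, n + 1, dtype=float) / n
        return t, y, w


@dataclass
class PowerLawFit:
    a: float
    b: float
    c: float
    direction: str            # "increasing" | "decreasing"
    weighted_sse: float
    t_window: np.ndarray
    y_window: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        sign = -1.0 if self.direction == "increasing" else 1.0
        return self.a + sign * self.b * t ** (-self.c)


_N_STARTS = 16


def _fit_weighted(t, y, w, direction: str, seed: int = 0) -> PowerLawFit:
    """Multi-start bounded weighted least squares.

    Increasing case is parametrized as (a, rho=b/a, log c) with
    a in (0,1), rho in (0,1), which enforces 0 < b < a < 1; the decreasing
    case fits (a, log b, log c) with a in [0,1] and b unconstrained above.
    """
    sw = np.sqrt(w)
    rng = np.random.default_rng(seed)
    eps = 1e-9

    if direction == "increasing":
        def resid(p):
            a, rho, logc = p
            return sw * (a - a * rho * t ** (-np.exp(logc)) - y)
        bounds = ([eps, eps, -7.0], [1.0 - eps, 1.0 - eps, 4.0])

        def unpack(p):
            a, rho, logc = p
            return a, a * rho, float(np.exp(logc))
    else:
        def resid(p):
            a, logb, logc = p
            return sw * (a + np.exp(logb) * t ** (-np.exp(logc)) - y)
        bounds = ([0.0, -12.0, -7.0], [1.0, 5.0, 4.0])

        def unpack(p):
            a, logb, logc = p
            return a, float(np.exp(logb)), float(np.exp(logc))

    y_hi, y_lo = float(np.max(y)), float(np.min(y))
    starts = []
    for k in range(_N_STARTS):
        if direction == "increasing":
            a0 = min(1 - 1e-3, max(1e-3, y_hi + rng.uniform(0.0, 0.1)))
            rho0 = rng.uniform(0.05, 0.95)
            starts.append([a0, rho0, rng.uniform(-2.5, 1.5)])
        else:
            a0 = max(0.0, min(1.0, y_lo - rng.uniform(0.0, 0.1)))
            b0 = max(1e-5, (y_hi - y_lo) or 0.1)
            starts.append([a0, np.log(b0) + rng.uniform(-1, 1),
                           rng.uniform(-2.5, 1.5)])

    best_sol, best_sse = None, np.inf
    for p0 in starts:
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            sol = least_squares(resid, p0, bounds=bounds, method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        sse = float(np.sum(sol.fun ** 2))
        if sse < best_sse:
            best_sse, best_sol = sse, sol
    if best_sol is None:
        raise ConfigError("power-law fit failed to converge from any start")
    a, b, c = unpack(best_sol.x)
    return PowerLawFit(a, b, c, direction, best_sse, t, y)


def fit_inverse_power(curve: AccuracyCurve, direction: str = "increasing",
                      seed: int = 0) -> PowerLawFit | None:
    """Weighted fit over the curve's last-n window; None (projection
    unavailable) until three distinct times exist."""
    t, y, w = curve.window()
    if len(np.unique(t)) < 3:
        return None
    return _fit_weighted(t, y, w, direction, seed=seed)


def fit_power_law_points(times, values, g: int = 20,
                         direction: str = "increasing",
                         seed: int = 0) -> PowerLawFit | None:
    """Windowed weighted fit on raw (t, y) points without the best-so-far
    floor (for curves that are not cumulative maxima, e.g. class-pair
    fractions or externally recorded traces)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = min(g, len(t))
    t, y = t[-n:], y[-n:]
    if len(np.unique(t)) < 3:
        return None
    w = np.arange(1, n + 1, dtype=float) / n
    return _fit_weighted(t, y, w, direction, seed=seed)


def project_accuracy(fit: PowerLawFit | None, t_future):
    """Plug-in projection; increasing fits saturate at ``a`` and are
    clipped there from above.  None marks an unavailable projection."""
    if fit is None:
        return None
    v = fit(t_future)
    if fit.direction == "increasing":
        v = np.minimum(v, fit.a)
    out = np.clip(v, 0.0, 1.0)
    return float(out) if np.isscalar(t_future) else out


# ---------------------------------------------------------------------------
# outcome projection
# ---------------------------------------------------------------------------

@dataclass
class OutcomeSpec:
    """Classes, prevalences q, user outcome matrix o, and fitted class-pair
    fraction curves p[c1][c2](t)."""

    classes: list
    q: np.ndarray
    o: np.ndarray
    pair_fits: dict = field(default_factory=dict)  # (i, j) -> PowerLawFit

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.o = np.asarray(self.o, dtype=float)
        k = len(self.classes)
        if abs(self.q.sum() - 1.0) > 1e-9:
            raise ConfigError("class proportions must sum to 1")
        if self.o.shape != (k, k):
            raise ConfigError("outcome matrix must be k x k")


def confusion_fractions(y_true, y_pred, classes) -> np.ndarray:
    """Row-normalized confusion matrix: fraction of class c1 predicted
    as c2 (rows sum to 1 for observed classes)."""
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((k, k), dtype=float)
    for yt, yp in zip(y_true, y_pred):
        m[idx[yt], idx[yp]] += 1.0
    sums = m.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return m / sums


def fit_class_pair_curves(times, fraction_history, classes, q, o,
                          g: int = 20, seed: int = 0) -> OutcomeSpec:
    """Fit one curve per ordered class pair from a history of confusion
    fractions (one k x k matrix per time).  Diagonal pairs reflect
    per-class accuracy and are fitted increasing; off-diagonal pairs
    reflect error rates and are fitted decreasing."""
    spec = OutcomeSpec(list(classes), q, o)
    k = len(classes)
    times = np.asarray(times, dtype=float)
    hist = np.asarray(fraction_history, dtype=float)  # (T, k, k)
    for i in range(k):
        for j in range(k):
            # raw (not best-so-far) fractions: window and weight directly
            n = min(g, len(times))
            t, y = times[-n:], hist[-n:, i, j]
            w = np.arange(1, n + 1, dtype=float) / n
            if len(np.unique(t)) < 3:
                spec.pair_fits[(i, j)] = None
                continue
            direction = "increasing" if i == j else "decreasing"
            spec.pair_fits[(i, j)] = _fit_weighted(t, y, w, direction,
                                                   seed=seed)
    return spec


def project_fractions(spec: OutcomeSpec, t_future: float) -> np.ndarray:
    """Projected confusion-fraction matrix at ``t_future``; each row is
    clipped to [0, 1] and renormalized to sum to 1."""
    k = len(spec.classes)
    p = np.zeros((k, k), dtype=float)
    for i in range(k):
        for j in range(k):
            fit = spec.pair_fits.get((i, j))
            if fit is None:
                p[i, j] = 1.0 if i == j else 0.0
            else:
                p[i, j] = np.clip(project_accuracy(fit, t_future), 0.0, 1.0)
    sums = p.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return p / sums


def project_outcome(spec: OutcomeSpec, t_future: float | None = None,
                    p: np.ndarray | None = None) -> float:
    """Expected outcome ``sum(q[c1] * p[c1][c2] * o[c1][c2])`` with ``p``
    either given directly or projected at ``t_future``."""
    if p is None:
        if t_future is None:
            raise ConfigError("need t_future or an explicit p matrix")
        p = project_fractions(spec, t_future)
    p = np.asarray(p, dtype=float)
    return float(np.sum(spec.q[:, None] * p * spec.o))


def handle_continuous_target(y, o, n_bins: int = 2) -> tuple:
    """Discretize a continuous target into quantile bins so the
    categorical outcome machinery applies.  Returns (bin labels per
    instance, OutcomeSpec without pair fits)."""
    y = pd.Series(np.asarray(y, dtype=float))
    if n_bins == 1:
        labels = pd.Series(np.zeros(len(y), dtype=int))
    else:
        labels = pd.qcut(y, n_bins, labels=False, duplicates="drop")
    classes = sorted(labels.unique())
    q = np.asarray([(labels == c).mean() for c in classes])
    o = np.asarray(o, dtype=float)
    return labels.to_numpy(), OutcomeSpec(classes, q, o)
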
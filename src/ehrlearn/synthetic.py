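"""Synthetic inputs with known ground truth.

Three generators cover everything the rest of the package consumes:

* an EAV cohort whose target depends, through a monotone link plus
  controllable label noise, on one *planted* (attribute, period, operator)
  aggregate — the recoverable ground truth for aggregation selection;
* wide benchmark tables whose generative family (axis-aligned rule,
  linear, interaction) determines which learner family is Bayes-optimal;
* noisy best-so-far accuracy traces drawn from a known inverse power law
  ``y = a - b * t**-c``.

Event timestamps follow a homogeneous Poisson process per attribute per
patient; values come from configurable normal/lognormal/categorical
distributions.  Every generator is bit-reproducible given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import AggregationSpec, CATALOG, make_spec, pivot_aggregate
from .data_model import ConfigError, EAVTable, InstanceTable

_T0 = np.datetime64("2020-01-01T00:00:00")


@dataclass(frozen=True)
class AttributeSpec:
    """One repeatedly recorded attribute: its type, monthly event rate and
    value distribution ``("normal", mu, sd) | ("lognormal", mu, sd) |
    ("categorical", (values...))``; event-typed attributes carry value 1."""

    name: str
    kind: str = "event"  # numeric | event | medication
    rate_per_month: float = 1.0
    dist: tuple = ("normal", 0.0, 1.0)

    def __post_init__(self):
        if self.rate_per_month <= 0:
            raise ConfigError("event rate must be > 0")


@dataclass
class CohortSpec:
    """Specification of a synthetic EAV cohort with one planted signal."""

    n_patients: int = 500
    attributes: tuple = (
        AttributeSpec("ed_visit", "event", 0.6),
        AttributeSpec("weight", "numeric", 1.0, ("normal", 80.0, 8.0)),
        AttributeSpec("steroid_dose", "medication", 0.8,
                      ("lognormal", 1.0, 0.4)),
    )
    horizon_days: int = 365
    planted: AggregationSpec = field(
        default_factory=lambda: make_spec("ed_visit", 90, "count"))
    noise: float = 0.0            # label-flip probability (categorical)
    target_type: str = "categorical"
    index_offsets_days: tuple = ()  # extra index dates per patient
    seed: int = 0

    def __post_init__(self):
        attr_types = {a.name: a.kind for a in self.attributes}
        planted_attr = self.planted.attribute
        if isinstance(planted_attr, str):
            op = CATALOG[self.planted.operator]
            if not op.applies_to(attr_types.get(planted_attr, "numeric")):
                raise ConfigError(
                    f"planted operator {op.id!r} does not apply to "
                    f"attribute {planted_attr!r}")


def _draw_values(dist, size, rng):
    kind = dist[0]
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size)
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], size)
    if kind == "categorical":
        return rng.choice(np.asarray(dist[1], dtype=object), size)
    raise ConfigError(f"unknown value distribution {kind!r}")


def generate_eav_cohort(spec: CohortSpec) -> tuple[EAVTable, InstanceTable]:
    """Generate (events, instances).  The target is a noisy monotone
    function of the planted aggregate over each instance's lookback window;
    with ``noise=0`` thresholding the planted aggregate at the cohort
    median reproduces the categorical target exactly."""
    rng = np.random.default_rng(spec.seed)
    records = []
    horizon_s = spec.horizon_days * 86400
    for p in range(spec.n_patients):
        pid = f"p{p:05d}"
        for attr in spec.attributes:
            lam = attr.rate_per_month * spec.horizon_days / 30.0
            n_ev = rng.poisson(lam)
            offs = np.sort(rng.uniform(0, horizon_s, n_ev)).astype("int64")
            if attr.kind == "event":
                vals = np.ones(n_ev)
            else:
                vals = _draw_values(attr.dist, n_ev, rng)
            for o, v in zip(offs, vals):
                records.append((pid, _T0 + np.timedelta64(int(o), "s"),
                                attr.name, v))
    frame = pd.DataFrame(records, columns=["patient_id", "timestamp",
                                           "attribute", "value"])
    if not len(frame):
        frame = pd.DataFrame({"patient_id": pd.Series(dtype=object),
                              "timestamp": pd.Series(dtype="datetime64[s]"),
                              "attribute": pd.Series(dtype=object),
                              "value": pd.Series(dtype=object)})
    eav = EAVTable(frame)

    offsets = [spec.horizon_days, *spec.index_offsets_days]
    inst_rows = []
    for p in range(spec.n_patients):
        pid = f"p{p:05d}"
        for j, off in enumerate(offsets):
            inst_rows.append({
                "instance_id": f"{pid}@{j}", "patient_id": pid,
                "index_date": _T0 + np.timedelta64(off * 86400, "s")})
    inst = InstanceTable(pd.DataFrame(
        inst_rows, columns=["instance_id", "patient_id", "index_date"]),
        index_date_col="index_date")
    if not spec.n_patients:
        inst.frame["target"] = pd.Series(dtype=object)
        inst.target, inst.target_type = "target", spec.target_type
        return eav, inst

    wide = pivot_aggregate(eav, [spec.planted], inst)
    z = pd.to_numeric(wide.frame[spec.planted.column],
                      errors="coerce").fillna(0.0).to_numpy(float)
    if spec.target_type == "categorical":
        y = (z > np.median(z)).astype(int)
        if spec.noise > 0:
            flip = rng.random(len(y)) < spec.noise
            y = np.where(flip, 1 - y, y)
        inst.frame["target"] = y
    else:
        zs = (z - z.mean()) / (z.std() or 1.0)
        inst.frame["target"] = zs + spec.noise * rng.normal(size=len(zs))
    inst.target = "target"
    inst.target_type = spec.target_type
    return eav, inst


@dataclass
class BenchmarkSpec:
    """Wide benchmark table with a known Bayes-optimal learner family."""

    n_instances: int = 2000
    n_features: int = 8
    family: str = "rule"   # rule | linear | interaction
    rule_features: int = 2  # XOR-parity of this many axis thresholds
    label_noise: float = 0.1
    seed: int = 0


def generate_benchmark(spec: BenchmarkSpec) -> InstanceTable:
    """The ``rule`` family labels by the parity of ``rule_features``
    axis-aligned thresholds (with one feature this is a single threshold a
    stump reproduces exactly; with two it is an XOR a linear model cannot
    express); ``linear`` labels by a logistic score over five features;
    ``interaction`` by the sign of a feature product."""
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_instances, spec.n_features
    X = rng.normal(size=(n, max(d, 1)))
    if spec.family == "rule":
        r = min(spec.rule_features, d)
        y = (X[:, :r] > 0).sum(axis=1) % 2
    elif spec.family == "linear":
        k = min(5, d)
        w = np.linspace(1.0, 2.0, k)
        score = X[:, :k] @ w
        y = (score > 0).astype(int)
    elif spec.family == "interaction":
        y = (X[:, 0] * X[:, min(1, d - 1)] > 0).astype(int)
    else:
        raise ConfigError(f"unknown family {spec.family!r}")
    if spec.label_noise > 0:
        flip = rng.random(n) < spec.label_noise
        y = np.where(flip, 1 - y, y)
    frame = pd.DataFrame(X[:, :d], columns=[f"f{j}" for j in range(d)])
    frame.insert(0, "instance_id", [f"i{k:06d}" for k in range(n)])
    frame["target"] = y.astype(int)
    return InstanceTable(frame, target="target", target_type="categorical")


def generate_accuracy_trace(a: float, b: float, c: float, times,
                            noise_sd: float = 0.0, seed: int = 0):
    """Points ``(t, a - b * t**-c + N(0, noise_sd^2))`` clipped to [0, 1]."""
    if not (0 < b < a < 1) or c <= 0:
        raise ConfigError("need 0 < b < a < 1 and c > 0")
    t = np.asarray(times, dtype=float)
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ConfigError("times must be positive and strictly increasing")
    rng = np.random.default_rng(seed)
    y = a - b * t ** (-c)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=len(t))
    return list(zip(t.tolist(), np.clip(y, 0.0, 1.0).tolist()))
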
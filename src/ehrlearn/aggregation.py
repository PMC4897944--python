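"""Automated temporal aggregation of repeatedly recorded clinical attributes.

A repeatedly recorded attribute (weight, lab results, visits, medication
doses) must be collapsed into per-instance features before modelling.  Each
feature is defined by an :class:`AggregationSpec` — a lookback *period*
ending at the instance's index date plus an *operator* (count, mean,
monotone trend, ...).  Operators are grouped into *categories*; operators in
the same category produce largely redundant features, so exactly one
(period, operator) pair is selected per (attribute, related category) by
scoring every enumerated candidate with an information-gain style relevance
measure and keeping the argmax.

Windows are half-open ``(index_date - period, index_date]``: an event at the
index date contributes, an event exactly at the far edge does not.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .data_model import ConfigError, EAVTable, InstanceTable

DAY = np.timedelta64(24 * 3600, "s")

#: events skipped because a numeric operator met a non-numeric value
skipped_non_numeric = 0

FREQ_BIN_DAYS = {"weekly": 7, "monthly": 30, "quarterly": 91}


@dataclass(frozen=True)
class AggregationOperator:
    id: str
    category: str
    applicability: frozenset  # of {"numeric", "event", "medication", "two-attribute"}
    output_type: str          # numeric | binary | count | duration-days
    needs_params: tuple = ()
    implemented: bool = True

    def applies_to(self, attr_type: str) -> bool:
        return attr_type in self.applicability


def _num(values) -> np.ndarray:
    """Keep numeric values only, counting skipped non-numerics."""
    global skipped_non_numeric
    out = []
    for v in values:
        if isinstance(v, (int, float, np.floating, np.integer)) and not (
                isinstance(v, float) and np.isnan(v)):
            out.append(float(v))
        else:
            skipped_non_numeric += 1
            warnings.warn("non-numeric value skipped by numeric operator")
    return np.asarray(out, dtype=float)


def _strictly_increasing(x: np.ndarray) -> int:
    return int(len(x) >= 2 and bool(np.all(np.diff(x) > 0)))


def _strictly_decreasing(x: np.ndarray) -> int:
    return int(len(x) >= 2 and bool(np.all(np.diff(x) < 0)))


def _freq_counts(times: np.ndarray, window, bin_days: int) -> np.ndarray:
    """Counts per complete bin, oldest first; bins laid backwards from the
    window end; a partial oldest bin is dropped."""
    start, end = window
    period_days = (end - start) / DAY
    nbins = int(np.floor(period_days / bin_days))
    counts = []
    for j in range(nbins):  # j = 0 is the most recent bin
        lo = end - np.timedelta64((j + 1) * bin_days * 24 * 3600, "s")
        hi = end - np.timedelta64(j * bin_days * 24 * 3600, "s")
        counts.append(int(np.sum((times > lo) & (times <= hi))))
    return np.asarray(counts[::-1], dtype=float)


def _op_impl(op_id, times, values, window, params):
    if op_id == "value_min":
        x = _num(values)
        return float(np.min(x)) if x.size else np.nan
    if op_id == "value_max":
        x = _num(values)
        return float(np.max(x)) if x.size else np.nan
    if op_id == "value_mean":
        x = _num(values)
        return float(np.mean(x)) if x.size else np.nan
    if op_id == "presence":
        return int(len(times) > 0)
    if op_id == "count":
        return int(len(times))
    if op_id == "duration_days":
        if len(times) == 0:
            return 0.0
        return float((times[-1] - times[0]) / DAY)
    if op_id == "most_recent_value":
        x = _num(values)
        return float(x[-1]) if x.size else np.nan
    if op_id == "value_increasing":
        return _strictly_increasing(_num(values))
    if op_id == "value_decreasing":
        return _strictly_decreasing(_num(values))
    if op_id == "value_change":
        x = _num(values)
        return float(x[-1] - x[0]) if x.size else np.nan
    if op_id == "value_relative_change":
        x = _num(values)
        if not x.size or x[0] == 0:
            return np.nan
        return float((x[-1] - x[0]) / abs(x[0]))
    if op_id in ("fraction_high", "fraction_low", "fraction_normal"):
        x = _num(values)
        if not x.size:
            return np.nan
        lo, hi = params["normal_range"]
        if op_id == "fraction_high":
            return float(np.mean(x > hi))
        if op_id == "fraction_low":
            return float(np.mean(x < lo))
        return float(np.mean((x >= lo) & (x <= hi)))
    if op_id == "fraction_equal":
        x = _num(values)
        return float(np.mean(x == params["value"])) if x.size else np.nan
    if op_id in ("freq_increasing", "freq_decreasing"):
        counts = _freq_counts(times, window, FREQ_BIN_DAYS[
            params.get("bin", "monthly")])
        if len(counts) < 2:
            return 0
        return (_strictly_increasing(counts) if op_id == "freq_increasing"
                else _strictly_decreasing(counts))
    if op_id == "med_intensified":
        return _strictly_increasing(_num(values))
    if op_id == "med_deintensified":
        return _strictly_decreasing(_num(values))
    raise NotImplementedError(f"operator {op_id!r} is not implemented")


_NUM = frozenset({"numeric"})
_ANY = frozenset({"numeric", "event", "medication"})
_MED = frozenset({"medication"})

#: operator catalog, ordered; catalog order is the selection tie-break
CATALOG: dict[str, AggregationOperator] = {o.id: o for o in [
    AggregationOperator("value_min", "summary", _NUM, "numeric"),
    AggregationOperator("value_max", "summary", _NUM, "numeric"),
    AggregationOperator("value_mean", "summary", _NUM, "numeric"),
    AggregationOperator("presence", "presence", _ANY, "binary"),
    AggregationOperator("duration_days", "duration",
                        frozenset({"medication", "event"}), "duration-days"),
    AggregationOperator("count", "count", _ANY, "count"),
    AggregationOperator("value_increasing", "value_trend", _NUM, "binary"),
    AggregationOperator("value_decreasing", "value_trend", _NUM, "binary"),
    AggregationOperator("most_recent_value", "recent", _NUM, "numeric"),
    AggregationOperator("value_change", "change", _NUM, "numeric"),
    AggregationOperator("value_relative_change", "change", _NUM, "numeric"),
    AggregationOperator("fraction_high", "fraction", _NUM, "numeric",
                        ("normal_range",)),
    AggregationOperator("fraction_low", "fraction", _NUM, "numeric",
                        ("normal_range",)),
    AggregationOperator("fraction_normal", "fraction", _NUM, "numeric",
                        ("normal_range",)),
    AggregationOperator("fraction_equal", "fraction", _NUM, "numeric",
                        ("value",)),
    AggregationOperator("freq_increasing", "frequency_trend", _ANY, "binary"),
    AggregationOperator("freq_decreasing", "frequency_trend", _ANY, "binary"),
    AggregationOperator("med_intensified", "med_intensity", _MED, "binary"),
    AggregationOperator("med_deintensified", "med_intensity", _MED, "binary"),
    AggregationOperator("event_before_event", "sequence",
                        frozenset({"two-attribute"}), "binary",
                        ("gap_days", "qualifier")),
    # named in the operator inventory but with no agreed definition:
    AggregationOperator("med_switched", "med_pattern", _MED, "binary",
                        implemented=False),
    AggregationOperator("med_multiple_therapies", "med_pattern", _MED,
                        "binary", implemented=False),
]}

#: binary/count-like operators that default to 0 on an empty window
_ZERO_ON_EMPTY = {"presence", "count", "duration_days", "value_increasing",
                  "value_decreasing", "freq_increasing", "freq_decreasing",
                  "med_intensified", "med_deintensified",
                  "event_before_event"}


def apply_operator(op, events, window, params=None):
    """Apply one operator to a patient's sorted ``(timestamp, value)`` events.

    Only events with ``start < t <= end`` contribute.  Empty windows yield 0
    for binary/count-like operators and missing (NaN) for numeric ones;
    monotonicity operators need at least two in-window observations.
    """
    if isinstance(op, str):
        op = CATALOG[op]
    if not op.implemented:
        raise NotImplementedError(
            f"operator {op.id!r} is registered but has no agreed definition")
    params = params or {}
    start, end = window
    times = np.asarray([np.datetime64(t) for t, _ in events],
                       dtype="datetime64[s]")
    order = np.argsort(times, kind="stable")
    times = times[order]
    vals = [events[i][1] for i in order]
    mask = (times > np.datetime64(start)) & (times <= np.datetime64(end))
    times_in = times[mask]
    vals_in = [v for v, m in zip(vals, mask) if m]
    if len(times_in) == 0 and op.id in _ZERO_ON_EMPTY:
        return 0
    return _op_impl(op.id, times_in, vals_in, (np.datetime64(start),
                                               np.datetime64(end)), params)


def event_before_event(events_a, events_b, qualifier, gap_days, window):
    """1 iff some A event precedes a qualifying B event by at most
    ``gap_days`` with both inside the window (e.g., a drug prescribed
    shortly before an abnormal lab result).

    ``qualifier`` is a predicate on B's value (e.g., outside a normal
    range)."""
    start, end = np.datetime64(window[0]), np.datetime64(window[1])
    gap = np.timedelta64(int(gap_days * 24 * 3600), "s")
    ta = [np.datetime64(t) for t, _ in events_a]
    ta = [t for t in ta if start < t <= end]
    tb = [np.datetime64(t) for t, v in events_b
          if qualifier(v) and start < np.datetime64(t) <= end]
    for b in tb:
        for a in ta:
            if np.timedelta64(0, "s") < b - a <= gap:
                return 1
    return 0


# ---------------------------------------------------------------------------
# periods, knowledge base, specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeriodSchedule:
    """Shortest/longest lookback in days plus a progression rule."""

    shortest: int
    longest: int
    progression: str = "exponential"  # or "arithmetic"
    factor: float = 2.0
    step_days: int = 30

    def __post_init__(self):
        if not (0 < self.shortest <= self.longest):
            raise ConfigError("need 0 < shortest <= longest")
        if self.progression == "exponential" and self.factor <= 1:
            raise ConfigError("exponential progression needs factor > 1")
        if self.progression == "arithmetic" and self.step_days <= 0:
            raise ConfigError("arithmetic progression needs step > 0")


def enumerate_periods(schedule: PeriodSchedule) -> list[int]:
    """Candidate period lengths (days), shortest first.  Elongation is
    exponential (e.g., doubling) or arithmetic; if the progression
    overshoots, the longest period itself is appended."""
    out = [schedule.shortest]
    while True:
        if schedule.progression == "exponential":
            nxt = int(round(out[-1] * schedule.factor))
        else:
            nxt = out[-1] + schedule.step_days
        if nxt > schedule.longest:
            break
        out.append(nxt)
    if out[-1] < schedule.longest:
        out.append(schedule.longest)
    return out


@dataclass(frozen=True)
class AggregationSpec:
    """One temporal aggregate feature: attribute, lookback period ending at
    the index date, operator, and any extra operator parameters."""

    attribute: str | tuple
    period_days: int
    operator: str
    params: tuple = ()  # sorted (key, value) pairs; hashable

    def params_dict(self) -> dict:
        return dict(self.params)

    @property
    def column(self) -> str:
        attr = (self.attribute if isinstance(self.attribute, str)
                else "+".join(self.attribute))
        return f"{attr}__{self.operator}__{self.period_days}d"


def make_spec(attribute, period_days, operator, **params) -> AggregationSpec:
    return AggregationSpec(attribute, int(period_days), operator,
                           tuple(sorted(params.items())))


@dataclass
class KnowledgeBase:
    """Expert knowledge steering aggregation.

    Maps each attribute to a group and a type, and each group to the
    operator categories worth trying with their period schedules.  Partial
    maps are legal — knowledge can be added over time."""

    attribute_groups: dict[str, str] = field(default_factory=dict)
    attribute_types: dict[str, str] = field(default_factory=dict)
    group_categories: dict[str, list] = field(default_factory=dict)
    normal_ranges: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for group, pairs in self.group_categories.items():
            for cat, _ in pairs:
                if not any(op.category == cat for op in CATALOG.values()):
                    raise ConfigError(f"unknown operator category {cat!r}")

    def categories_for(self, attribute: str):
        group = self.attribute_groups.get(attribute)
        return self.group_categories.get(group, [])

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeBase":
        gc = {}
        for group, items in d.get("group_categories", {}).items():
            gc[group] = [(it["category"], PeriodSchedule(
                shortest=it["shortest_days"], longest=it["longest_days"],
                progression=it.get("progression", "exponential"),
                factor=it.get("factor", 2.0),
                step_days=it.get("step_days", 30))) for it in items]
        return cls(attribute_groups=dict(d.get("attribute_groups", {})),
                   attribute_types=dict(d.get("attribute_types", {})),
                   group_categories=gc,
                   normal_ranges={k: tuple(v) for k, v in
                                  d.get("normal_ranges", {}).items()})

    @classmethod
    def from_file(cls, path) -> "KnowledgeBase":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# pivoting EAV -> wide
# ---------------------------------------------------------------------------

def _events_by_patient(eav: EAVTable, attributes: set) -> dict:
    """patient -> attribute -> sorted [(timestamp, value)]; tuples for
    attributes not named by any spec are filtered before grouping."""
    frame = eav.frame
    frame = frame[frame["attribute"].isin(attributes)]
    frame = frame.sort_values("timestamp", kind="stable")
    out: dict = {}
    for (pid, attr), grp in frame.groupby(["patient_id", "attribute"],
                                          sort=False):
        out.setdefault(pid, {})[attr] = list(
            zip(grp["timestamp"].to_numpy(), grp["value"].tolist()))
    return out


def _pivot_rows(rows, events, specs):
    data = []
    for pid, index_date in rows:
        end = np.datetime64(index_date)
        rec = {}
        pat = events.get(pid, {})
        for spec in specs:
            start = end - np.timedelta64(
                spec.period_days * 24 * 3600, "s")
            params = spec.params_dict()
            if spec.operator == "event_before_event":
                attr_a, attr_b = spec.attribute
                qual = params.get("qualifier", lambda v: True)
                rec[spec.column] = event_before_event(
                    pat.get(attr_a, []), pat.get(attr_b, []), qual,
                    params["gap_days"], (start, end))
            else:
                rec[spec.column] = apply_operator(
                    CATALOG[spec.operator], pat.get(spec.attribute, []),
                    (start, end), params)
        data.append(rec)
    return data


def pivot_aggregate(eav: EAVTable, specs, instances: InstanceTable,
                    n_jobs: int = 1) -> InstanceTable:
    """Compute one aggregate column per spec, one row per
    (patient, index date) instance.  The result is identical whether
    computed serially or with several workers."""
    if instances.index_date_col is None:
        raise ConfigError("instances need an index_date column to pivot")
    frame = instances.frame
    attrs = set()
    for s in specs:
        attrs.update([s.attribute] if isinstance(s.attribute, str)
                     else list(s.attribute))
    events = _events_by_patient(eav, attrs)
    pids = (frame["patient_id"] if "patient_id" in frame.columns
            else frame["instance_id"])
    rows = list(zip(pids, frame[instances.index_date_col]))
    if n_jobs == 1 or len(rows) < 2 * n_jobs:
        data = _pivot_rows(rows, events, specs)
    else:
        chunks = np.array_split(np.arange(len(rows)), n_jobs)
        parts = Parallel(n_jobs=n_jobs, backend="threading")(
            delayed(_pivot_rows)([rows[i] for i in c], events, specs)
            for c in chunks)
        data = [rec for part in parts for rec in part]
    agg = pd.DataFrame(data, index=frame.index)
    out = pd.concat([frame.reset_index(drop=True),
                     agg.reset_index(drop=True)], axis=1)
    return InstanceTable(out, target=instances.target,
                         target_type=instances.target_type,
                         index_date_col=instances.index_date_col,
                         column_types=dict(instances.column_types))


# ---------------------------------------------------------------------------
# relevance scoring
# ---------------------------------------------------------------------------

def _discretize(x: pd.Series, n_bins: int = 10) -> pd.Series:
    """Equal-frequency bins for numeric features; missing is its own bin."""
    x = pd.Series(np.asarray(x, dtype=object))
    numeric = pd.to_numeric(x, errors="coerce")
    if numeric.notna().sum() and numeric.nunique() > n_bins:
        binned = pd.qcut(numeric, n_bins, duplicates="drop",
                         labels=False).astype(object)
    else:
        binned = numeric.astype(object)
        binned[numeric.isna()] = None
    binned[pd.isna(binned)] = "__missing__"
    return binned


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def information_gain(feature, target) -> float:
    """IG = H(target) − H(target | feature) in bits, with numeric features
    discretized into 10 equal-frequency bins and missing as its own bin."""
    f = _discretize(pd.Series(feature))
    y = pd.Series(np.asarray(target, dtype=object)).reset_index(drop=True)
    h_y = _entropy(y.value_counts().to_numpy(dtype=float))
    n = len(y)
    h_cond = 0.0
    for _, idx in y.groupby(f, sort=False).groups.items():
        sub = y.loc[idx]
        h_cond += len(sub) / n * _entropy(
            sub.value_counts().to_numpy(dtype=float))
    return max(0.0, h_y - h_cond)


def variance_reduction(feature, target) -> float:
    """Regression analogue of information gain: Var(y) − E[Var(y | bin)]."""
    f = _discretize(pd.Series(feature))
    y = pd.Series(np.asarray(target, dtype=float)).reset_index(drop=True)
    var_y = float(np.var(y))
    n = len(y)
    cond = 0.0
    for _, idx in y.groupby(f, sort=False).groups.items():
        sub = y.loc[idx]
        cond += len(sub) / n * float(np.var(sub))
    return max(0.0, var_y - cond)


def relevance_score(feature, target, target_type: str) -> float:
    if target_type == "categorical":
        return information_gain(feature, target)
    return variance_reduction(feature, target)


# ---------------------------------------------------------------------------
# selection: one (period, operator) pair per (attribute, category)
# ---------------------------------------------------------------------------

def _candidate_specs(attribute: str, attr_type: str, category: str,
                     schedule: PeriodSchedule, kb: KnowledgeBase):
    periods = enumerate_periods(schedule)
    ops = [op for op in CATALOG.values()
           if op.category == category and op.implemented
           and op.applies_to(attr_type)]
    out = []
    for period in periods:
        for op in ops:
            params = {}
            if "normal_range" in op.needs_params:
                if attribute not in kb.normal_ranges:
                    continue
                params["normal_range"] = kb.normal_ranges[attribute]
            if "value" in op.needs_params:
                continue  # needs a user-given comparison value
            out.append(make_spec(attribute, period, op.id, **params))
    return out


def select_spec_per_category(eav: EAVTable, instances: InstanceTable,
                             kb: KnowledgeBase, sample_size: int = 5000,
                             seed: int = 0, n_jobs: int = 1):
    """For every (attribute, related category) enumerate all period x
    operator pairs, score each candidate feature on a seeded sample of
    instances, and return exactly the argmax pair per category.

    Ties break toward the shorter period, then catalog order.  Returns
    ``(specs, provenance)`` where provenance lists every candidate and its
    score.
    """
    if instances.target is None:
        raise ConfigError("selection needs a target column")
    frame = instances.frame
    n = len(frame)
    rng = np.random.default_rng(seed)
    if n > sample_size:
        if instances.target_type == "categorical":
            idx = []
            for cls, grp in frame.groupby(instances.target, sort=False):
                k = max(1, int(round(sample_size * len(grp) / n)))
                pick = rng.choice(grp.index.to_numpy(), size=min(k, len(grp)),
                                  replace=False)
                idx.extend(pick.tolist())
            idx = sorted(idx)
        else:
            idx = sorted(rng.choice(frame.index.to_numpy(),
                                    size=sample_size, replace=False).tolist())
        sample = instances.subset(frame.loc[idx, "instance_id"])
    else:
        sample = instances
    y = sample.frame[instances.target]

    present = set(eav.frame["attribute"].unique())
    catalog_order = {op_id: i for i, op_id in enumerate(CATALOG)}
    selected, provenance = [], []
    covered = False
    for attribute in sorted(present):
        attr_type = kb.attribute_types.get(attribute, "numeric")
        for category, schedule in kb.categories_for(attribute):
            cands = _candidate_specs(attribute, attr_type, category,
                                     schedule, kb)
            if not cands:
                continue
            covered = True
            wide = pivot_aggregate(eav, cands, sample, n_jobs=n_jobs)
            scored = []
            for spec in cands:
                s = relevance_score(wide.frame[spec.column], y,
                                    instances.target_type)
                scored.append((spec, s))
                provenance.append({"attribute": attribute,
                                   "category": category,
                                   "operator": spec.operator,
                                   "period_days": spec.period_days,
                                   "score": s})
            best = max(scored, key=lambda t: (
                t[1], -t[0].period_days, -catalog_order[t[0].operator]))
            if best[1] == 0.0:
                warnings.warn(f"uninformative: every candidate for "
                              f"({attribute}, {category}) scored 0")
            selected.append(best[0])
    if not covered:
        raise ConfigError("knowledge base covers no attribute in the data")
    return selected, provenance


class TemporalFeatureSelector(BaseEstimator):
    """Transformer selecting one aggregate feature per (attribute, operator
    category) and pivoting the EAV table into a wide instance table.

    ``fit`` scores candidates on a seeded instance sample and stores
    ``selected_specs_`` and ``provenance_``; ``transform`` computes the
    winning features for all instances and joins them to the static columns.
    """

    def __init__(self, knowledge_base=None, sample_size=5000, seed=0,
                 n_jobs=1):
        self.knowledge_base = knowledge_base
        self.sample_size = sample_size
        self.seed = seed
        self.n_jobs = n_jobs

    def fit(self, eav: EAVTable, instances: InstanceTable):
        if self.knowledge_base is None:
            raise ConfigError("a knowledge base is required")
        self.selected_specs_, self.provenance_ = select_spec_per_category(
            eav, instances, self.knowledge_base,
            sample_size=self.sample_size, seed=self.seed, n_jobs=self.n_jobs)
        return self

    def transform(self, eav: EAVTable, instances: InstanceTable
                  ) -> InstanceTable:
        return pivot_aggregate(eav, self.selected_specs_, instances,
                               n_jobs=self.n_jobs)

    def fit_transform(self, eav, instances):
        return self.fit(eav, instances).transform(eav, instances)
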
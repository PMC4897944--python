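"""Domain containers for tall (entity-attribute-value) and wide clinical tables.

EAV tables store one clinical event per row: the entity is the pair
(patient id, timestamp), the attribute names a clinical parameter, and the
value carries its recorded value.  Wide ("instance") tables hold one row per
prediction instance with typed feature columns and an optional target.
This module also owns deterministic splitting and the doubling
progressive-sampling schedule used by the search engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EAV_COLUMNS = ["patient_id", "timestamp", "attribute", "value"]


class ConfigError(ValueError):
    """A configuration or file-contract violation that must abort the run."""


@dataclass
class EAVTable:
    """Tall table of clinical events.

    ``frame`` has columns ``patient_id`` (str), ``timestamp``
    (timezone-naive datetime64), ``attribute`` (str) and ``value``
    (object: float where parseable, else str).  ``n_dropped`` counts input
    rows discarded for unparseable timestamps.
    """

    frame: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in EAV_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"EAV table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.frame)

    def attributes(self) -> list[str]:
        return sorted(self.frame["attribute"].unique())


@dataclass
class InstanceTable:
    """Wide per-instance table.

    ``frame`` carries one row per instance; ``instance_id`` is a column.
    ``target`` names the target column (or None), ``target_type`` is
    ``"categorical"`` or ``"continuous"``.  ``index_date_col`` optionally
    names a datetime column anchoring temporal windows.
    """

    frame: pd.DataFrame
    target: str | None = None
    target_type: str | None = None
    index_date_col: str | None = None
    column_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ConfigError("duplicate column names in instance table")
        if "instance_id" not in self.frame.columns:
            raise ConfigError("instance table requires an instance_id column")
        if self.target is not None and self.target not in self.frame.columns:
            raise ConfigError(f"target column {self.target!r} not present")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def feature_columns(self) -> list[str]:
        skip = {"instance_id", self.target, self.index_date_col}
        return [c for c in self.frame.columns if c not in skip]

    def ids(self) -> list:
        return list(self.frame["instance_id"])

    def subset(self, ids) -> "InstanceTable":
        idx = self.frame["instance_id"].isin(set(ids))
        return InstanceTable(
            self.frame.loc[idx].reset_index(drop=True),
            target=self.target,
            target_type=self.target_type,
            index_date_col=self.index_date_col,
            column_types=dict(self.column_types),
        )


def _parse_value(v):
    if pd.isna(v) or v == "":
        return np.nan
    try:
        return float(v)
    except (TypeError, ValueError):
        return str(v)


def read_eav_csv(path, dialect: dict[str, str] | None = None) -> EAVTable:
    """Read an EAV CSV; rows with unparseable timestamps are dropped.

    ``dialect`` optionally maps the canonical column names to the file's
    header names.  A header lacking a required column is a fatal
    :class:`ConfigError`; an empty file yields an empty table.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for canon in EAV_COLUMNS:
        src = (dialect or {}).get(canon, canon)
        if src not in raw.columns:
            raise ConfigError(f"EAV CSV {path} lacks required column {src!r}")
        rename[src] = canon
    raw = raw.rename(columns=rename)[EAV_COLUMNS]
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad = ts.isna()
    n_dropped = int(bad.sum())
    frame = raw.loc[~bad].copy()
    frame["timestamp"] = ts[~bad]
    frame["value"] = frame["value"].map(_parse_value)
    frame = frame.reset_index(drop=True)
    return EAVTable(frame, n_dropped=n_dropped)


def write_eav_csv(table: EAVTable, path) -> None:
    out = table.frame.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_instance_csv(path, target: str | None = None,
                      column_types: dict[str, str] | None = None,
                      index_date_col: str | None = None) -> InstanceTable:
    """Read a wide CSV.  ``column_types`` maps columns to
    ``numeric``/``categorical``/``datetime``; unlisted columns are inferred
    (numeric if fully parseable)."""
    frame = pd.read_csv(path)
    column_types = dict(column_types or {})
    for col, kind in column_types.items():
        if col not in frame.columns:
            raise ConfigError(f"declared column {col!r} not in {path}")
        if kind == "numeric":
            frame[col] = pd.to_numeric(frame[col])
        elif kind == "categorical":
            frame[col] = frame[col].astype(object)
        elif kind == "datetime":
            frame[col] = pd.to_datetime(frame[col])
    if index_date_col and index_date_col not in column_types:
        frame[index_date_col] = pd.to_datetime(frame[index_date_col])
    target_type = None
    if target is not None:
        target_type = ("continuous"
                       if column_types.get(target) == "numeric"
                       or (target not in column_types
                           and pd.api.types.is_float_dtype(frame[target]))
                       else "categorical")
    return InstanceTable(frame, target=target, target_type=target_type,
                         index_date_col=index_date_col,
                         column_types=column_types)


def write_instance_csv(table: InstanceTable, path) -> None:
    out = table.frame.copy()
    if table.index_date_col:
        out[table.index_date_col] = pd.to_datetime(
            out[table.index_date_col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# splitting and the progressive-sampling schedule
# ---------------------------------------------------------------------------

def stratified_split(table: InstanceTable, fractions, seed: int
                     ) -> list[InstanceTable]:
    """Partition into disjoint parts with the given fractions.

    For categorical targets the split is stratified: each part's per-class
    count is within one instance of exact proportionality.  Deterministic
    given ``seed``.
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_parts = len(fractions)
    parts_ids: list[list] = [[] for _ in range(n_parts)]

    def allot(ids: np.ndarray) -> None:
        ids = ids.copy()
        rng.shuffle(ids)
        n = len(ids)
        if n < n_parts:
            warnings.warn("class smaller than number of parts; round-robin")
        # largest-remainder apportionment keeps every part within 1 of exact
        quotas = np.array([f * n for f in fractions])
        base = np.floor(quotas).astype(int)
        rem = quotas - base
        short = n - base.sum()
        for j in np.argsort(-rem, kind="stable")[:short]:
            base[j] += 1
        start = 0
        for j, k in enumerate(base):
            parts_ids[j].extend(ids[start:start + k])
            start += k

    ids_arr = np.asarray(table.frame["instance_id"])
    if table.target is not None and table.target_type == "categorical":
        y = table.frame[table.target]
        for cls in sorted(pd.unique(y), key=str):
            allot(ids_arr[np.asarray(y == cls)])
    else:
        allot(ids_arr)
    return [table.subset(ids) for ids in parts_ids]


@dataclass
class SampleSchedule:
    """Nested doubling training samples with a fixed test sample."""

    initial_size: int
    sizes: list[int]
    test_ids: list
    train_ids_per_round: list[list]
    seed: int

    @property
    def n_rounds(self) -> int:
        return len(self.sizes)

    def train_ids(self, round_index: int) -> list:
        return self.train_ids_per_round[round_index]


def make_schedule(pool_ids, initial_size: int, test_fraction: float,
                  seed: int, stratify_labels=None) -> SampleSchedule:
    """Build the doubling schedule: the training sample doubles each round
    up to the full trainable pool while the test sample stays fixed.

    ``stratify_labels``, if given (mapping id -> class), stratifies the
    test draw.  Train sets are nested by construction (prefixes of one
    seeded shuffle of the trainable pool).
    """
    if not (0 < test_fraction <= 0.5):
        raise ConfigError("test_fraction must be in (0, 0.5]")
    pool_ids = list(pool_ids)
    rng = np.random.default_rng(seed)
    if stratify_labels is not None:
        test_ids: list = []
        by_cls: dict = {}
        for i in pool_ids:
            by_cls.setdefault(stratify_labels[i], []).append(i)
        for cls in sorted(by_cls, key=str):
            ids = np.asarray(by_cls[cls], dtype=object)
            rng.shuffle(ids)
            k = int(round(test_fraction * len(ids)))
            test_ids.extend(ids[:k])
        test_set = set(test_ids)
    else:
        ids = np.asarray(pool_ids, dtype=object)
        rng.shuffle(ids)
        k = int(round(test_fraction * len(ids)))
        test_ids = list(ids[:k])
        test_set = set(test_ids)
    trainable = np.asarray([i for i in pool_ids if i not in test_set],
                           dtype=object)
    rng.shuffle(trainable)
    pool = len(trainable)
    if initial_size >= pool:
        warnings.warn("initial size >= trainable pool; single-round schedule")
        sizes = [pool]
    else:
        sizes = [initial_size]
        while sizes[-1] < pool:
            sizes.append(min(2 * sizes[-1], pool))
    train_ids_per_round = [list(trainable[:s]) for s in sizes]
    return SampleSchedule(initial_size=sizes[0], sizes=sizes,
                          test_ids=list(test_ids),
                          train_ids_per_round=train_ids_per_round, seed=seed)


def default_initial_size(pool: int, n_classes: int = 2) -> int:
    """Small first-round sample: min(ceil(pool/8), 500), floor 2 per class."""
    return max(2 * n_classes, min(int(np.ceil(pool / 8)), 500))
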
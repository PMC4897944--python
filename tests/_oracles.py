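"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops over event lists, with no
shared code with the package's vectorized operator implementations.
"""

from __future__ import annotations

import datetime as dt
import math

BIN_DAYS = {"weekly": 7, "monthly": 30, "quarterly": 91}


def _to_dt(x) -> dt.datetime:
    if isinstance(x, dt.datetime):
        return x
    s = str(x)
    if "T" in s:
        return dt.datetime.fromisoformat(s.split(".")[0])
    try:
        return dt.datetime.fromisoformat(s)
    except ValueError:
        return dt.datetime.strptime(s[:10], "%Y-%m-%d")


def _in_window(events, window):
    start, end = _to_dt(window[0]), _to_dt(window[1])
    out = [(_to_dt(t), v) for t, v in events]
    out.sort(key=lambda tv: tv[0])
    return [(t, v) for t, v in out if start < t <= end], start, end


def _numeric(vals):
    out = []
    for v in vals:
        if isinstance(v, bool):
            continue
        if isinstance(v, (int, float)) and not (isinstance(v, float)
                                                and math.isnan(v)):
            out.append(float(v))
    return out


def brute_apply(op_id, events, window, params=None):
    params = params or {}
    ev, start, end = _in_window(events, window)
    times = [t for t, _ in ev]
    nums = _numeric([v for _, v in ev])

    if op_id == "count":
        return len(ev)
    if op_id == "presence":
        return 1 if ev else 0
    if op_id == "duration_days":
        if not ev:
            return 0.0
        return (times[-1] - times[0]).total_seconds() / 86400.0
    if op_id == "value_min":
        return min(nums) if nums else float("nan")
    if op_id == "value_max":
        return max(nums) if nums else float("nan")
    if op_id == "value_mean":
        return sum(nums) / len(nums) if nums else float("nan")
    if op_id == "most_recent_value":
        return nums[-1] if nums else float("nan")
    if op_id in ("value_increasing", "med_intensified"):
        if len(nums) < 2:
            return 0
        return int(all(b > a for a, b in zip(nums, nums[1:])))
    if op_id in ("value_decreasing", "med_deintensified"):
        if len(nums) < 2:
            return 0
        return int(all(b < a for a, b in zip(nums, nums[1:])))
    if op_id == "value_change":
        return nums[-1] - nums[0] if nums else float("nan")
    if op_id == "value_relative_change":
        if not nums or nums[0] == 0:
            return float("nan")
        return (nums[-1] - nums[0]) / abs(nums[0])
    if op_id == "fraction_high":
        if not nums:
            return float("nan")
        lo, hi = params["normal_range"]
        return sum(1 for v in nums if v > hi) / len(nums)
    if op_id == "fraction_low":
        if not nums:
            return float("nan")
        lo, hi = params["normal_range"]
        return sum(1 for v in nums if v < lo) / len(nums)
    if op_id == "fraction_normal":
        if not nums:
            return float("nan")
        lo, hi = params["normal_range"]
        return sum(1 for v in nums if lo <= v <= hi) / len(nums)
    if op_id == "fraction_equal":
        if not nums:
            return float("nan")
        return sum(1 for v in nums if v == params["value"]) / len(nums)
    if op_id in ("freq_increasing", "freq_decreasing"):
        bdays = BIN_DAYS[params.get("bin", "monthly")]
        total_days = (end - start).total_seconds() / 86400.0
        nbins = int(total_days // bdays)
        counts = []
        for j in range(nbins):  # j = 0 newest, laid back from the end
            hi = end - dt.timedelta(days=j * bdays)
            lo = end - dt.timedelta(days=(j + 1) * bdays)
            counts.append(sum(1 for t in times if lo < t <= hi))
        counts = counts[::-1]
        if len(counts) < 2:
            return 0
        if op_id == "freq_increasing":
            return int(all(b > a for a, b in zip(counts, counts[1:])))
        return int(all(b < a for a, b in zip(counts, counts[1:])))
    raise KeyError(op_id)


def brute_event_before_event(events_a, events_b, qualifier, gap_days,
                             window):
    ea, start, end = _in_window(events_a, window)
    eb, _, _ = _in_window(events_b, window)
    for tb, vb in eb:
        if not qualifier(vb):
            continue
        for ta, _ in ea:
            delta = (tb - ta).total_seconds() / 86400.0
            if 0 < delta <= gap_days:
                return 1
    return 0


def brute_information_gain_2x2(counts):
    """IG for a 2x2 contingency table [[n00, n01], [n10, n11]] of
    (feature value, class) counts, straight from the entropy formula."""
    n = sum(sum(r) for r in counts)

    def h(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    py = [(counts[0][c] + counts[1][c]) / n for c in (0, 1)]
    out = h(py)
    for r in (0, 1):
        nr = sum(counts[r])
        if nr:
            out -= nr / n * h([counts[r][c] / nr for c in (0, 1)])
    return out
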
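import warnings

import numpy as np
import pytest

import ehrlearn as el

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


def random_events(rng, n_max=8, days=200):
    """Random (iso-timestamp, value) events inside early 2020."""
    n = int(rng.integers(0, n_max + 1))
    offs = np.sort(rng.uniform(0, days * 86400, n))
    vals = rng.normal(1.0, 2.0, n)
    base = np.datetime64("2020-01-01T00:00:00")
    return [(str(base + np.timedelta64(int(o), "s")), float(v))
            for o, v in zip(offs, vals)]


@pytest.fixture(scope="session")
def small_cohort():
    spec = el.CohortSpec(n_patients=250, seed=11)
    return spec, *el.generate_eav_cohort(spec)


@pytest.fixture(scope="session")
def utilization_kb():
    return el.KnowledgeBase(
        attribute_groups={"ed_visit": "utilization", "weight": "vitals"},
        attribute_types={"ed_visit": "event", "weight": "numeric"},
        group_categories={
            "utilization": [
                ("count", el.PeriodSchedule(30, 360, "arithmetic",
                                            step_days=30)),
                ("presence", el.PeriodSchedule(30, 360, "arithmetic",
                                               step_days=90))],
            "vitals": [("summary", el.PeriodSchedule(90, 360))]},
        normal_ranges={"weight": (60.0, 100.0)})


@pytest.fixture(scope="session")
def rule_benchmark():
    return el.generate_benchmark(el.BenchmarkSpec(
        n_instances=800, n_features=6, family="rule", seed=7))
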
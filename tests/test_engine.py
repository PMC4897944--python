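import numpy as np
import pytest

import ehrlearn as el
from ehrlearn.data_model import ConfigError
from ehrlearn.engine import (TrialResult, build_ensemble,
                             eliminate_algorithms, eliminate_evaluators,
                             prefilter_features, scale_accuracy,
                             screen_random_group)
from ehrlearn.space import Configuration, SearchSpace


def _trial(alg="a", quality=0.5, status="completed", evaluator="none",
           size=100, cfg_extra=()):
    cfg = Configuration(alg, tuple(cfg_extra), "none", evaluator)
    return TrialResult(cfg, 0, size, quality, 0.0, status, 0)


class TestPrefilter:
    def test_signal_survives_constant_removed_mandatory_kept(self):
        rng = np.random.default_rng(0)
        n = 500
        signal = rng.normal(size=n)
        y = (signal > 0).astype(int)
        X = np.column_stack([signal, np.ones(n), rng.normal(size=n)])
        kept = prefilter_features(X, y, "classification",
                                  ["signal", "const", "noise"],
                                  mandatory=("const",), seed=0)
        assert "signal" in kept
        assert "const" in kept          # mandatory despite zero relevance
        kept2 = prefilter_features(X, y, "classification",
                                   ["signal", "const", "noise"], seed=0)
        assert "const" not in kept2

    def test_top_k_rule(self):
        rng = np.random.default_rng(1)
        n = 400
        s = rng.normal(size=n)
        y = (s > 0).astype(int)
        X = np.column_stack([s, rng.normal(size=n), rng.normal(size=n)])
        kept = prefilter_features(X, y, "classification",
                                  ["s", "n1", "n2"], top_k=1, seed=0)
        assert kept == ["s"]


class TestEliminateAlgorithms:
    def test_margin_rule(self):
        assert eliminate_algorithms({"A": 0.80, "B": 0.78, "C": 0.55},
                                    delta=0.10) == ["A", "B"]

    def test_all_equal_all_survive(self):
        assert sorted(eliminate_algorithms({"A": .7, "B": .7, "C": .7},
                                           0.05)) == ["A", "B", "C"]

    def test_single_algorithm_survives(self):
        assert eliminate_algorithms({"A": 0.1}, 0.1) == ["A"]

    def test_final_round_keeps_argmax_only(self):
        assert eliminate_algorithms({"A": .8, "B": .79}, 0.1,
                                    final=True) == ["A"]

    def test_min_survivors_backfills(self):
        out = eliminate_algorithms({"A": .9, "B": .5, "C": .4}, 0.05,
                                   min_survivors=2)
        assert out == ["A", "B"]

    def test_untested_algorithm_ranks_last(self):
        out = eliminate_algorithms({"A": .8, "B": None}, 0.1,
                                   min_survivors=1)
        assert out == ["A"]


class TestEliminateEvaluators:
    EVS = ["none", "e1", "e2", "e3", "e4", "e5", "e6"]

    def _ledger(self, n_per=25):
        ledger = []
        quality = {"e1": .9, "e2": .85, "e3": .8, "e4": .75, "e5": .7,
                   "e6": .65}
        for e, q in quality.items():
            for i in range(n_per):
                ledger.append(_trial(quality=q - 0.001 * i, evaluator=e))
        return ledger

    def test_drops_worst_one_per_round(self):
        evs = eliminate_evaluators(self._ledger(), self.EVS, max_keep=4)
        assert evs == ["none", "e1", "e2", "e3", "e4", "e5"]

    def test_converges_to_max_keep(self):
        evs = list(self.EVS)
        for _ in range(5):
            evs = eliminate_evaluators(self._ledger(), evs, max_keep=4)
        assert evs == ["none", "e1", "e2", "e3", "e4"]

    def test_judgment_waits_for_min_tests(self):
        evs = eliminate_evaluators(self._ledger(n_per=12), self.EVS,
                                   max_keep=4, min_tests=20)
        assert evs == self.EVS

    def test_max_keep_at_roster_size_no_elimination(self):
        evs = eliminate_evaluators(self._ledger(), self.EVS, max_keep=6)
        assert evs == self.EVS


class TestScaleAccuracy:
    def test_mean_uplift_applied(self):
        ledger = []
        for i, (lo, hi) in enumerate([(0.60, 0.70), (0.62, 0.72)]):
            cfg_extra = (("p", i),)
            ledger.append(_trial(quality=lo, size=100, cfg_extra=cfg_extra))
            ledger.append(_trial(quality=hi, size=400, cfg_extra=cfg_extra))
        assert scale_accuracy(0.65, "a", ledger, 100, 400) == \
            pytest.approx(0.75)

    def test_no_pairs_falls_back_to_input(self):
        assert scale_accuracy(0.65, "a", [], 100, 400) == 0.65

    def test_estimate_clipped(self):
        ledger = [_trial(quality=0.5, size=100, cfg_extra=(("p", 0),)),
                  _trial(quality=1.0, size=400, cfg_extra=(("p", 0),))]
        assert scale_accuracy(0.9, "a", ledger, 100, 400) == 1.0


class TestScreening:
    def test_top_ten_by_round1_quality(self):
        cands = [Configuration("a", (("p", i),)) for i in range(30)]
        quals = [i / 100 for i in range(30)]
        top, rest = screen_random_group(cands, quals, group_size=10)
        assert len(top) == 10 and len(rest) == 20
        assert {c.params[0][1] for c in top} == set(range(20, 30))

    def test_failed_screens_rank_last(self):
        cands = [Configuration("a", (("p", i),)) for i in range(12)]
        quals = [None] * 6 + [0.5] * 6
        top, rest = screen_random_group(cands, quals, group_size=10)
        assert all(q is None for _, q in rest)


class _FakeModel:
    def __init__(self, scores, classes=np.array([0, 1])):
        self._s = np.asarray(scores, dtype=float)
        self.classes = classes

    def score_matrix(self, X=None):
        return self._s


class TestEnsemble:
    def _y(self):
        return np.array([0, 0, 1, 1, 0, 1, 0, 1])

    def _proba(self, p1):
        p1 = np.asarray(p1, dtype=float)
        return np.column_stack([1 - p1, p1])

    def test_library_of_one(self):
        y = self._y()
        m = _FakeModel(self._proba([.1, .2, .8, .9, .3, .7, .4, .6]))
        ens = build_ensemble([m], y, "classification",
                             cached_scores=[m.score_matrix()])
        assert ens.members == [m] and list(ens.weights) == [1.0]

    def test_duplicate_of_best_splits_weight_without_quality_loss(self):
        y = self._y()
        s = self._proba([.1, .2, .8, .9, .3, .7, .4, .6])
        lib = [_FakeModel(s), _FakeModel(s)]
        ens = build_ensemble(lib, y, "classification", iterations=10,
                             cached_scores=[m.score_matrix() for m in lib])
        from ehrlearn.engine import quality_of
        assert quality_of(ens.score_matrix(None), y, "classification") == \
            quality_of(s, y, "classification")

    def test_hillclimb_never_below_best_single(self):
        from ehrlearn.engine import quality_of
        y = self._y()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lib = [_FakeModel(self._proba(rng.uniform(0, 1, len(y))))
                   for _ in range(6)]
            scores = [m.score_matrix() for m in lib]
            best_single = max(quality_of(s, y, "classification")
                              for s in scores)
            ens = build_ensemble(lib, y, "classification", iterations=15,
                                 cached_scores=scores)
            assert quality_of(ens.score_matrix(None), y,
                              "classification") >= best_single - 1e-12

    def test_complementary_members_can_beat_best_single(self):
        from ehrlearn.engine import quality_of
        y = self._y()
        a = self._proba([.1, .6, .9, .4, .2, .8, .45, .55])
        b = self._proba([.6, .1, .4, .9, .45, .55, .2, .8])
        lib = [_FakeModel(a), _FakeModel(b)]
        scores = [m.score_matrix() for m in lib]
        ens = build_ensemble(lib, y, "classification", iterations=20,
                             cached_scores=scores)
        best_single = max(quality_of(s, y, "classification")
                          for s in scores)
        assert quality_of(ens.score_matrix(None), y,
                          "classification") >= best_single


SMALL = dict(algorithms=["decision_tree", "naive_bayes"],
             fs_evaluators=["none", "infogain"], n_random=6,
             min_evaluator_tests=4, random_pool_size=200,
             ensemble_iterations=8)


class TestSearch:
    def test_single_algorithm_single_config(self, rule_benchmark):
        est = el.search(rule_benchmark, seed=0,
                        algorithms=["decision_tree"],
                        fs_evaluators=["none"], n_random=0,
                        min_evaluator_tests=0, max_rounds=1,
                        ensemble_iterations=2)
        assert est.best_config_.algorithm == "decision_tree"
        assert est.best_config_.params_dict() == {"max_depth": 5,
                                                  "min_samples_leaf": 1}

    def test_abort_after_round_one_still_returns_model(self,
                                                       rule_benchmark):
        est = el.search(rule_benchmark, seed=1, max_rounds=1, **SMALL)
        assert est.best_quality_ > 0.5
        assert est.final_model_.predict(
            rule_benchmark.frame[est.feature_names_].to_numpy(
                dtype=float)).shape == (len(rule_benchmark),)

    def test_full_search_properties(self, rule_benchmark):
        est = el.search(rule_benchmark, seed=2, **SMALL)
        # best-so-far curve nondecreasing
        assert all(b >= a for a, b in zip(est.curve_.y, est.curve_.y[1:]))
        # survivor sets shrink weakly
        surv = [set(h["survivors"]) for h in est.round_history_]
        assert all(s2 <= s1 for s1, s2 in zip(surv, surv[1:]))
        evs = [set(h["evaluators"]) for h in est.round_history_]
        assert all(e2 <= e1 for e1, e2 in zip(evs, evs[1:]))
        # potentials recomputed from completed non-screen trials only
        for h in est.round_history_:
            for a, p in h["potentials"].items():
                want = [t.quality for t in est.ledger_
                        if t.config.algorithm == a
                        and t.status == "completed" and not t.screen
                        and t.round_index <= h["round"]]
                if p is not None and want:
                    assert p <= max(want) + 1e-12
        # holdout is disjoint from guidance
        assert not set(est.guide_ids_) & set(est.holdout_ids_)

    def test_estimated_trials_never_drive_potentials(self, rule_benchmark):
        est = el.search(rule_benchmark, seed=3, initial_size=60,
                        screen_from_round=2, screen_count=8,
                        **SMALL)
        estimated = [t for t in est.ledger_ if t.status == "estimated"]
        completed_best = max(t.quality for t in est.ledger_
                             if t.status == "completed" and not t.screen)
        assert max(est.curve_.y) <= completed_best + 1e-12
        for h in est.round_history_:
            for a, p in h["potentials"].items():
                comp = [t.quality for t in est.ledger_
                        if t.config.algorithm == a and not t.screen
                        and t.status == "completed"
                        and t.round_index <= h["round"]]
                if p is not None:
                    assert comp and p == pytest.approx(max(comp))
        assert isinstance(estimated, list)  # screening may or may not fire

    @pytest.mark.parametrize("workers", [2, 4])
    def test_deterministic_replay_across_workers(self, rule_benchmark,
                                                 workers):
        def sig(est):
            return [(t.config.key(), t.round_index, t.size,
                     None if t.quality is None else round(t.quality, 12),
                     t.status) for t in est.ledger_]
        base = el.search(rule_benchmark, seed=9, workers=1, **SMALL)
        other = el.search(rule_benchmark, seed=9, workers=workers, **SMALL)
        assert sig(base) == sig(other)

    def test_every_trial_failing_is_an_error(self):
        bad = el.InstanceTable(
            el.generate_benchmark(el.BenchmarkSpec(
                n_instances=60, n_features=1, seed=0)).frame.assign(
                    target=["x"] * 60),
            target="target", target_type="categorical")
        with pytest.raises(ConfigError):
            el.search(bad, seed=0, algorithms=["decision_tree"],
                      n_random=0, min_evaluator_tests=0)

    def test_mandatory_features_always_in_model(self, rule_benchmark):
        est = el.search(rule_benchmark, seed=4, max_rounds=1,
                        mandatory_features=("f5",),
                        algorithms=["decision_tree"],
                        fs_evaluators=["none", "infogain"], n_random=6,
                        min_evaluator_tests=4, ensemble_iterations=2)
        i5 = est.feature_names_.index("f5")
        assert i5 in set(est.best_model_.fs_cols)


class TestRefinement:
    def test_no_flagged_params_identity(self, rule_benchmark):
        est = el.search(rule_benchmark, seed=5, max_rounds=1, **SMALL)
        assert not any(t.config.provenance == "refined"
                       for t in est.ledger_)

    def test_expensive_direction_explored_quality_never_drops(self):
        t = el.generate_benchmark(el.BenchmarkSpec(
            n_instances=500, n_features=5, family="rule", seed=12))
        est = el.search(t, seed=6, algorithms=["random_forest"],
                        fs_evaluators=["none"], n_random=3,
                        min_evaluator_tests=0, max_rounds=2,
                        refine_budget=3, ensemble_iterations=2)
        refined = [tr for tr in est.ledger_
                   if tr.config.provenance == "refined"]
        assert refined  # the flagged tree count was pushed upward
        base_best = max(tr.quality for tr in est.ledger_
                        if tr.status == "completed" and not tr.screen
                        and tr.config.provenance != "refined")
        assert est.best_quality_ >= base_best - 1e-12
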
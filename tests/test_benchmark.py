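"""Benchmark harness: MAE, pairing, significance calls, report round trips."""

import json
from statistics import median

import numpy as np
import pytest

from potencybench.benchmark import (
    BenchmarkReport,
    PotencyBenchmark,
    compare_methods,
    mae,
    run_benchmark,
    validate_report_dict,
)
from potencybench.regressors import PredictionSet
from potencybench.benchmark import TrialResult
from potencybench.datamods import SplitPlan


class TestMae:
    @pytest.mark.parametrize(
        "y, yhat, expected",
        [
            ((5, 6, 7), (5, 6, 7), 0.0),
            ((5, 7), (6, 6), 1.0),
            ((5.0, 8.0, 9.5), (6.0, 7.5, 9.5), 0.5),
        ],
    )
    def test_values(self, y, yhat, expected):
        assert mae(y, yhat) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            mae([], [])
        with pytest.raises(ValueError):
            mae([np.nan], [1.0])


def _fake_results(mae_by_method, class_id="C1", n_test=10):
    """TrialResults with prescribed per-trial MAE vectors (paired)."""
    results = []
    n = len(next(iter(mae_by_method.values())))
    plan = SplitPlan(train_ids=("a", "b"), test_ids=("c",), ratio=0.8, mode="random")
    for method, maes in mae_by_method.items():
        for t, v in enumerate(maes, start=1):
            ps = PredictionSet(method=method, test_ids=("c",), predicted=(6.0,))
            results.append(TrialResult(class_id=class_id, method=method, trial_index=t,
                                       mae=v, n_test=n_test, predictions=ps, split=plan))
    return results


class TestRunBenchmark:
    def test_cardinality_and_pairing(self, tiny_class):
        results = run_benchmark([tiny_class], methods=("MR", "1NN"), n_trials=3, seed=4)
        assert len(results) == 2 * 3
        by_trial = {}
        for r in results:
            by_trial.setdefault(r.trial_index, set()).add(r.split.train_ids)
        # all methods share one split within a trial
        assert all(len(v) == 1 for v in by_trial.values())

    def test_deterministic(self, tiny_class):
        a = run_benchmark([tiny_class], methods=("MR", "1NN"), n_trials=3, seed=4)
        b = run_benchmark([tiny_class], methods=("MR", "1NN"), n_trials=3, seed=4)
        assert [(r.method, r.trial_index, r.mae) for r in a] == \
               [(r.method, r.trial_index, r.mae) for r in b]

    def test_mr_trials_match_closed_form(self, tiny_class):
        results = run_benchmark([tiny_class], methods=("MR",), n_trials=3, seed=4)
        potency = {r.compound_id: r.potency for r in tiny_class.records}
        for r in results:
            train_median = median(potency[c] for c in r.split.train_ids)
            expected = np.mean([abs(potency[c] - train_median) for c in r.split.test_ids])
            assert r.mae == pytest.approx(expected, abs=1e-12)

    def test_unknown_method_rejected(self, tiny_class):
        with pytest.raises(ValueError):
            run_benchmark([tiny_class], methods=("DNN",))

    def test_too_small_class_skipped(self):
        from potencybench.containers import ActivityClass, CompoundRecord

        cls = ActivityClass("S", [CompoundRecord(f"c{i}", "S", "CCO", 6.0) for i in range(4)])
        assert run_benchmark([cls], methods=("MR",), n_trials=2, seed=0) == []


class TestCompareMethods:
    def test_identical_vectors_not_significant(self):
        maes = {"A": [0.5] * 10, "B": [0.5] * 10}
        report = compare_methods(_fake_results(maes))
        cell = report.pairwise["C1"]["A|B"]
        assert cell["p_value"] == 1.0 and not cell["significant"]

    def test_uniform_dominance_minimal_exact_p(self):
        a = [0.40 + 0.01 * t for t in range(10)]
        b = [v + 0.05 + 0.001 * t for t, v in enumerate(a)]  # distinct magnitudes
        report = compare_methods(_fake_results({"A": a, "B": b}))
        cell = report.pairwise["C1"]["A|B"]
        assert cell["p_value"] == pytest.approx(2 / 2**10, rel=1e-12)
        assert cell["significant"]  # at alpha = 0.005

    def test_p_values_in_unit_interval(self, tiny_class):
        results = run_benchmark([tiny_class], methods=("MR", "1NN", "kNN"), n_trials=4, seed=0)
        report = compare_methods(results)
        for pairs in report.pairwise.values():
            for cell in pairs.values():
                assert 0.0 <= cell["p_value"] <= 1.0

    def test_incomplete_cells_rejected(self):
        results = _fake_results({"A": [0.5] * 10, "B": [0.5] * 10})
        with pytest.raises(ValueError, match="C1"):
            compare_methods(results[:-1])

    def test_quartiles_and_median(self):
        maes = {"A": [float(t) for t in range(1, 11)]}
        report = compare_methods(_fake_results(maes))
        cell = report.cells["C1"]["A"]
        assert cell["median"] == pytest.approx(5.5)
        assert cell["min"] == 1.0 and cell["max"] == 10.0


class TestReportSerialization:
    @pytest.fixture()
    def report(self, tiny_class):
        results = run_benchmark([tiny_class], methods=("MR", "1NN"), n_trials=3, seed=4)
        return compare_methods(results)

    def test_json_round_trip(self, report, tmp_path):
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = BenchmarkReport.from_json(path)
        assert loaded.cells == report.cells
        assert loaded.pairwise == report.pairwise
        assert loaded.alpha == report.alpha

    def test_json_validates_against_schema(self, report):
        validate_report_dict(json.loads(report.to_json()))

    def test_malformed_report_rejected(self):
        with pytest.raises(ValueError):
            validate_report_dict({"alpha": 0.005, "n_trials": 10, "cells": {}})
        with pytest.raises(ValueError):
            validate_report_dict(
                {"alpha": 0.005, "n_trials": 10,
                 "cells": {"C": {"MR": {"maes": [], "median": 0}}}, "pairwise": {}}
            )

    def test_csv_row_counts(self, report, tmp_path):
        import pandas as pd

        report.write_csv(tmp_path)
        medians = pd.read_csv(tmp_path / "median_mae.csv")
        assert len(medians) == len(report.class_ids) * len(report.methods)
        trials = pd.read_csv(tmp_path / "trial_mae.csv")
        assert len(trials) == len(medians) * report.n_trials

    def test_summary_mentions_every_class(self, report):
        text = report.summary()
        for cid in report.class_ids:
            assert cid in text


class TestPotencyBenchmark:
    def test_model_results_workflow(self, tiny_class):
        bench = PotencyBenchmark([tiny_class], methods=("MR", "1NN"), n_trials=3, seed=4)
        report = bench.run()
        assert bench.trial_results_ is not None
        assert set(report.methods) == {"MR", "1NN"}
        best, value = report.best_method(tiny_class.class_id)
        assert best in {"MR", "1NN"} and value >= 0.0
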
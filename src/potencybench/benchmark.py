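"""Multi-trial benchmarking harness and its results object.

`PotencyBenchmark` is the model-like entry point: it is constructed from a
list of activity classes and a protocol (methods, split ratio and mode,
number of trials, master seed) and `run()` produces a `BenchmarkReport`.
Within each (class, trial) all methods share one split plan, so per-trial
MAE values are paired and method differences can be tested with the
Wilcoxon signed-rank test. Significance is called at a
Bonferroni-corrected alpha (default 0.005, i.e. 0.05 corrected for ten
comparisons).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error

from ._util import derive_seed
from .chem import compute_fingerprint
from .containers import ActivityClass
from .datamods import SplitPlan, analog_partition, extract_analog_series, random_split
from .regressors import METHODS, PredictionSet, fit_predict

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.005  # 0.05 Bonferroni-corrected for 10 comparisons


def mae(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean absolute error between experimental and predicted pIC50 values."""
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between y_true and y_pred")
    if len(y_true) == 0:
        raise ValueError("empty input")
    yt, yp = np.asarray(y_true, dtype=float), np.asarray(y_pred, dtype=float)
    if not (np.isfinite(yt).all() and np.isfinite(yp).all()):
        raise ValueError("non-finite values")
    return float(mean_absolute_error(yt, yp))


@dataclass(frozen=True)
class TrialResult:
    """MAE of one method on one trial's split of one class."""

    class_id: str
    method: str
    trial_index: int
    mae: float
    n_test: int
    predictions: PredictionSet
    split: SplitPlan

    def __post_init__(self) -> None:
        if self.mae < 0 or self.n_test < 1:
            raise ValueError("invalid trial result")


def run_benchmark(
    classes: Sequence[ActivityClass],
    methods: Sequence[str] = METHODS,
    ratio: float = 0.8,
    mode: str = "random",
    n_trials: int = 10,
    seed: int = 0,
) -> list[TrialResult]:
    """Run all methods over all classes for ``n_trials`` paired trials.

    For each (class, trial) one split plan is drawn and shared by every
    method, so per-trial results are paired. Classes too small for the
    split or the internal cross-validation (or, in analog mode, with fewer
    than two extractable series) are skipped with a logged warning. Fully
    reproducible from ``seed``.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if mode not in ("random", "analog_series"):
        raise ValueError(f"unknown split mode {mode!r}")

    results: list[TrialResult] = []
    for c_idx, cls in enumerate(classes):
        fps = {r.compound_id: compute_fingerprint(r.structure) for r in cls.records}
        records = {r.compound_id: r for r in cls.records}

        series = None
        if mode == "analog_series":
            series = extract_analog_series(cls)
            if len(series) < 2:
                logger.warning("class %s skipped: fewer than two analog series", cls.class_id)
                continue

        skipped = False
        for trial in range(1, n_trials + 1):
            split_seed = derive_seed(seed, c_idx, trial)
            try:
                if mode == "random":
                    plan = random_split(cls, ratio, trial_index=trial, seed=split_seed)
                else:
                    plan = analog_partition(series, ratio, seed=split_seed, trial_index=trial)
            except ValueError as err:
                logger.warning("class %s skipped: %s", cls.class_id, err)
                skipped = True
                break
            train = [records[i] for i in plan.train_ids]
            test = [records[i] for i in plan.test_ids]
            if len(train) < 5 or len(test) < 1:
                logger.warning("class %s skipped: split too small for internal CV", cls.class_id)
                skipped = True
                break
            cv_seed = derive_seed(seed, c_idx, trial, 1)
            for method in methods:
                ps = fit_predict(method, train, test, seed=cv_seed, fingerprints=fps)
                y_true = [records[i].potency for i in ps.test_ids]
                results.append(
                    TrialResult(class_id=cls.class_id, method=method, trial_index=trial,
                                mae=mae(y_true, ps.predicted), n_test=len(test),
                                predictions=ps, split=plan)
                )
        if skipped:
            results = [r for r in results if r.class_id != cls.class_id]
    return results


def _wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired MAE vectors.

    Zero differences are dropped (the classical convention); if every
    difference is zero the methods are indistinguishable and p = 1.
    """
    diffs = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(diffs == 0):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue)


@dataclass
class BenchmarkReport:
    """Aggregated benchmark results: per-cell MAE statistics and significance.

    ``cells`` maps class_id -> method -> {"maes", "median", "q1", "q3",
    "min", "max", "n_test"}; ``pairwise`` maps class_id -> "m1|m2" ->
    {"p_value", "significant"}.
    """

    cells: dict
    pairwise: dict
    alpha: float = DEFAULT_ALPHA
    n_trials: int = 10

    @property
    def class_ids(self) -> list[str]:
        return sorted(self.cells)

    @property
    def methods(self) -> list[str]:
        first = next(iter(self.cells.values()), {})
        return sorted(first)

    def median_mae(self, class_id: str, method: str) -> float:
        return self.cells[class_id][method]["median"]

    def best_method(self, class_id: str) -> tuple[str, float]:
        """Method with the lowest median MAE for a class (ties: method name)."""
        items = self.cells[class_id]
        best = min(items, key=lambda m: (items[m]["median"], m))
        return best, items[best]["median"]

    def summary(self) -> str:
        """Human-readable per-class table of median MAE values."""
        methods = self.methods
        lines = ["Potency prediction benchmark (median MAE over "
                 f"{self.n_trials} trials, alpha={self.alpha})"]
        header = f"{'class':<12}" + "".join(f"{m:>9}" for m in methods) + "   best"
        lines.append(header)
        lines.append("-" * len(header))
        for cid in self.class_ids:
            row = f"{cid:<12}"
            for m in methods:
                row += f"{self.cells[cid][m]['median']:>9.3f}"
            best, _ = self.best_method(cid)
            lines.append(row + f"   {best}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.class_ids:
            for m in sorted(self.cells[cid]):
                c = self.cells[cid][m]
                rows.append({"class_id": cid, "method": m, "median_mae": c["median"],
                             "q1": c["q1"], "q3": c["q3"], "min": c["min"],
                             "max": c["max"], "n_test": c["n_test"]})
        return pd.DataFrame(rows)

    def trials_frame(self) -> pd.DataFrame:
        """Long-format (boxplot-ready) per-trial MAE table."""
        rows = []
        for cid in self.class_ids:
            for m in sorted(self.cells[cid]):
                for t, v in enumerate(self.cells[cid][m]["maes"], start=1):
                    rows.append({"class_id": cid, "method": m, "trial": t, "mae": v})
        return pd.DataFrame(rows)

    def significance_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.pairwise):
            for pair in sorted(self.pairwise[cid]):
                m1, m2 = pair.split("|")
                cell = self.pairwise[cid][pair]
                rows.append({"class_id": cid, "method_a": m1, "method_b": m2,
                             "p_value": cell["p_value"], "significant": cell["significant"]})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "n_trials": self.n_trials,
                "cells": self.cells, "pairwise": self.pairwise}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "BenchmarkReport":
        validate_report_dict(data)
        return cls(cells=dict(data["cells"]), pairwise=dict(data["pairwise"]),
                   alpha=float(data["alpha"]), n_trials=int(data["n_trials"]))

    @classmethod
    def from_json(cls, source: str | Path) -> "BenchmarkReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def write_csv(self, out_dir: str | Path) -> None:
        """Write medians, long-format trials and the significance matrix."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "median_mae.csv", index=False)
        self.trials_frame().to_csv(out / "trial_mae.csv", index=False)
        self.significance_frame().to_csv(out / "significance.csv", index=False)


_CELL_KEYS = {"maes", "median", "q1", "q3", "min", "max", "n_test"}


def validate_report_dict(data: Mapping) -> None:
    """Structural validation of a serialized report (raises ValueError)."""
    for key in ("alpha", "n_trials", "cells", "pairwise"):
        if key not in data:
            raise ValueError(f"report missing key {key!r}")
    for cid, per_method in data["cells"].items():
        for m, cell in per_method.items():
            missing = _CELL_KEYS - set(cell)
            if missing:
                raise ValueError(f"cell ({cid}, {m}) missing {sorted(missing)}")
    for cid, pairs in data["pairwise"].items():
        for pair, cell in pairs.items():
            if "|" not in pair or not {"p_value", "significant"} <= set(cell):
                raise ValueError(f"malformed pairwise entry ({cid}, {pair})")
            if not 0.0 <= cell["p_value"] <= 1.0:
                raise ValueError(f"p-value out of [0,1] in ({cid}, {pair})")


def compare_methods(
    results: Sequence[TrialResult], alpha: float = DEFAULT_ALPHA
) -> BenchmarkReport:
    """Aggregate trial results into a report with pairwise significance calls.

    Requires complete cells: every (class, method) present must have the
    same trial indices so the Wilcoxon signed-rank test is paired.
    """
    by_cell: dict[tuple[str, str], dict[int, float]] = {}
    n_test: dict[tuple[str, str], int] = {}
    for r in results:
        by_cell.setdefault((r.class_id, r.method), {})[r.trial_index] = r.mae
        n_test[(r.class_id, r.method)] = r.n_test

    class_ids = sorted({cid for cid, _ in by_cell})
    cells: dict = {}
    pairwise: dict = {}
    for cid in class_ids:
        methods = sorted(m for c, m in by_cell if c == cid)
        trial_sets = {frozenset(by_cell[(cid, m)]) for m in methods}
        if len(trial_sets) != 1:
            raise ValueError(f"incomplete cells for class {cid}: unpaired trial indices")
        trials = sorted(next(iter(trial_sets)))
        cells[cid] = {}
        for m in methods:
            maes = [by_cell[(cid, m)][t] for t in trials]
            q1, med, q3 = np.percentile(maes, [25, 50, 75])
            cells[cid][m] = {"maes": maes, "median": float(med), "q1": float(q1),
                             "q3": float(q3), "min": float(min(maes)),
                             "max": float(max(maes)), "n_test": n_test[(cid, m)]}
        pairwise[cid] = {}
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1:]:
                p = _wilcoxon_paired(cells[cid][m1]["maes"], cells[cid][m2]["maes"])
                pairwise[cid][f"{m1}|{m2}"] = {"p_value": p, "significant": bool(p < alpha)}
    n_trials = len(next(iter(by_cell.values()))) if by_cell else 0
    return BenchmarkReport(cells=cells, pairwise=pairwise, alpha=alpha, n_trials=n_trials)


class PotencyBenchmark:
    """Benchmark model: activity classes plus a prediction protocol.

    Parameters
    ----------
    classes : list of ActivityClass
        The (possibly modified) activity classes to evaluate on.
    methods : sequence of {"SVR", "kNN", "1NN", "MR"}
    ratio : float
        Training fraction of each split.
    mode : {"random", "analog_series"}
    n_trials : int
        Independent paired trials per class.
    alpha : float
        Significance level for Wilcoxon calls (Bonferroni-corrected).
    seed : int
        Master seed; every split and internal CV derives from it.
    """

    def __init__(
        self,
        classes: Sequence[ActivityClass],
        methods: Sequence[str] = METHODS,
        ratio: float = 0.8,
        mode: str = "random",
        n_trials: int = 10,
        alpha: float = DEFAULT_ALPHA,
        seed: int = 0,
    ):
        self.classes = list(classes)
        self.methods = tuple(methods)
        self.ratio = ratio
        self.mode = mode
        self.n_trials = n_trials
        self.alpha = alpha
        self.seed = seed
        self.trial_results_: list[TrialResult] | None = None

    def run(self) -> BenchmarkReport:
        """Execute all trials and aggregate; keeps raw trials on the instance."""
        self.trial_results_ = run_benchmark(
            self.classes, methods=self.methods, ratio=self.ratio,
            mode=self.mode, n_trials=self.n_trials, seed=self.seed,
        )
        return compare_methods(self.trial_results_, alpha=self.alpha)

    fit = run  # estimator-style alias
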
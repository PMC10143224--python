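"""Potency predictors of graded complexity behind one fit/predict contract.

Four methods, from the field's standard machine-learning approach down to
the simplest possible control:

* **SVR** — support vector regression with the Tanimoto kernel on 2048-bit
  ECFP4 fingerprints; the regularization constant C is selected from a
  fixed grid by 5-fold internal cross-validation on the training set.
* **kNN** — mean potency of the k most Tanimoto-similar training
  compounds, k selected from {1, 3, 5} by the same internal CV.
* **1-NN** — the nearest training compound's potency, always reported
  alongside tuned kNN.
* **MR** — median regression: every test compound receives the training
  set's median potency.

The internal model-selection metric is the mean absolute error, matching
the evaluation metric; grid ties resolve to the smallest C (or k) for
regularization parsimony. Similarity ties in neighbor ranking resolve by
ascending compound_id, so predictions are permutation-invariant in
training order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR as _SKSVR

from .chem import Fingerprint, compute_fingerprint, tanimoto_matrix
from .containers import CompoundRecord

METHODS = ("SVR", "kNN", "1NN", "MR")

#: C grid for the Tanimoto-kernel SVR.
DEFAULT_C_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 10.0, 100.0, 10000.0)


@dataclass(frozen=True)
class SvrConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    epsilon: float = 0.1
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("C values must be positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass(frozen=True)
class KnnConfig:
    k_grid: tuple[int, ...] = (1, 3, 5)
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.k_grid):
            raise ValueError("k values must be positive")
        if self.inner_cv_folds < 2:
            raise ValueError("inner_cv_folds must be >= 2")


@dataclass(frozen=True)
class PredictionSet:
    """Predictions of one method for one train/test split."""

    method: str
    test_ids: tuple[str, ...]
    predicted: tuple[float, ...]
    chosen_hyperparameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.test_ids) != len(self.predicted):
            raise ValueError("one prediction per test compound required")
        if not all(np.isfinite(self.predicted)):
            raise ValueError("predictions must be finite")


def _fingerprints(
    records: Sequence[CompoundRecord], cache: Mapping[str, Fingerprint] | None
) -> list[Fingerprint]:
    if cache is None:
        return [compute_fingerprint(r.structure) for r in records]
    return [cache[r.compound_id] for r in records]


def _mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.mean(np.abs(y_true - y_pred)))


# ---------------------------------------------------------------------------
# nearest-neighbor machinery (shared by kNN and 1-NN so that kNN with
# k_grid={1} is bit-for-bit identical to 1-NN)


def _rank_neighbors(sim: np.ndarray, train_ids: Sequence[str]) -> np.ndarray:
    """Per test row, training indices ranked by similarity desc, id asc."""
    id_rank = np.argsort(np.argsort(np.asarray(train_ids, dtype=object)))
    # lexsort: primary key last; -sim descending, then id ascending
    return np.stack([np.lexsort((id_rank, -row)) for row in sim])


def _knn_predict(sim: np.ndarray, train_ids: Sequence[str], y_train: np.ndarray, k: int) -> np.ndarray:
    order = _rank_neighbors(sim, train_ids)
    return y_train[order[:, :k]].mean(axis=1)


def fit_predict_knn(
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    config: KnnConfig | None = None,
    fingerprints: Mapping[str, Fingerprint] | None = None,
) -> PredictionSet:
    """k-nearest-neighbor regression with internal CV selection of k."""
    config = config or KnnConfig()
    if max(config.k_grid) > len(train):
        raise ValueError(f"k={max(config.k_grid)} exceeds training set size {len(train)}")
    fps_train = _fingerprints(train, fingerprints)
    fps_test = _fingerprints(test, fingerprints)
    train_ids = [r.compound_id for r in train]
    y_train = np.array([r.potency for r in train])

    if len(config.k_grid) == 1:
        best_k = config.k_grid[0]
    else:
        sim_train = tanimoto_matrix(fps_train)
        folds = KFold(n_splits=config.inner_cv_folds, shuffle=True, random_state=config.seed)
        scores = {k: [] for k in config.k_grid}
        for tr_idx, va_idx in folds.split(sim_train):
            usable = [k for k in config.k_grid if k <= len(tr_idx)]
            sub_sim = sim_train[np.ix_(va_idx, tr_idx)]
            sub_ids = [train_ids[i] for i in tr_idx]
            for k in usable:
                pred = _knn_predict(sub_sim, sub_ids, y_train[tr_idx], k)
                scores[k].append(_mae(y_train[va_idx], pred))
        mean_scores = {k: float(np.mean(v)) for k, v in scores.items() if v}
        best = min(mean_scores.values())
        best_k = min(k for k, s in mean_scores.items() if s == best)

    sim = tanimoto_matrix(fps_test, fps_train)
    pred = _knn_predict(sim, train_ids, y_train, best_k)
    return PredictionSet(method="kNN", test_ids=tuple(r.compound_id for r in test),
                         predicted=tuple(float(p) for p in pred),
                         chosen_hyperparameters={"k": best_k})


def predict_1nn(
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    fingerprints: Mapping[str, Fingerprint] | None = None,
) -> PredictionSet:
    """Assign each test compound the potency of its most similar trainer."""
    if not train:
        raise ValueError("empty training set")
    ps = fit_predict_knn(train, test, KnnConfig(k_grid=(1,)), fingerprints)
    return PredictionSet(method="1NN", test_ids=ps.test_ids, predicted=ps.predicted,
                         chosen_hyperparameters={"k": 1})


def predict_mr(
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    fingerprints: Mapping[str, Fingerprint] | None = None,
) -> PredictionSet:
    """Median regression: every prediction is the training-set median potency.

    Even-count median is the mean of the two central values.
    """
    if not train:
        raise ValueError("empty training set")
    m = float(median(r.potency for r in train))
    return PredictionSet(method="MR", test_ids=tuple(r.compound_id for r in test),
                         predicted=tuple(m for _ in test))


def fit_predict_svr(
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    config: SvrConfig | None = None,
    fingerprints: Mapping[str, Fingerprint] | None = None,
) -> PredictionSet:
    """Tanimoto-kernel SVR with grid-searched C (5-fold internal CV).

    The kernel is passed to scikit-learn's SVR as a precomputed matrix;
    test-versus-train kernel rows use the same Tanimoto similarity.
    """
    config = config or SvrConfig()
    if len(train) < config.inner_cv_folds:
        raise ValueError("training set smaller than the number of internal CV folds")
    fps_train = _fingerprints(train, fingerprints)
    fps_test = _fingerprints(test, fingerprints)
    y_train = np.array([r.potency for r in train])
    K_train = tanimoto_matrix(fps_train)

    folds = KFold(n_splits=config.inner_cv_folds, shuffle=True, random_state=config.seed)
    scores = {c: [] for c in config.c_grid}
    for tr_idx, va_idx in folds.split(K_train):
        K_tr = K_train[np.ix_(tr_idx, tr_idx)]
        K_va = K_train[np.ix_(va_idx, tr_idx)]
        for c in config.c_grid:
            model = _SKSVR(kernel="precomputed", C=c, epsilon=config.epsilon)
            model.fit(K_tr, y_train[tr_idx])
            scores[c].append(_mae(y_train[va_idx], model.predict(K_va)))
    mean_scores = {c: float(np.mean(v)) for c, v in scores.items()}
    best = min(mean_scores.values())
    best_c = min(c for c, s in mean_scores.items() if s == best)

    model = _SKSVR(kernel="precomputed", C=best_c, epsilon=config.epsilon)
    model.fit(K_train, y_train)
    K_test = tanimoto_matrix(fps_test, fps_train)
    pred = model.predict(K_test)
    return PredictionSet(method="SVR", test_ids=tuple(r.compound_id for r in test),
                         predicted=tuple(float(p) for p in pred),
                         chosen_hyperparameters={"C": best_c, "epsilon": config.epsilon})


def fit_predict(
    method: str,
    train: Sequence[CompoundRecord],
    test: Sequence[CompoundRecord],
    seed: int = 0,
    fingerprints: Mapping[str, Fingerprint] | None = None,
) -> PredictionSet:
    """Dispatch on method name ('SVR', 'kNN', '1NN', 'MR')."""
    if method == "SVR":
        return fit_predict_svr(train, test, SvrConfig(seed=seed), fingerprints)
    if method == "kNN":
        return fit_predict_knn(train, test, KnnConfig(seed=seed), fingerprints)
    if method == "1NN":
        return predict_1nn(train, test, fingerprints)
    if method == "MR":
        return predict_mr(train, test, fingerprints)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
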
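"""One-vs-all SVM classification of survival profiles.

One binary margin classifier is trained per survival class on that class's
selected voxels; hyper-parameters (kernel, regularization, kernel parameters)
are tuned to maximise the mean informedness (Youden's J = sensitivity +
specificity - 1) over stratified 10-fold cross-validation, by either random
search or a sequential Gaussian-process expected-improvement search.  Final
performance is reported on a stratified 10% holdout: per-class error rate,
informedness, and the c-statistic (tie-averaged rank AUROC of the continuous
decision values).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .laplacian import ClassFeatureRanking

__all__ = [
    "OvaModel",
    "EvalReport",
    "SearchResult",
    "split_train_test",
    "informedness",
    "auroc",
    "tune_hyperparameters",
    "train_ova",
    "evaluate_holdout",
    "baseline_knn",
]

KERNELS = ("linear", "rbf", "poly")
LOG_C_RANGE = (-3.0, 3.0)
LOG_GAMMA_RANGE = (-4.0, 1.0)
DEGREES = (2, 3, 4)


def split_train_test(
    subject_ids: Sequence,
    labels: Sequence[int],
    test_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list, list]:
    """Stratified train/holdout split with test size round(f * n).

    The test size is floored at the number of classes so stratification can
    place at least one holdout subject per class.
    """
    subject_ids = list(subject_ids)
    labels = np.asarray(labels)
    if len(subject_ids) != labels.size:
        raise ValueError("subject_ids and labels must have equal length")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"every class needs >= 2 members; offending: {bad.tolist()}")
    n = labels.size
    n_test = max(int(round(test_fraction * n)), classes.size)
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=n_test, stratify=labels, random_state=seed
    )
    return [subject_ids[i] for i in train_idx], [subject_ids[i] for i in test_idx]


def informedness(confusion: Sequence[int]) -> float:
    """Youden's J from 2x2 counts (TP, FN, FP, TN)."""
    tp, fn, fp, tn = (int(v) for v in confusion)
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("informedness needs both positive and negative examples")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def auroc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """c-statistic via the rank statistic, ties averaged.

    Equals the probability that a random positive outranks a random negative
    (ties counted 1/2).
    """
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# hyper-parameter search


@dataclass
class SearchResult:
    kernel: str
    C: float
    gamma: float | None
    degree: int | None
    cv_informedness: float
    trajectory: list[dict] = field(default_factory=list)

    def make_estimator(self) -> SVC:
        kw: dict = {"kernel": self.kernel, "C": self.C, "class_weight": "balanced"}
        if self.kernel == "rbf":
            kw["gamma"] = self.gamma
        elif self.kernel == "poly":
            kw["degree"] = self.degree
            kw["gamma"] = "scale"
            kw["coef0"] = 1.0
        return SVC(**kw)


def _sample_config(rng: np.random.Generator) -> dict:
    kernel = KERNELS[rng.integers(len(KERNELS))]
    cfg = {
        "kernel": kernel,
        "C": float(10.0 ** rng.uniform(*LOG_C_RANGE)),
        "gamma": None,
        "degree": None,
    }
    if kernel == "rbf":
        cfg["gamma"] = float(10.0 ** rng.uniform(*LOG_GAMMA_RANGE))
    elif kernel == "poly":
        cfg["degree"] = int(rng.choice(DEGREES))
    return cfg


def _encode(cfg: dict) -> np.ndarray:
    """Numeric embedding of a configuration for the GP surrogate."""
    onehot = [1.0 if cfg["kernel"] == k else 0.0 for k in KERNELS]
    log_c = (np.log10(cfg["C"]) - LOG_C_RANGE[0]) / (LOG_C_RANGE[1] - LOG_C_RANGE[0])
    if cfg["gamma"] is not None:
        log_g = (np.log10(cfg["gamma"]) - LOG_GAMMA_RANGE[0]) / (
            LOG_GAMMA_RANGE[1] - LOG_GAMMA_RANGE[0]
        )
    else:
        log_g = 0.5
    deg = (cfg["degree"] - DEGREES[0]) / (DEGREES[-1] - DEGREES[0]) if cfg["degree"] else 0.5
    return np.array(onehot + [log_c, log_g, deg])


def _cv_informedness(
    estimator: SVC, X: np.ndarray, y: np.ndarray, splits: list
) -> float:
    """Mean fold informedness; degenerate folds are skipped with a warning."""
    js = []
    for tr, va in splits:
        if np.unique(y[tr]).size < 2 or np.unique(y[va]).size < 2:
            warnings.warn("skipping single-class CV fold", stacklevel=2)
            continue
        est = SVC(**estimator.get_params())
        est.fit(X[tr], y[tr])
        pred = est.predict(X[va])
        tp = int(((pred == 1) & (y[va] == 1)).sum())
        fn = int(((pred == 0) & (y[va] == 1)).sum())
        fp = int(((pred == 1) & (y[va] == 0)).sum())
        tn = int(((pred == 0) & (y[va] == 0)).sum())
        js.append(informedness((tp, fn, fp, tn)))
    if not js:
        raise ValueError("all cross-validation folds were degenerate")
    return float(np.mean(js))


def tune_hyperparameters(
    X_train: np.ndarray,
    y_binary: np.ndarray,
    budget: int = 50,
    folds: int = 10,
    seed: int = 0,
    method: str = "bayes",
    n_initial: int = 10,
) -> SearchResult:
    """Maximise 10-fold CV informedness over kernel/C/kernel-parameter space.

    ``method="bayes"`` runs a sequential model-based search: after
    ``n_initial`` random configurations a Gaussian-process surrogate with an
    expected-improvement acquisition proposes each next configuration from a
    random candidate pool.  ``method="random"`` evaluates ``budget`` random
    configurations.  Both are deterministic under ``seed`` and return the
    best configuration visited.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if method not in ("bayes", "random"):
        raise ValueError(f"unknown search method {method!r}")
    X_train = np.asarray(X_train, dtype=float)
    y_binary = np.asarray(y_binary).astype(int)
    counts = np.bincount(y_binary, minlength=2)
    if counts.min() == 0:
        raise ValueError("y_binary must contain both classes")
    folds_eff = int(min(folds, counts.min()))
    if folds_eff < 2:
        raise ValueError("need at least 2 subjects in the rarer class for CV")
    if folds_eff < folds:
        warnings.warn(
            f"reducing CV folds from {folds} to {folds_eff} (rare positive class)",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    splits = list(skf.split(X_train, y_binary))
    rng = np.random.default_rng(seed)

    trajectory: list[dict] = []

    def evaluate(cfg: dict) -> float:
        res = SearchResult(cv_informedness=np.nan, trajectory=[], **cfg)
        j = _cv_informedness(res.make_estimator(), X_train, y_binary, splits)
        trajectory.append({**cfg, "cv_informedness": j})
        return j

    n_init = min(n_initial, budget) if method == "bayes" else budget
    for _ in range(n_init):
        evaluate(_sample_config(rng))

    if method == "bayes":
        while len(trajectory) < budget:
            X_obs = np.stack([_encode(t) for t in trajectory])
            y_obs = np.array([t["cv_informedness"] for t in trajectory])
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(1.0) * Matern(length_scale=0.5, nu=2.5)
                + WhiteKernel(noise_level=1e-3),
                normalize_y=True,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X_obs, y_obs)
            candidates = [_sample_config(rng) for _ in range(128)]
            Xc = np.stack([_encode(c) for c in candidates])
            mu, sd = gp.predict(Xc, return_std=True)
            best_y = y_obs.max()
            sd = np.maximum(sd, 1e-9)
            z = (mu - best_y) / sd
            ei = (mu - best_y) * norm.cdf(z) + sd * norm.pdf(z)
            evaluate(candidates[int(np.argmax(ei))])

    best = max(trajectory, key=lambda t: t["cv_informedness"])
    return SearchResult(
        kernel=best["kernel"],
        C=best["C"],
        gamma=best["gamma"],
        degree=best["degree"],
        cv_informedness=best["cv_informedness"],
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# one-vs-all training and evaluation


@dataclass
class OvaModel:
    """One trained binary classifier (its class positive, the rest negative)."""

    class_id: int
    feature_set: np.ndarray
    kernel: str
    C: float
    kernel_params: dict
    estimator: SVC
    cv_informedness: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.decision_function(np.asarray(X)[:, self.feature_set])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X)[:, self.feature_set]).astype(int)

    def manifest(self) -> dict:
        return {
            "class_id": int(self.class_id),
            "kernel": self.kernel,
            "C": self.C,
            "kernel_params": self.kernel_params,
            "cv_informedness": self.cv_informedness,
            "n_features": int(self.feature_set.size),
            "feature_set": self.feature_set.tolist(),
        }


def train_ova(
    X_train: np.ndarray,
    labels_train: np.ndarray,
    rankings: dict[int, ClassFeatureRanking],
    budget: int = 50,
    folds: int = 10,
    seed: int = 0,
    method: str = "bayes",
) -> list[OvaModel]:
    """Tune and fit one binary SVM per survival class on its own voxel set.

    After the search, each classifier is re-fitted on all training rows with
    the optimal hyper-parameters.  Overlapping per-class voxel sets are
    allowed; the models stay independent.
    """
    X_train = np.asarray(X_train, dtype=float)
    labels_train = np.asarray(labels_train).astype(int)
    class_ids = sorted(np.unique(labels_train).tolist())
    missing = [c for c in class_ids if c not in rankings]
    if missing:
        raise ValueError(f"rankings missing for classes {missing}")
    models = []
    for i, c in enumerate(class_ids):
        fs = np.asarray(rankings[c].selected, dtype=int)
        y = (labels_train == c).astype(int)
        best = tune_hyperparameters(
            X_train[:, fs], y, budget=budget, folds=folds, seed=seed + 7919 * i,
            method=method,
        )
        est = best.make_estimator()
        est.fit(X_train[:, fs], y)
        models.append(
            OvaModel(
                class_id=c,
                feature_set=fs,
                kernel=best.kernel,
                C=best.C,
                kernel_params={"gamma": best.gamma, "degree": best.degree},
                estimator=est,
                cv_informedness=best.cv_informedness,
            )
        )
    return models


@dataclass
class EvalReport:
    """Per-class one-vs-all holdout metrics."""

    per_class: dict[int, dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({str(k): v for k, v in self.per_class.items()}, indent=1))

    def to_text(self) -> str:
        lines = [f"{'class':>5} {'error%':>8} {'informedness':>13} {'c-stat':>7}  TP/FN/FP/TN"]
        for c, row in sorted(self.per_class.items()):
            if not row.get("defined", True):
                lines.append(f"{c:>5}  (class absent from the test set)")
                continue
            tp, fn, fp, tn = row["confusion"]
            lines.append(
                f"{c:>5} {100 * row['error_rate']:>8.2f} {row['informedness']:>13.3f} "
                f"{row['c_statistic']:>7.3f}  {tp}/{fn}/{fp}/{tn}"
            )
        return "\n".join(lines)


def _binary_report(y_true: np.ndarray, pred: np.ndarray, scores: np.ndarray) -> dict:
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    defined = (tp + fn) > 0 and (tn + fp) > 0
    return {
        "defined": defined,
        "confusion": [tp, fn, fp, tn],
        "error_rate": (fp + fn) / y_true.size,
        "informedness": informedness((tp, fn, fp, tn)) if defined else float("nan"),
        "c_statistic": auroc(y_true == 1, scores),
    }


def evaluate_holdout(
    models: Sequence[OvaModel], X_test: np.ndarray, labels_test: np.ndarray
) -> EvalReport:
    """Per-class error rate, informedness, and c-statistic on the holdout."""
    X_test = np.asarray(X_test, dtype=float)
    labels_test = np.asarray(labels_test).astype(int)
    report = {}
    for model in models:
        y = (labels_test == model.class_id).astype(int)
        report[model.class_id] = _binary_report(
            y, model.predict(X_test), model.decision_values(X_test)
        )
    return EvalReport(per_class=report)


def baseline_knn(
    X_train: np.ndarray,
    labels_train: np.ndarray,
    rankings: dict[int, ClassFeatureRanking],
    X_test: np.ndarray,
    labels_test: np.ndarray,
    k_neighbors: int = 5,
) -> EvalReport:
    """K-nearest-neighbour one-vs-all baseline under the same contract."""
    X_train = np.asarray(X_train, dtype=float)
    labels_train = np.asarray(labels_train).astype(int)
    labels_test = np.asarray(labels_test).astype(int)
    if k_neighbors >= X_train.shape[0]:
        raise ValueError("k_neighbors must be smaller than the training size")
    report = {}
    for c in sorted(np.unique(labels_train).tolist()):
        fs = np.asarray(rankings[c].selected, dtype=int)
        if fs.size == 0:
            raise ValueError("empty feature set")
        y_tr = (labels_train == c).astype(int)
        knn = KNeighborsClassifier(n_neighbors=k_neighbors).fit(X_train[:, fs], y_tr)
        Xt = np.asarray(X_test, dtype=float)[:, fs]
        pred = knn.predict(Xt)
        proba = knn.predict_proba(Xt)
        scores = proba[:, list(knn.classes_).index(1)] if 1 in knn.classes_ else np.zeros(len(Xt))
        report[c] = _binary_report((labels_test == c).astype(int), pred, scores)
    return EvalReport(per_class=report)
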
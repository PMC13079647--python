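"""Cross-individual evaluation machinery.

The benchmark validates every classifier across individuals: all trials
of one mouse form the test set (leave-one-mouse-out) and, per held-out
mouse, 10 bootstrap resamples of the training trials yield 10 models, so
a four-mouse cohort gives 40 evaluations per scenario-algorithm pair.
Bootstrap seeds live in the split plan, not in the classifier, so every
algorithm sees byte-identical training multisets for the same (mouse,
bootstrap) cell — a prerequisite for the paired significance tests.

Class balance is enforced by downsampling the majority class before
bootstrapping; hyperparameters are tuned per evaluation by a stratified
3-fold grid search on the training data only.  Metrics cover accuracy at
the 0.5 threshold, ROC and Precision-Recall AUC, the Brier score, and
per-sample train/inference runtimes.  Platt calibration refits the model
on 67 % of the training set and learns a univariate logistic map from
held-out (probability, label) pairs.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    brier_score_loss,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split


@dataclass(frozen=True)
class Split:
    held_out_mouse: str
    training_mice: tuple[str, ...]
    bootstrap_index: int
    bootstrap_seed: int


@dataclass
class SplitPlan:
    splits: list[Split]
    n_bootstraps: int
    seed: int

    def __len__(self) -> int:
        return len(self.splits)


def make_split_plan(
    mouse_ids, n_bootstraps: int = 10, seed: int = 0
) -> SplitPlan:
    """Leave-one-mouse-out x bootstrap plan.

    ``mouse_ids`` may be a cohort (anything with a ``mouse_ids``
    attribute) or a list of ids.  Bootstrap seeds are drawn once from the
    plan seed so they are shared by every algorithm evaluated under the
    plan.
    """
    ids = list(getattr(mouse_ids, "mouse_ids", mouse_ids))
    if len(ids) < 2:
        raise ValueError("cross-individual validation needs at least 2 mice")
    rng = np.random.default_rng(seed)
    splits = []
    for held_out in ids:
        training = tuple(m for m in ids if m != held_out)
        for b in range(n_bootstraps):
            splits.append(
                Split(
                    held_out_mouse=held_out,
                    training_mice=training,
                    bootstrap_index=b,
                    bootstrap_seed=int(rng.integers(2**31)),
                )
            )
    return SplitPlan(splits=splits, n_bootstraps=n_bootstraps, seed=seed)


def balance_by_downsampling(
    labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a perfectly class-balanced subset.

    The minority class is kept entirely; the majority class is
    downsampled uniformly without replacement to the minority count.
    Returned indices are sorted, so equal rngs give identical subsets.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    n_min = counts.min()
    keep = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def bootstrap_resample(indices: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample with replacement to the original size."""
    indices = np.asarray(indices)
    return rng.choice(indices, size=len(indices), replace=True)


def grid_search_cv(
    build,
    grid: list[dict],
    X: np.ndarray,
    y: np.ndarray,
    k: int = 3,
    seed: int = 0,
) -> tuple[dict, list[tuple[dict, float]]]:
    """Stratified k-fold grid search by mean accuracy.

    ``build`` maps a hyperparameter dict to an unfitted classifier.
    Ties break toward the earlier grid point.  Returns the best
    parameters and the full (params, mean accuracy) table.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) < k:
        raise ValueError(f"need at least {k} trials for {k}-fold cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    table = []
    for params in grid:
        accs = []
        for train_idx, val_idx in folds:
            model = build(params)
            model.fit(X[train_idx], y[train_idx])
            proba = model.predict_proba(X[val_idx])[:, 1]
            accs.append(float(np.mean((proba >= 0.5).astype(int) == y[val_idx])))
        table.append((params, float(np.mean(accs))))
    best = max(range(len(table)), key=lambda i: (table[i][1], -i))
    return dict(table[best][0]), table


@dataclass
class EvaluationReport:
    """Metrics of one model evaluation on one held-out mouse."""

    accuracy: float
    roc_auc: float | None
    pr_auc: float | None
    brier: float
    n_train: int
    n_test: int
    train_runtime_per_sample: float = np.nan
    infer_runtime_per_sample: float = np.nan
    calibrated: bool = False
    scenario: str | None = None
    algorithm: str | None = None
    held_out_mouse: str | None = None
    bootstrap_index: int | None = None
    best_params: dict = field(default_factory=dict)


def evaluate_probabilities(
    proba: np.ndarray, y_test: np.ndarray, **meta
) -> EvaluationReport:
    """Metrics from positive-class probabilities and binary labels."""
    proba = np.asarray(proba, dtype=float)
    y_test = np.asarray(y_test)
    accuracy = float(np.mean((proba >= 0.5).astype(int) == y_test))
    brier = float(brier_score_loss(y_test, proba))
    if len(np.unique(y_test)) < 2:
        warnings.warn("single-class test set: ROC/PR AUC undefined", stacklevel=2)
        roc = pr = None
    else:
        roc = float(roc_auc_score(y_test, proba))
        pr = float(average_precision_score(y_test, proba))
    meta.setdefault("n_train", 0)
    return EvaluationReport(
        accuracy=accuracy,
        roc_auc=roc,
        pr_auc=pr,
        brier=brier,
        n_test=len(y_test),
        **meta,
    )


def evaluate_model(
    model, X_test: np.ndarray, y_test: np.ndarray, calibrator=None, **meta
) -> EvaluationReport:
    """Evaluate a trained model; probabilities pass through the calibrator
    (if any) before every metric."""
    proba = model.predict_proba(np.asarray(X_test))[:, 1]
    if calibrator is not None:
        proba = calibrator(proba)
    meta.setdefault("calibrated", calibrator is not None)
    return evaluate_probabilities(proba, y_test, **meta)


# ---------------------------------------------------------------------------
# Platt calibration


@dataclass
class PlattCalibrator:
    """Univariate logistic map from raw scores to calibrated probabilities."""

    slope: float
    intercept: float

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        z = self.slope * np.asarray(scores, dtype=float) + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> PlattCalibrator:
    """Fit the logistic calibration map on (score, label) pairs."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("calibration hold-out must contain both classes")
    lr = LogisticRegression(max_iter=2000)
    lr.fit(np.asarray(scores, dtype=float).reshape(-1, 1), labels)
    return PlattCalibrator(slope=float(lr.coef_[0, 0]), intercept=float(lr.intercept_[0]))


def platt_calibrate(
    build_model,
    X: np.ndarray,
    y: np.ndarray,
    holdout_fraction: float = 1.0 / 3.0,
    seed: int = 0,
):
    """Platt-calibrate a model without touching any test data.

    A stratified ``holdout_fraction`` (33 %) of the training set is set
    aside; the primary model is fitted on the remaining 67 % and its
    hold-out probabilities train the logistic calibrator.  Returns
    ``(fitted_model, calibrator)``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    X_fit, X_hold, y_fit, y_hold = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    if len(np.unique(y_hold)) < 2 or len(np.unique(y_fit)) < 2:
        raise ValueError("calibration split left a single-class subset")
    model = build_model()
    model.fit(X_fit, y_fit)
    calibrator = fit_platt(model.predict_proba(X_hold)[:, 1], y_hold)
    return model, calibrator


# ---------------------------------------------------------------------------
# significance tests and runtime accounting


def paired_wilcoxon(acc_a, acc_b) -> float | None:
    """Two-sided Wilcoxon signed-rank p-value on paired accuracies.

    Zero differences are dropped (classic convention); with fewer than
    two non-zero differences the test is undefined and ``None`` is
    returned.  The exact null distribution is used for small samples
    without ties, the continuity-corrected normal approximation
    otherwise (scipy's ``method='auto'``).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.count_nonzero(diffs) < 2:
        return None
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method="auto"
    )
    return float(res.pvalue)


def fisher_exact_vs_chance(
    correct_count: int, n: int, chance: float = 0.5
) -> float:
    """Fisher's exact test of an accuracy against the chance level.

    Builds the 2x2 table of observed correct/incorrect counts against the
    counts expected by chance and returns the two-sided exact p-value.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= correct_count <= n:
        raise ValueError("correct_count must be in [0, n]")
    expected = int(round(n * chance))
    table = [[correct_count, n - correct_count], [expected, n - expected]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def measure_runtime(func, n_samples: int):
    """Run ``func`` and return ``(result, wall seconds per sample)``."""
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    t0 = time.perf_counter()
    result = func()
    elapsed = time.perf_counter() - t0
    return result, elapsed / n_samples
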
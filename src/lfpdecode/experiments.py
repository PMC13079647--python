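"""Scenario runner: benchmark grid, peri-length sweep, calibration study.

A *classification scenario* fixes the task (stimulus detection SD or
response prediction RP), the analysis window (PRE / PERI / FULL), the
feature type (RAW / FFT), the cortical layer (single layer or ALL) and
the stimulus-intensity subset.  For every scenario-algorithm pair the
runner executes the full leave-one-mouse-out bootstrap protocol: QC
filtering, causal Butterworth filtering, feature extraction, class
balancing by downsampling, bootstrap resampling, train-anchored Min-Max
scaling, 3-fold grid search, final fit, and evaluation on the held-out
mouse — 40 evaluations for a four-mouse, ten-bootstrap plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baselines import ClassifierSpec, build_classifier, default_grid
from .features import (
    FeatureMatrix,
    WindowSpec,
    apply_minmax,
    extract_fft,
    extract_raw,
    fit_minmax,
)
from .preprocess import FilterSpec, QCConfig, apply_butterworth, filter_trials
from .synth import Cohort, INTENSITIES, Trial, WOP_MS
from .validation import (
    EvaluationReport,
    SplitPlan,
    balance_by_downsampling,
    bootstrap_resample,
    evaluate_model,
    evaluate_probabilities,
    fit_platt,
    grid_search_cv,
    measure_runtime,
)

TASKS = ("SD", "RP")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the benchmark grid."""

    task: str = "SD"
    window: WindowSpec = field(default_factory=lambda: WindowSpec("PERI"))
    feature_type: str = "RAW"
    layer: str = "L4"
    intensity_subset: tuple[int, ...] | str = "all"
    balance: bool = True

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.feature_type not in ("RAW", "FFT"):
            raise ValueError("feature_type must be RAW or FFT")
        if isinstance(self.window, str):
            object.__setattr__(self, "window", WindowSpec(self.window))
        if self.intensity_subset != "all":
            subset = tuple(sorted(self.intensity_subset))
            if not set(subset) <= set(INTENSITIES):
                raise ValueError(f"intensities must be within {INTENSITIES}")
            object.__setattr__(self, "intensity_subset", subset)

    @property
    def intensities(self) -> tuple[int, ...]:
        return INTENSITIES if self.intensity_subset == "all" else self.intensity_subset

    @property
    def name(self) -> str:
        sub = "all" if self.intensity_subset == "all" else "-".join(
            str(i) for i in self.intensity_subset
        )
        trunc = (
            f"@{self.window.peri_truncation_ms:g}ms"
            if self.window.peri_truncation_ms is not None
            else ""
        )
        return f"{self.task}:{self.window.name}{trunc}:{self.feature_type}:{self.layer}:{sub}"


@dataclass
class SweepSpec:
    """Peri-length x intensity sweep configuration."""

    intensities: tuple[int, ...] = (20, 40, 60, 80, 100)
    peri_lengths_ms: tuple[float, ...] = tuple(range(5, 101, 5))
    algorithm: str = "LSM"

    def __post_init__(self) -> None:
        if any(not 0 < l <= 100 for l in self.peri_lengths_ms):
            raise ValueError("peri lengths must be in (0, 100] ms")


def label_trials(trials: list[Trial], task: str) -> np.ndarray:
    """Binary labels: SD = stimulus present; RP = lick inside the WOP.

    Early-lick trials must be excluded upstream by QC; encountering one
    here is an error because its label is undefined by the protocol.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    labels = np.empty(len(trials), dtype=int)
    for i, t in enumerate(trials):
        lat = t.lick_latency_ms
        if lat is not None and 0.0 <= lat < WOP_MS[0]:
            raise ValueError(
                f"trial {t.trial_id} has an early lick; exclude it via QC first"
            )
        if task == "SD":
            labels[i] = int(t.intensity_pct > 0)
        else:
            labels[i] = int(lat is not None and WOP_MS[0] <= lat < WOP_MS[1])
    return labels


def build_features(
    cohort: Cohort,
    scenario: ScenarioSpec,
    qc: QCConfig | None = None,
    filter_spec: FilterSpec | None = None,
) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """QC-filter, Butterworth-filter and featurize a cohort for a scenario.

    Returns the unscaled feature matrix (Min-Max scaling is
    train-anchored and therefore applied per split, not here), the task
    labels and the mouse id per row.
    """
    filter_spec = filter_spec or FilterSpec()
    rows, names, mice, kept_trials = [], None, [], []
    for session in cohort.iter_sessions():
        kept, _ = filter_trials(session, qc)
        kept = [t for t in kept if t.intensity_pct in scenario.intensities]
        if not kept:
            continue
        layer_map = session.layer_map
        extract = extract_raw if scenario.feature_type == "RAW" else extract_fft
        for trial in kept:
            filtered = apply_butterworth(trial.signal)
            vec, vec_names = extract(filtered, scenario.window, scenario.layer, layer_map)
            rows.append(vec)
            names = vec_names
            mice.append(trial.mouse_id)
            kept_trials.append(trial)
    if not rows:
        raise ValueError("no trials survive QC and intensity selection")
    labels = label_trials(kept_trials, scenario.task)
    matrix = FeatureMatrix(
        np.vstack(rows), names, trial_ids=[t.trial_id for t in kept_trials]
    )
    return matrix, labels, np.array(mice)


def _n_traces(scenario: ScenarioSpec) -> int:
    return 4 if scenario.layer == "ALL" else 1


def run_scenario(
    cohort: Cohort,
    scenario: ScenarioSpec,
    algorithm: str,
    plan: SplitPlan,
    qc: QCConfig | None = None,
    filter_spec: FilterSpec | None = None,
    grid: list[dict] | None = None,
    calibrate: bool = False,
    measure_runtimes: bool = True,
    prepared: tuple | None = None,
) -> list[EvaluationReport]:
    """Run every split of the plan for one scenario and one algorithm.

    ``prepared`` may carry a precomputed ``build_features`` result to
    share extraction across algorithms.  Per split: balance the training
    trials by downsampling, draw one bootstrap resample, fit the Min-Max
    scaler on the resample, grid-search with stratified 3-fold CV, fit
    the winning setting on the full resample and evaluate on the held-out
    mouse.  With ``calibrate=True`` the final model is instead fitted on
    67 % of the resample and Platt-calibrated on the remaining 33 %.
    """
    matrix, labels, mice = prepared or build_features(cohort, scenario, qc, filter_spec)
    grid = grid if grid is not None else default_grid(algorithm)
    series = scenario.feature_type == "RAW"
    n_traces = _n_traces(scenario)
    reports = []
    for split in plan.splits:
        rng = np.random.default_rng(split.bootstrap_seed)
        train_mask = np.isin(mice, split.training_mice)
        test_mask = mice == split.held_out_mouse
        train_idx = np.flatnonzero(train_mask)
        y_train_all = labels[train_idx]
        if scenario.balance:
            bal = balance_by_downsampling(y_train_all, rng)
            train_idx = train_idx[bal]
        boot_idx = bootstrap_resample(train_idx, rng)

        X_train = FeatureMatrix(
            matrix.values[boot_idx], list(matrix.feature_names)
        )
        y_train = labels[boot_idx]
        X_test = FeatureMatrix(matrix.values[test_mask], list(matrix.feature_names))
        y_test = labels[test_mask]

        scaler = fit_minmax(X_train)
        X_tr = apply_minmax(scaler, X_train).values
        X_te = apply_minmax(scaler, X_test).values

        def build(params):
            return build_classifier(
                ClassifierSpec(algorithm, params, seed=split.bootstrap_seed % (2**31)),
                n_traces=n_traces,
                series=series,
            )

        best_params, _ = grid_search_cv(
            build, grid, X_tr, y_train, k=3, seed=split.bootstrap_seed % (2**31)
        )

        calibrator = None
        if calibrate:
            from .validation import platt_calibrate

            model, calibrator = platt_calibrate(
                lambda: build(best_params),
                X_tr,
                y_train,
                seed=split.bootstrap_seed % (2**31),
            )
            train_rt = np.nan
        else:
            model = build(best_params)
            if measure_runtimes:
                _, train_rt = measure_runtime(
                    lambda: model.fit(X_tr, y_train), len(y_train)
                )
            else:
                model.fit(X_tr, y_train)
                train_rt = np.nan
        if measure_runtimes:
            proba_holder = {}
            _, infer_rt = measure_runtime(
                lambda: proba_holder.setdefault("p", model.predict_proba(X_te)),
                len(y_test),
            )
        else:
            infer_rt = np.nan
        report = evaluate_model(
            model,
            X_te,
            y_test,
            calibrator=calibrator,
            n_train=len(y_train),
            scenario=scenario.name,
            algorithm=algorithm,
            held_out_mouse=split.held_out_mouse,
            bootstrap_index=split.bootstrap_index,
            best_params=best_params,
            train_runtime_per_sample=train_rt,
            infer_runtime_per_sample=infer_rt,
        )
        reports.append(report)
    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])


def run_benchmark(
    cohort: Cohort,
    scenarios: list[ScenarioSpec],
    algorithms: list[str],
    plan: SplitPlan,
    qc: QCConfig | None = None,
    filter_spec: FilterSpec | None = None,
    measure_runtimes: bool = True,
) -> pd.DataFrame:
    """Full scenario x algorithm cross product; one tidy row per evaluation."""
    frames = []
    for scenario in scenarios:
        prepared = build_features(cohort, scenario, qc, filter_spec)
        for algorithm in algorithms:
            reports = run_scenario(
                cohort,
                scenario,
                algorithm,
                plan,
                qc=qc,
                filter_spec=filter_spec,
                prepared=prepared,
                measure_runtimes=measure_runtimes,
            )
            frame = reports_to_frame(reports)
            frame["task"] = scenario.task
            frame["window"] = scenario.window.name
            frame["feature_type"] = scenario.feature_type
            frame["layer"] = scenario.layer
            frame["intensity_subset"] = scenario.name.rsplit(":", 1)[1]
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def accuracy_heatmap(results: pd.DataFrame) -> pd.DataFrame:
    """Median accuracy by (scenario, algorithm), ready for plotting."""
    return results.pivot_table(
        index="scenario", columns="algorithm", values="accuracy", aggfunc="median"
    )


def peri_length_sweep(
    cohort: Cohort,
    sweep: SweepSpec,
    plan: SplitPlan,
    qc: QCConfig | None = None,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Stimulus detection vs catch for each intensity at each peri length.

    Uses RAW features of the truncated peri-stimulus window (layer L4)
    and reports mean accuracy with its standard error over the plan's
    evaluations per (intensity, length) cell.
    """
    rows = []
    for intensity in sweep.intensities:
        for length in sweep.peri_lengths_ms:
            scenario = ScenarioSpec(
                task="SD",
                window=WindowSpec("PERI", peri_truncation_ms=float(length)),
                feature_type="RAW",
                layer="L4",
                intensity_subset=(0, intensity),
            )
            reports = run_scenario(
                cohort,
                scenario,
                sweep.algorithm,
                plan,
                qc=qc,
                filter_spec=filter_spec,
                measure_runtimes=False,
            )
            accs = np.array([r.accuracy for r in reports])
            rows.append(
                {
                    "intensity_pct": intensity,
                    "peri_length_ms": length,
                    "mean_accuracy": accs.mean(),
                    "sem_accuracy": accs.std(ddof=1) / np.sqrt(len(accs)),
                    "n_evaluations": len(accs),
                }
            )
    return pd.DataFrame(rows)


def run_imbalanced_analysis(
    cohort: Cohort,
    plan: SplitPlan,
    algorithms: tuple[str, ...] = ("GLM", "LSM"),
    intensity_subset: tuple[int, ...] | str = "all",
    qc: QCConfig | None = None,
    filter_spec: FilterSpec | None = None,
) -> pd.DataFrame:
    """Balanced vs natural class mix, raw vs Platt-calibrated probabilities.

    Runs the PERI/RAW/L4 stimulus-detection scenario in four variants per
    algorithm (balance x calibration) and adds an always-positive naive
    baseline per split for context.  On the all-intensity mix the
    positive fraction is 5/6, so accuracy alone is misleading and the
    threshold-free metrics (ROC/PR AUC) plus the Brier score matter.
    """
    frames = []
    base = ScenarioSpec(
        task="SD", window=WindowSpec("PERI"), feature_type="RAW", layer="L4",
        intensity_subset=intensity_subset,
    )
    for balance in (True, False):
        scenario = replace(base, balance=balance)
        prepared = build_features(cohort, scenario, qc, filter_spec)
        for algorithm in algorithms:
            for calibrate in (False, True):
                reports = run_scenario(
                    cohort,
                    scenario,
                    algorithm,
                    plan,
                    qc=qc,
                    filter_spec=filter_spec,
                    prepared=prepared,
                    calibrate=calibrate,
                    measure_runtimes=False,
                )
                frame = reports_to_frame(reports)
                frame["balanced_training"] = balance
                frames.append(frame)
        # naive always-positive baseline on the same test sets
        _, labels, mice = prepared
        naive = []
        for split in plan.splits:
            y_test = labels[mice == split.held_out_mouse]
            report = evaluate_probabilities(
                np.ones(len(y_test)),
                y_test,
                scenario=scenario.name,
                algorithm="NAIVE_POS",
                held_out_mouse=split.held_out_mouse,
                bootstrap_index=split.bootstrap_index,
            )
            naive.append(report)
        frame = reports_to_frame(naive)
        frame["balanced_training"] = balance
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
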